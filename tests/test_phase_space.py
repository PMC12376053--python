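"""Pretreatment, delay/dimension selection and trajectory reconstruction."""

import numpy as np
import pandas as pd
import pytest

from pod12risk import (SeriesPanel, delay_by_mutual_information,
                       embedding_dim_by_fnn, embed_panel,
                       impute_before_after_mean, reconstruct, stabilize)
from pod12risk.phase_space import _mutual_information


def _panel(values: dict) -> SeriesPanel:
    df = pd.DataFrame(values)
    return SeriesPanel(values=df, mask=df.notna())


class TestImputation:
    def test_interior_gap_is_neighbor_mean(self):
        panel = _panel({"v": [1.0, np.nan, 3.0]})
        out = impute_before_after_mean(panel)
        assert out.values["v"].tolist() == [1.0, 2.0, 3.0]

    def test_no_missing_is_identity(self):
        panel = _panel({"v": [1.0, 5.0, 2.0, 4.0]})
        out = impute_before_after_mean(panel)
        pd.testing.assert_frame_equal(out.values, panel.values)

    def test_symmetric_zero_neighbors(self):
        out = impute_before_after_mean(_panel({"v": [0.0, np.nan, 0.0]}))
        assert out.values["v"].iloc[1] == 0.0

    def test_consecutive_gaps_reach_fixed_point(self):
        # iterating x_i=(x_{i-1}+x_{i+1})/2 converges to the linear interpolant
        out = impute_before_after_mean(_panel({"v": [0.0, np.nan, np.nan, 3.0]}))
        assert out.values["v"].tolist() == [0.0, 1.0, 2.0, 3.0]

    def test_boundary_gap_takes_nearest_observation(self):
        out = impute_before_after_mean(_panel({"v": [np.nan, 2.0, 4.0]}))
        assert out.values["v"].iloc[0] == 2.0

    def test_mask_still_marks_imputed_positions(self):
        panel = _panel({"v": [1.0, np.nan, 3.0]})
        out = impute_before_after_mean(panel)
        assert not out.mask["v"].iloc[1]


class TestStabilize:
    def test_imputed_entry_scaled_by_mu(self):
        panel = impute_before_after_mean(_panel({"v": [1.0, np.nan, 3.0]}))
        out = stabilize(panel, mu=0.85)
        assert out.values["v"].iloc[1] == pytest.approx(2.0 * 0.85)
        assert out.values["v"].iloc[0] == 1.0  # observed entries untouched

    def test_mu_one_is_identity(self):
        panel = impute_before_after_mean(_panel({"v": [1.0, np.nan, 3.0]}))
        out = stabilize(panel, mu=1.0)
        pd.testing.assert_frame_equal(out.values, panel.values)

    def test_zero_imputed_stays_zero(self):
        panel = impute_before_after_mean(_panel({"v": [0.0, np.nan, 0.0]}))
        assert stabilize(panel).values["v"].iloc[1] == 0.0

    def test_scope_all_scales_everything(self):
        panel = _panel({"v": [2.0, 4.0, 6.0]})
        out = stabilize(panel, mu=0.5, mu_scope="all")
        assert out.values["v"].tolist() == [1.0, 2.0, 3.0]

    def test_invalid_mu_rejected(self):
        with pytest.raises(ValueError):
            stabilize(_panel({"v": [1.0, 2.0, 3.0]}), mu=0.0)


class TestMutualInformationDelay:
    def test_sine_delay_near_quarter_period(self):
        rng = np.random.default_rng(0)
        t = np.arange(1000)
        x = 2 + np.sin(2 * np.pi * t / 40) + rng.normal(0, 0.05, 1000)
        tau, curve = delay_by_mutual_information(x, max_lag=60)
        assert abs(tau - 10) <= 3
        assert curve.size == 60

    def test_iid_noise_falls_back_to_lag_one(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=2000)
        tau, curve = delay_by_mutual_information(x, max_lag=20)
        # for independent samples MI(lag>=1) is near zero everywhere
        assert curve[5:].mean() < 0.1 * np.log(np.sqrt(2000))
        assert tau >= 1

    def test_affine_rescaling_invariance(self, lorenz_series):
        tau_a, _ = delay_by_mutual_information(lorenz_series, max_lag=50)
        tau_b, _ = delay_by_mutual_information(5.0 * lorenz_series - 3.0,
                                               max_lag=50)
        assert tau_a == tau_b

    def test_lorenz_delay_matches_bruteforce_mi(self, lorenz_series):
        tau, curve = delay_by_mutual_information(lorenz_series, max_lag=40)
        # independent oracle: direct MI recomputation on the same bins
        n_bins = int(np.ceil(np.sqrt(lorenz_series.size)))
        oracle = [_bruteforce_mi(lorenz_series, lag, n_bins) for lag in range(1, 41)]
        assert np.allclose(curve, oracle, atol=1e-12)

    def test_constant_series_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            delay_by_mutual_information(np.ones(500), max_lag=10)


def _bruteforce_mi(x, lag, n_bins):
    """Plain double-loop MI over the joint histogram (oracle)."""
    a, b = x[:-lag], x[lag:]
    joint, _, _ = np.histogram2d(a, b, bins=n_bins)
    p = joint / joint.sum()
    px, py = p.sum(axis=1), p.sum(axis=0)
    total = 0.0
    for i in range(n_bins):
        for j in range(n_bins):
            if p[i, j] > 0:
                total += p[i, j] * np.log(p[i, j] / (px[i] * py[j]))
    return total


class TestFalseNearestNeighbors:
    def test_noiseless_sine_needs_two_dimensions(self, sine_series):
        m, curve = embedding_dim_by_fnn(sine_series, tau=10)
        assert m == 2
        assert curve[0] > 0.1  # 1-D projection folds the cycle

    def test_lorenz_needs_three_dimensions(self, lorenz_series):
        tau, _ = delay_by_mutual_information(lorenz_series, max_lag=50)
        m, _ = embedding_dim_by_fnn(lorenz_series, tau=tau)
        assert m == 3

    def test_constant_series_dimension_one(self):
        m, _ = embedding_dim_by_fnn(np.ones(200), tau=1)
        assert m == 1

    def test_fnn_fraction_nonincreasing_for_sine(self, sine_series):
        _, curve = embedding_dim_by_fnn(sine_series, tau=10, max_m=4,
                                        threshold=0.0)  # force full curve
        assert all(curve[i + 1] <= curve[i] + 0.02 for i in range(len(curve) - 1))

    def test_short_series_rejected(self):
        with pytest.raises(ValueError, match="too short"):
            embedding_dim_by_fnn(np.arange(30, dtype=float), tau=5, max_m=10)


class TestReconstruct:
    def test_hand_enumerated_embedding(self):
        psm = reconstruct(np.arange(1.0, 7.0), m=2, tau=1)
        np.testing.assert_array_equal(
            psm.matrix, [[1, 2, 3, 4], [2, 3, 4, 5]])
        np.testing.assert_array_equal(psm.targets, [3, 4, 5, 6])

    def test_m_one_is_identity_embedding(self):
        x = np.arange(10.0)
        psm = reconstruct(x, m=1, tau=1, l=0)
        np.testing.assert_array_equal(psm.matrix[0], x)

    def test_supervised_pair_count_formula(self):
        # N - (m-1)*tau - l pairs
        psm = reconstruct(np.arange(6.0), m=2, tau=2, l=1)
        assert psm.n_points == 6 - 2 - 1

    def test_deembedding_recovers_series_segment(self, sine_series):
        psm = reconstruct(sine_series, m=3, tau=7, l=0)
        np.testing.assert_array_equal(psm.matrix[0],
                                      sine_series[:psm.n_points])

    def test_total_dimension_accounting(self):
        t = np.arange(600)
        rng = np.random.default_rng(2)
        panel = SeriesPanel(
            values=pd.DataFrame({
                "a": 2 + np.sin(2 * np.pi * t / 40) + rng.normal(0, 0.02, 600),
                "b": 2 + np.cos(2 * np.pi * t / 30) + rng.normal(0, 0.02, 600)}),
            mask=pd.DataFrame(True, index=range(600), columns=["a", "b"]))
        params = embed_panel(panel)
        assert params.total_dimension == sum(params.m.values())
        assert set(params.tau) == {"a", "b"}

    def test_sizing_error_names_parameters(self):
        with pytest.raises(ValueError, match="N=5"):
            reconstruct(np.arange(5.0), m=3, tau=3)
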