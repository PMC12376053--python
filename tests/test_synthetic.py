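"""Cohort and monitoring-series generators: structure, calibration, dynamics."""

import numpy as np
import pandas as pd
import pytest

from pod12risk import (CohortSpec, SeriesSpec, fit_logistic, simulate_cohort,
                       simulate_series)
from pod12risk.synthetic import (DEFAULT_LOG_ODDS, DEFAULT_PREVALENCE,
                                 SeriesPanel, calibrate_intercept)


def _rosenstein_lyapunov(x, n_steps=8, min_sep=20):
    """Brute-force largest-Lyapunov oracle: mean log divergence slope of
    nearest-neighbor pairs (temporal neighbors excluded)."""
    n = x.size - n_steps
    pts = x[:n]
    div = np.zeros(n_steps + 1)
    counts = 0
    for i in range(n):
        d = np.abs(pts - pts[i])
        d[max(0, i - min_sep):i + min_sep] = np.inf
        j = int(np.argmin(d))
        if not np.isfinite(d[j]) or d[j] == 0:
            continue
        traj = np.abs(x[i:i + n_steps + 1] - x[j:j + n_steps + 1])
        if np.all(traj > 0):
            div += np.log(traj)
            counts += 1
    div /= counts
    slope = np.polyfit(np.arange(n_steps + 1), div, 1)[0]
    return slope


class TestCohort:
    def test_null_model_incidence_half(self):
        spec = CohortSpec(n=4000, log_odds={k: 0.0 for k in DEFAULT_LOG_ODDS},
                          intercept=0.0, seed=0)
        cohort = simulate_cohort(spec)
        assert cohort["pod12"].mean() == pytest.approx(0.5, abs=0.03)

    def test_default_incidence_calibrated_to_46pct(self):
        cohort = simulate_cohort(CohortSpec(n=4000, seed=1))
        assert cohort["pod12"].mean() == pytest.approx(0.46, abs=0.05)

    def test_degenerate_prevalence_forces_flag(self):
        prev = dict(DEFAULT_PREVALENCE)
        prev["ecog"] = 1.0
        cohort = simulate_cohort(CohortSpec(n=200, prevalence=prev, seed=0))
        assert (cohort["ecog"] == 1).all()

    def test_univariate_b2mg_or_inside_published_ci(self, large_cohort):
        row = fit_logistic(large_cohort, "pod12", ["b2mg"])["b2mg"]
        assert 2.787 < row.odds_ratio < 27.348

    def test_same_seed_is_bit_identical(self):
        a = simulate_cohort(CohortSpec(n=100, seed=7))
        b = simulate_cohort(CohortSpec(n=100, seed=7))
        pd.testing.assert_frame_equal(a, b)

    def test_raising_log_odds_does_not_decrease_incidence(self):
        base = simulate_cohort(CohortSpec(n=10000, seed=3)).pod12.mean()
        lo = dict(DEFAULT_LOG_ODDS)
        lo["ecog"] += 1.5
        # keep the calibrated-intercept of the *base* spec so the shift acts
        intercept = calibrate_intercept(DEFAULT_PREVALENCE, DEFAULT_LOG_ODDS)
        up = simulate_cohort(CohortSpec(n=10000, log_odds=lo,
                                        intercept=intercept, seed=3)).pod12.mean()
        assert up >= base

    def test_parameter_recovery_over_seeds(self):
        ok = total = 0
        for seed in range(20):
            cohort = simulate_cohort(CohortSpec(n=2000, seed=seed))
            fit = fit_logistic(cohort, "pod12", list(DEFAULT_LOG_ODDS), joint=True)
            for factor, beta in DEFAULT_LOG_ODDS.items():
                row = fit[factor]
                total += 1
                ok += abs(row.beta - beta) <= 2 * row.se
        assert ok / total >= 0.90

    def test_continuous_labs_consistent_with_flags(self):
        cohort = simulate_cohort(CohortSpec(n=500, seed=5))
        above = cohort["nlr_value"] >= 1.73
        assert (above == cohort["nlr"].astype(bool)).all()

    def test_unknown_factor_rejected(self):
        with pytest.raises(ValueError, match="unknown factor"):
            simulate_cohort(CohortSpec(prevalence={"not_a_factor": 0.5}))

    def test_log_odds_without_prevalence_rejected(self):
        with pytest.raises(ValueError, match="without a prevalence"):
            simulate_cohort(CohortSpec(prevalence={"ldh": 0.5},
                                       log_odds={"ecog": 1.0}))


class TestSeries:
    def test_constant_system_has_zero_variance(self):
        panel = simulate_series(SeriesSpec(system="constant", n_points=100,
                                           noise_sd=0.0, seed=0))
        assert panel.values.var().max() == 0.0

    def test_sine_autocorrelation_at_period_is_one(self):
        panel = simulate_series(SeriesSpec(system="sine", n_points=400,
                                           period=50, noise_sd=0.0, seed=0))
        x = panel.values.iloc[:, 0].to_numpy()
        r = np.corrcoef(x[:-50], x[50:])[0, 1]
        assert r == pytest.approx(1.0, abs=1e-10)

    def test_logistic_map_has_positive_lyapunov(self, logistic_map_series):
        assert _rosenstein_lyapunov(logistic_map_series) > 0

    def test_same_seed_is_bit_identical(self):
        a = simulate_series(SeriesSpec(system="lorenz", n_points=200, seed=9,
                                       missing_rate=0.05))
        b = simulate_series(SeriesSpec(system="lorenz", n_points=200, seed=9,
                                       missing_rate=0.05))
        pd.testing.assert_frame_equal(a.values, b.values)
        pd.testing.assert_frame_equal(a.mask, b.mask)

    def test_missingness_rate_and_mask_agree(self):
        panel = simulate_series(SeriesSpec(system="sine", n_points=1000,
                                           missing_rate=0.1, seed=4))
        frac = 1.0 - panel.mask.to_numpy().mean()
        assert frac == pytest.approx(0.1, abs=0.03)
        assert panel.values.isna().to_numpy().sum() == (~panel.mask).to_numpy().sum()

    def test_long_round_trip(self):
        panel = simulate_series(SeriesSpec(system="sine", n_points=50,
                                           missing_rate=0.05, seed=1))
        back = SeriesPanel.from_long(panel.to_long())
        pd.testing.assert_frame_equal(
            back.values[panel.variables], panel.values)

    def test_unknown_system_rejected(self):
        with pytest.raises(ValueError, match="unknown system"):
            simulate_series(SeriesSpec(system="rossler"))

    def test_short_chaotic_series_rejected(self):
        with pytest.raises(ValueError, match="n_points"):
            simulate_series(SeriesSpec(system="lorenz", n_points=20))
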