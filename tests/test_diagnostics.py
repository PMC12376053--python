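"""Cut-off selection, 2x2 diagnostics, Wald arithmetic, logistic fits, power."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import binom

from pod12risk import (ConfusionTable, confusion_metrics, fit_logistic,
                       proportion_power, wald_ci, youden_cutoff)
from pod12risk.synthetic import CohortSpec, simulate_cohort


class TestYoudenCutoff:
    def test_perfect_separation_gives_j_one(self):
        values = np.array([1.0, 2.0, 3.0, 10.0, 11.0, 12.0])
        labels = np.array([0, 0, 0, 1, 1, 1])
        res = youden_cutoff(values, labels)
        assert res.youden_j == pytest.approx(1.0)
        assert 3.0 < res.cutoff < 10.0

    def test_j_is_sensitivity_plus_specificity_minus_one(self):
        # the study's NLR operating point: sensitivity 0.483, specificity 0.853
        assert 0.483 + 0.853 - 1 == pytest.approx(0.336)
        rng = np.random.default_rng(0)
        values = rng.normal(size=200)
        labels = (rng.random(200) < 0.4).astype(int)
        res = youden_cutoff(values, labels)
        assert res.youden_j == pytest.approx(
            res.sensitivity + res.specificity - 1.0)

    def test_independent_labels_give_small_j(self):
        rng = np.random.default_rng(1)
        values = rng.normal(size=4000)
        labels = (rng.random(4000) < 0.5).astype(int)
        res = youden_cutoff(values, labels)
        # permutation null: optimal J over ~n candidates stays modest
        assert res.youden_j < 0.1

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(2)
        values = rng.gamma(2.0, size=300)
        labels = (values + rng.normal(0, 1, 300) > 2.0).astype(int)
        base = youden_cutoff(values, labels)
        trans = youden_cutoff(np.log(values), labels)
        assert trans.youden_j == pytest.approx(base.youden_j)
        assert trans.sensitivity == pytest.approx(base.sensitivity)

    def test_single_class_labels_error(self):
        with pytest.raises(ValueError, match="both label classes"):
            youden_cutoff([1.0, 2.0, 3.0], [1, 1, 1])


class TestConfusionMetrics:
    def test_study_validation_counts(self, study_confusion_counts):
        m = confusion_metrics(ConfusionTable(**study_confusion_counts))
        assert m.ppv == pytest.approx(0.7027, abs=5e-5)
        assert m.npv == pytest.approx(0.8846, abs=5e-5)
        assert m.accuracy == pytest.approx(0.7778, abs=5e-5)
        assert m.odds_ratio == pytest.approx(18.121, abs=5e-3)
        assert m.ci_low == pytest.approx(4.494, abs=2e-3)
        assert m.ci_high == pytest.approx(73.078, abs=5e-2)
        # the "2.769-fold" figure is a positive likelihood ratio
        assert m.positive_lr == pytest.approx(2.77, abs=0.01)

    def test_perfect_classifier_flags_undefined_or(self):
        m = confusion_metrics(ConfusionTable(tp=10, fp=0, fn=0, tn=10))
        assert m.sensitivity == m.specificity == m.ppv == m.npv == m.accuracy == 1.0
        assert not m.or_defined

    def test_symmetric_table(self):
        m = confusion_metrics(ConfusionTable(tp=1, fp=1, fn=1, tn=1))
        assert m.odds_ratio == pytest.approx(1.0)
        assert m.accuracy == pytest.approx(0.5)

    @given(tp=st.integers(1, 200), fp=st.integers(1, 200),
           fn=st.integers(1, 200), tn=st.integers(1, 200))
    @settings(derandomize=True, max_examples=50)
    def test_count_conservation(self, tp, fp, fn, tn):
        m = confusion_metrics(ConfusionTable(tp, fp, fn, tn))
        assert m.sensitivity * (tp + fn) == pytest.approx(tp)
        assert m.ci_low <= m.odds_ratio <= m.ci_high

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            ConfusionTable(tp=-1, fp=0, fn=0, tn=1)


class TestWaldCI:
    @pytest.mark.parametrize("beta,se,or_exp,lo_exp,hi_exp", [
        (2.167, 0.583, 8.73, 2.787, 27.348),   # beta2-microglobulin row
        (1.517, 0.542, 4.56, 1.575, 13.205),   # ECOG row
        (2.485, 0.809, 12.0, 2.456, 58.631),   # model B medium/high row
    ])
    def test_published_rows_reproduce(self, beta, se, or_exp, lo_exp, hi_exp):
        or_, lo, hi = wald_ci(beta, se)
        assert or_ == pytest.approx(or_exp, rel=5e-3)
        assert lo == pytest.approx(lo_exp, rel=5e-3)
        assert hi == pytest.approx(hi_exp, rel=5e-3)

    def test_zero_beta_symmetric_about_one(self):
        or_, lo, hi = wald_ci(0.0, 0.7)
        assert or_ == 1.0
        assert lo * hi == pytest.approx(1.0)

    @given(beta=st.floats(-3, 3), se=st.floats(0.05, 2))
    @settings(derandomize=True, max_examples=50)
    def test_sign_flip_inverts(self, beta, se):
        or_, lo, hi = wald_ci(beta, se)
        or_m, lo_m, hi_m = wald_ci(-beta, se)
        assert or_m == pytest.approx(1 / or_, rel=1e-9)
        assert lo_m == pytest.approx(1 / hi, rel=1e-9)

    def test_nonpositive_se_rejected(self):
        with pytest.raises(ValueError):
            wald_ci(1.0, 0.0)


class TestFitLogistic:
    def test_single_binary_factor_matches_2x2_closed_form(self):
        rng = np.random.default_rng(3)
        n = 400
        import pandas as pd
        x = (rng.random(n) < 0.4).astype(int)
        y = (rng.random(n) < np.where(x == 1, 0.6, 0.3)).astype(int)
        row = fit_logistic(pd.DataFrame({"x": x, "y": y}), "y", ["x"])["x"]
        a = np.sum((x == 1) & (y == 1)); b = np.sum((x == 1) & (y == 0))
        c = np.sum((x == 0) & (y == 1)); d = np.sum((x == 0) & (y == 0))
        assert row.beta == pytest.approx(math.log(a * d / (b * c)), rel=1e-6)
        se_closed = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
        assert row.se == pytest.approx(se_closed, rel=1e-6)

    def test_null_factor_has_small_effect(self):
        rng = np.random.default_rng(4)
        import pandas as pd
        n = 4000
        df = pd.DataFrame({"x": (rng.random(n) < 0.5).astype(int),
                           "y": (rng.random(n) < 0.5).astype(int)})
        row = fit_logistic(df, "y", ["x"])["x"]
        assert abs(row.beta) < 3 * row.se

    def test_generating_coefficient_recovered(self, large_cohort):
        from pod12risk.synthetic import DEFAULT_LOG_ODDS
        fit = fit_logistic(large_cohort, "pod12", list(DEFAULT_LOG_ODDS),
                           joint=True)
        row = fit["b2mg"]
        assert abs(row.beta - 2.615) <= 2 * row.se

    def test_perfect_separation_is_flagged(self):
        import pandas as pd
        df = pd.DataFrame({"x": [0, 0, 0, 1, 1, 1] * 5,
                           "y": [0, 0, 0, 1, 1, 1] * 5})
        with pytest.warns(UserWarning, match="separation"):
            fit = fit_logistic(df, "y", ["x"])
        assert fit["x"].separated


class TestProportionPower:
    def test_null_equals_alternative_gives_alpha(self):
        assert proportion_power(63, 0.26, 0.26) == pytest.approx(0.05, abs=1e-9)

    def test_power_tends_to_one(self):
        assert proportion_power(10 ** 6, 0.46, 0.26) > 0.9999

    def test_against_exact_binomial_enumeration(self):
        n, p0, p1 = 63, 0.26, 0.46
        z = 1.959963984540054
        se0 = math.sqrt(p0 * (1 - p0) / n)
        ks = np.arange(n + 1)
        reject = np.abs((ks / n - p0) / se0) > z
        exact = binom.pmf(ks, n, p1)[reject].sum()
        approx = proportion_power(n, p1, p0)
        assert approx == pytest.approx(exact, abs=0.03)  # discreteness slack

    def test_invalid_proportions_rejected(self):
        with pytest.raises(ValueError):
            proportion_power(63, 0.0, 0.26)
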