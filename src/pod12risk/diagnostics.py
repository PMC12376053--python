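"""Cut-off selection, 2x2 diagnostics, logistic regression and power.

The arithmetic backbone of the cohort half of the pipeline: Youden-index
cut-off selection on a continuous marker, diagnostic summaries of a 2x2
high-risk x POD12 table, Wald confidence intervals on log-odds scale, and
maximum-likelihood logistic fits (optionally adjusted for the first-line
treatment covariate).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import norm

Z95 = 1.959963984540054  # normal 97.5% quantile; tables use 1.96


class SeparationWarning(UserWarning):
    """Raised when a logistic fit shows (quasi-)complete separation."""


@dataclass(frozen=True)
class ConfusionTable:
    """2x2 counts: prediction = high-risk (rows) vs outcome = POD12."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        counts = (self.tp, self.fp, self.fn, self.tn)
        if any(c < 0 for c in counts):
            raise ValueError("confusion counts must be nonnegative")
        if sum(counts) < 1:
            raise ValueError("confusion table must contain at least one count")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @classmethod
    def from_predictions(cls, pred, outcome) -> "ConfusionTable":
        pred = np.asarray(pred, dtype=bool)
        outcome = np.asarray(outcome, dtype=bool)
        if pred.shape != outcome.shape:
            raise ValueError("prediction and outcome must have the same length")
        return cls(
            tp=int(np.sum(pred & outcome)),
            fp=int(np.sum(pred & ~outcome)),
            fn=int(np.sum(~pred & outcome)),
            tn=int(np.sum(~pred & ~outcome)),
        )


@dataclass(frozen=True)
class DiagnosticSummary:
    sensitivity: float
    specificity: float
    ppv: float
    npv: float
    accuracy: float
    positive_lr: float
    odds_ratio: float
    ci_low: float
    ci_high: float
    z_quantile: float = 1.96
    or_defined: bool = True

    def as_dict(self) -> dict:
        return {k: getattr(self, k) for k in (
            "sensitivity", "specificity", "ppv", "npv", "accuracy",
            "positive_lr", "odds_ratio", "ci_low", "ci_high", "or_defined")}


@dataclass(frozen=True)
class CutoffResult:
    variable: str
    cutoff: float
    sensitivity: float
    specificity: float
    youden_j: float


@dataclass
class LogisticRow:
    factor: str
    beta: float
    se: float
    wald: float
    odds_ratio: float
    ci_low: float
    ci_high: float
    p_value: float
    converged: bool = True
    separated: bool = False


@dataclass
class LogisticFit:
    rows: list[LogisticRow] = field(default_factory=list)

    def __getitem__(self, factor: str) -> LogisticRow:
        for row in self.rows:
            if row.factor == factor:
                return row
        raise KeyError(factor)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"factor": r.factor, "beta": r.beta, "SE": r.se, "Wald": r.wald,
              "OR": r.odds_ratio, "ci_low": r.ci_low, "ci_high": r.ci_high,
              "p_value": r.p_value, "separated": r.separated}
             for r in self.rows]
        )


def youden_cutoff(values, labels, variable: str = "") -> CutoffResult:
    """Pick the threshold maximizing Youden's J = sensitivity + specificity - 1.

    Candidate thresholds are midpoints between sorted distinct values and
    prediction is ``value >= threshold`` (matching the ">=" factor coding of
    the clinical cut-offs). Ties are broken toward the smaller threshold.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if values.shape != labels.shape or values.size < 2:
        raise ValueError("values and labels must be equal-length series of size >= 2")
    pos = labels == 1
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both label classes must be present; ROC is undefined")

    distinct = np.unique(values)
    if distinct.size < 2:
        raise ValueError("values are constant; no candidate cutoff exists")
    candidates = (distinct[:-1] + distinct[1:]) / 2.0

    best = None
    for cut in candidates:  # ascending, so ties keep the smaller threshold
        pred = values >= cut
        sens = np.sum(pred & pos) / n_pos
        spec = np.sum(~pred & ~pos) / n_neg
        j = sens + spec - 1.0
        if best is None or j > best[0] + 1e-12:
            best = (j, cut, sens, spec)
    j, cut, sens, spec = best
    return CutoffResult(variable=variable, cutoff=float(cut),
                        sensitivity=float(sens), specificity=float(spec),
                        youden_j=float(j))


def confusion_metrics(t: ConfusionTable, z_quantile: float = 1.96) -> DiagnosticSummary:
    """Diagnostic summary of a 2x2 table.

    OR and its Wald CI are computed from the cross product with
    SE = sqrt(1/tp + 1/fp + 1/fn + 1/tn); a zero cell leaves them flagged
    undefined (no continuity correction).
    """
    tp, fp, fn, tn = t.tp, t.fp, t.fn, t.tn
    sens = tp / (tp + fn) if tp + fn else float("nan")
    spec = tn / (tn + fp) if tn + fp else float("nan")
    ppv = tp / (tp + fp) if tp + fp else float("nan")
    npv = tn / (tn + fn) if tn + fn else float("nan")
    acc = (tp + tn) / t.total
    plr = sens / (1.0 - spec) if spec < 1.0 else float("inf")

    if min(tp, fp, fn, tn) > 0:
        or_ = tp * tn / (fp * fn)
        se = math.sqrt(1 / tp + 1 / fp + 1 / fn + 1 / tn)
        lo = math.exp(math.log(or_) - z_quantile * se)
        hi = math.exp(math.log(or_) + z_quantile * se)
        defined = True
    else:
        or_ = lo = hi = float("nan")
        defined = False
    return DiagnosticSummary(sensitivity=float(sens), specificity=float(spec),
                             ppv=float(ppv), npv=float(npv), accuracy=float(acc),
                             positive_lr=float(plr), odds_ratio=float(or_),
                             ci_low=float(lo), ci_high=float(hi),
                             z_quantile=z_quantile, or_defined=defined)


def _exp(x: float) -> float:
    return math.exp(x) if x < 700 else float("inf")


def wald_ci(beta: float, se: float, z_quantile: float = 1.96):
    """OR = exp(beta) with 95% Wald bounds exp(beta -/+ z*se)."""
    if se <= 0:
        raise ValueError("standard error must be positive")
    return _exp(beta), _exp(beta - z_quantile * se), _exp(beta + z_quantile * se)


def _fit_one(X: pd.DataFrame, y: np.ndarray):
    """Logit MLE via IRLS (statsmodels); returns (params, bse, converged)."""
    model = sm.Logit(y, X)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = model.fit(disp=0, maxiter=100)
            return res.params, res.bse, bool(res.mle_retvals.get("converged", True))
        except Exception:
            # Newton step fails under (quasi-)separation; BFGS still returns
            # reportable (if unstable) coefficients
            res = model.fit(disp=0, maxiter=500, method="bfgs")
            return res.params, res.bse, False


def _is_separated(x: np.ndarray, y: np.ndarray) -> bool:
    """A binary factor perfectly separates the outcome if a 2x2 cell is empty."""
    vals = np.unique(x)
    if vals.size > 2:
        return False
    for v in vals:
        sub = y[x == v]
        if sub.size and (sub.min() == sub.max()):
            return True
    return False


def fit_logistic(cohort: pd.DataFrame, outcome: str, factors,
                 adjust_for=None, z_quantile: float = 1.96,
                 joint: bool = False) -> LogisticFit:
    """Logistic regression rows in the "beta SE Wald OR CI p" table layout.

    With ``joint=False`` (default) each factor is fitted in its own model
    together with the adjustment covariates — the "adjusted univariate"
    design used for the treatment-corrected screens. With ``joint=True`` all
    factors enter a single multivariable model.
    """
    factors = list(factors)
    adjust_for = list(adjust_for) if adjust_for else []
    y = np.asarray(cohort[outcome], dtype=float)
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValueError("outcome must be binary 0/1")
    if y.min() == y.max():
        raise ValueError("outcome must contain both classes")

    fit = LogisticFit()
    groups = [factors] if joint else [[f] for f in factors]
    for group in groups:
        cols = group + [a for a in adjust_for if a not in group]
        X = sm.add_constant(cohort[cols].astype(float), has_constant="add")
        sep = any(_is_separated(np.asarray(cohort[f], dtype=float), y) for f in group)
        if sep:
            warnings.warn(
                f"perfect separation detected for {group}; coefficients unreliable",
                SeparationWarning, stacklevel=2)
        params, bse, converged = _fit_one(X, y)
        for f in group:
            b, se = float(params[f]), float(bse[f])
            wald = (b / se) ** 2 if se > 0 else float("inf")
            or_, lo, hi = (_exp(b),
                           _exp(b - z_quantile * se) if se > 0 else float("nan"),
                           _exp(b + z_quantile * se) if se > 0 else float("nan"))
            p = 2 * (1 - norm.cdf(abs(b / se))) if se > 0 else 0.0
            fit.rows.append(LogisticRow(factor=f, beta=b, se=se, wald=wald,
                                        odds_ratio=or_, ci_low=lo, ci_high=hi,
                                        p_value=float(p), converged=converged,
                                        separated=sep))
    return fit


def proportion_power(n: int, p_alt: float, p_null: float,
                     alpha: float = 0.05, sided: int = 2) -> float:
    """Power of the one-sample proportion z-test (normal approximation).

    The test statistic uses the null SE sqrt(p0*q0/n); power integrates the
    rejection region under the alternative SE sqrt(p1*q1/n). Two-sided power
    sums both tails.
    """
    if not (0 < p_null < 1 and 0 < p_alt < 1):
        raise ValueError("proportions must lie strictly inside (0, 1)")
    if n < 1:
        raise ValueError("n must be >= 1")
    z = norm.ppf(1 - alpha / sided)
    se0 = math.sqrt(p_null * (1 - p_null) / n)
    se1 = math.sqrt(p_alt * (1 - p_alt) / n)
    delta = p_alt - p_null
    upper = norm.cdf((delta - z * se0) / se1)
    lower = norm.cdf((-delta - z * se0) / se1)
    return float(upper + lower) if sided == 2 else float(norm.cdf((abs(delta) - z * se0) / se1))
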