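"""Synthetic cohorts and monitoring series for the POD12 pipeline.

The study's 63-patient DLBCL dataset is private, so every downstream stage is
exercised on simulated data with the same statistical structure: a cohort of
dichotomized risk factors driving POD12 through a logistic model (with the
published multivariable coefficients as generating truth and the intercept
calibrated so the marginal incidence is ~46%), and multivariate monitoring
panels with known chaotic/periodic dynamics, noise and missingness.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.stats import lognorm, norm

# Dichotomized risk-factor prevalences in the study cohort (n = 63).
# Blood-index prevalences (nlr/sii/plr/lmr) are implied by the printed
# (sensitivity, specificity) pairs at the optimal cut-offs and the 29/34
# POD12 split.
DEFAULT_PREVALENCE: dict[str, float] = {
    "sex_male": 29 / 63,
    "age_ge60": 0.698,
    "stage": 0.714,          # Ann Arbor III-IV
    "b_symptom": 0.254,
    "ecog": 0.460,           # ECOG >= 2
    "extranodal_ge2": 0.381,
    "bulky": 0.190,
    "b2mg": 0.492,           # beta2-microglobulin >= 3 umol/L
    "ldh": 0.476,            # LDH >= 250 IU/L
    "albumin_ge40": 0.206,
    "ast_high": 0.079,
    "non_gcb": 0.667,
    "rituximab": 0.841,      # first-line rituximab + chemo
    "nlr": 19 / 63,          # NLR >= 1.73
    "sii": 17 / 63,          # SII >= 304.2
    "plr": 47 / 63,          # PLR >= 306.494
    "lmr": 45 / 63,          # LMR >= 4.867
}

# Multivariable logistic coefficients for the six model-A factors, used as
# the generating truth of the default cohort.
DEFAULT_LOG_ODDS: dict[str, float] = {
    "ldh": 0.251,
    "b2mg": 2.615,
    "stage": 0.991,
    "ecog": 2.299,
    "nlr": 0.408,
    "sii": 1.371,
}

DEFAULT_INCIDENCE = 0.46  # marginal POD12 incidence in the study cohort

CANONICAL_FACTORS = frozenset(DEFAULT_PREVALENCE)

# Optimal cut-offs of the blood-count indices; continuous labs are generated
# as log-normals consistent with the binary flags so cut-off selection can be
# exercised end to end.  (name -> (cutoff, log-scale sd))
LAB_CUTOFFS: dict[str, tuple[float, float]] = {
    "nlr": (1.73, 0.55),
    "sii": (304.2, 0.80),
    "plr": (306.494, 0.50),
    "lmr": (4.867, 0.45),
}

SERIES_VARIABLES = ("LDH", "B2MG", "STAGE", "ECOG", "NLR", "SII")


@dataclass(frozen=True)
class CohortSpec:
    n: int = 63
    prevalence: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_PREVALENCE))
    log_odds: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_LOG_ODDS))
    intercept: float | None = None  # None -> calibrate to target_incidence
    target_incidence: float = DEFAULT_INCIDENCE
    correlation: float = 0.0  # Gaussian-copula common correlation, off by default
    continuous_labs: bool = True
    seed: int = 0

    def validate(self) -> None:
        if self.n < 1:
            raise ValueError("cohort size must be >= 1")
        unknown = set(self.prevalence) - CANONICAL_FACTORS
        if unknown:
            raise ValueError(f"unknown factor name(s): {sorted(unknown)}")
        for name, p in self.prevalence.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"prevalence of {name} outside [0, 1]")
        missing = set(self.log_odds) - set(self.prevalence)
        if missing:
            raise ValueError(f"log_odds name(s) without a prevalence: {sorted(missing)}")
        if not -1.0 < self.correlation < 1.0:
            raise ValueError("copula correlation must be in (-1, 1)")


@dataclass(frozen=True)
class SeriesSpec:
    system: str = "lorenz"
    n_points: int = 1000
    noise_sd: float = 0.0
    missing_rate: float = 0.0
    variables: tuple[str, ...] = SERIES_VARIABLES
    seed: int = 0
    # system-specific knobs
    period: int = 50          # sine: samples per period
    offset: float = 2.0       # sine: positive baseline so relative errors are defined
    r: float = 3.9            # logistic map growth rate
    dt: float = 0.01          # lorenz integration step
    constant_value: float = 1.0

    def validate(self) -> None:
        if self.system not in {"lorenz", "mackey_glass", "logistic_map", "sine", "constant"}:
            raise ValueError(f"unknown system {self.system!r}")
        if self.system in {"lorenz", "mackey_glass", "logistic_map"} and self.n_points < 50:
            raise ValueError("chaotic systems need n_points >= 50")
        if self.n_points < 2:
            raise ValueError("n_points must be >= 2")
        if not 0.0 <= self.missing_rate < 0.5:
            raise ValueError("missing_rate must be in [0, 0.5)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")


@dataclass
class SeriesPanel:
    """Multivariate monitoring panel: values (N x I) with a missing mask."""

    values: pd.DataFrame          # NaN where missing
    mask: pd.DataFrame            # True where observed
    time_step: str = "1h"         # opaque metadata

    def __post_init__(self) -> None:
        if self.values.shape != self.mask.shape:
            raise ValueError("mask must have the same shape as values")
        if len(self.values) < 2:
            raise ValueError("panel needs at least two time points")

    @property
    def variables(self) -> list[str]:
        return list(self.values.columns)

    def to_long(self) -> pd.DataFrame:
        long = self.values.reset_index(names="time").melt(
            id_vars="time", var_name="variable", value_name="value")
        return long.sort_values(["variable", "time"], ignore_index=True)

    @classmethod
    def from_long(cls, long: pd.DataFrame) -> "SeriesPanel":
        wide = long.pivot(index="time", columns="variable", values="value").sort_index()
        wide.columns.name = None
        wide.index.name = None
        return cls(values=wide, mask=wide.notna())


def _expected_incidence(intercept: float, prevalence, log_odds) -> float:
    """Exact E[sigmoid] over independent binary factors (enumeration)."""
    names = list(log_odds)
    total = 0.0
    for bits in range(2 ** len(names)):
        prob, eta = 1.0, intercept
        for j, name in enumerate(names):
            on = (bits >> j) & 1
            p = prevalence[name]
            prob *= p if on else (1.0 - p)
            eta += log_odds[name] * on
        total += prob / (1.0 + math.exp(-eta))
    return total


def calibrate_intercept(prevalence, log_odds, target: float = DEFAULT_INCIDENCE) -> float:
    """Bisection for the intercept hitting the target marginal incidence."""
    f = lambda b0: _expected_incidence(b0, prevalence, log_odds) - target
    return brentq(f, -30.0, 30.0, xtol=1e-10)


def _sample_flags(rng: np.random.Generator, spec: CohortSpec) -> pd.DataFrame:
    names = list(spec.prevalence)
    n, k = spec.n, len(names)
    if spec.correlation == 0.0:
        u = rng.random((n, k))
    else:  # Gaussian copula with a single common correlation
        rho = spec.correlation
        cov = np.full((k, k), rho) + np.eye(k) * (1.0 - rho)
        z = rng.multivariate_normal(np.zeros(k), cov, size=n, method="cholesky")
        u = norm.cdf(z)
    flags = (u < np.array([spec.prevalence[f] for f in names])).astype(int)
    return pd.DataFrame(flags, columns=names)


def _lab_value(rng: np.random.Generator, flag: np.ndarray, cutoff: float,
               sigma: float, prevalence: float) -> np.ndarray:
    """Truncated log-normal consistent with the exceedance flag.

    mu is set so P(X >= cutoff) equals the flag prevalence; values are then
    drawn from the conditional distribution above/below the cut-off.
    """
    p = min(max(prevalence, 1e-6), 1 - 1e-6)
    mu = math.log(cutoff) - sigma * norm.ppf(1.0 - p)
    dist = lognorm(s=sigma, scale=math.exp(mu))
    f_cut = dist.cdf(cutoff)
    u = rng.random(flag.size)
    q = np.where(flag == 1, f_cut + u * (1.0 - f_cut), u * f_cut)
    return dist.ppf(np.clip(q, 1e-12, 1 - 1e-12))


def simulate_cohort(spec: CohortSpec | None = None) -> pd.DataFrame:
    """Simulate a patient cohort: dichotomized factors, raw labs, POD12.

    Binary factors are drawn independently (or through an optional Gaussian
    copula) with their prevalences; POD12 follows a logistic model with the
    supplied per-factor log-odds and an intercept calibrated (by default) so
    the expected incidence matches the study's 46%.
    """
    spec = spec or CohortSpec()
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    cohort = _sample_flags(rng, spec)

    intercept = spec.intercept
    if intercept is None:
        intercept = calibrate_intercept(spec.prevalence, spec.log_odds,
                                        spec.target_incidence)
    eta = np.full(spec.n, intercept)
    for name, beta in spec.log_odds.items():
        eta += beta * cohort[name].to_numpy()
    cohort["pod12"] = (rng.random(spec.n) < 1.0 / (1.0 + np.exp(-eta))).astype(int)

    if spec.continuous_labs:
        for name, (cutoff, sigma) in LAB_CUTOFFS.items():
            if name in cohort:
                cohort[f"{name}_value"] = _lab_value(
                    rng, cohort[name].to_numpy(), cutoff, sigma,
                    spec.prevalence[name])
    return cohort


# ---------------------------------------------------------------------------
# monitoring series


def _lorenz(rng: np.random.Generator, n: int, dt: float) -> np.ndarray:
    """RK4-integrated Lorenz x-component, sigma=10 rho=28 beta=8/3."""
    sigma, rho, beta = 10.0, 28.0, 8.0 / 3.0

    def deriv(s):
        x, y, z = s
        return np.array([sigma * (y - x), x * (rho - z) - y, x * y - beta * z])

    s = np.array([1.0, 1.0, 1.0]) + rng.normal(0, 0.5, 3)
    out = np.empty(n)
    for i in range(-1000, n):  # discard transient
        if i >= 0:
            out[i] = s[0]
        k1 = deriv(s)
        k2 = deriv(s + 0.5 * dt * k1)
        k3 = deriv(s + 0.5 * dt * k2)
        k4 = deriv(s + dt * k3)
        s = s + dt / 6.0 * (k1 + 2 * k2 + 2 * k3 + k4)
    return out


def _mackey_glass(rng: np.random.Generator, n: int) -> np.ndarray:
    """Mackey-Glass delay system (beta=0.2, gamma=0.1, n=10, tau=17), dt=0.1,
    sampled every unit time."""
    beta, gamma, power, tau = 0.2, 0.1, 10.0, 17.0
    dt, sample_every = 0.1, 10
    lag = int(tau / dt)
    n_steps = 1000 + n * sample_every
    x = np.empty(n_steps + lag)
    x[:lag] = 1.2 + rng.normal(0, 0.05, lag)
    for i in range(lag, n_steps + lag - 1):
        xd = x[i - lag]
        x[i + 1] = x[i] + dt * (beta * xd / (1.0 + xd ** power) - gamma * x[i])
    series = x[lag + 1000:][::sample_every]
    return series[:n]


def _one_series(rng: np.random.Generator, spec: SeriesSpec) -> np.ndarray:
    n = spec.n_points
    if spec.system == "lorenz":
        return _lorenz(rng, n, spec.dt)
    if spec.system == "mackey_glass":
        return _mackey_glass(rng, n)
    if spec.system == "logistic_map":
        x = rng.uniform(0.2, 0.8)
        out = np.empty(n)
        for i in range(100 + n):  # burn in
            x = spec.r * x * (1.0 - x)
            if i >= 100:
                out[i - 100] = x
        return out
    if spec.system == "sine":
        phase = rng.uniform(0, 2 * np.pi)
        t = np.arange(n)
        return spec.offset + np.sin(2 * np.pi * t / spec.period + phase)
    if spec.system == "constant":
        return np.full(n, spec.constant_value)
    raise ValueError(f"unknown system {spec.system!r}")


def simulate_series(spec: SeriesSpec | None = None) -> SeriesPanel:
    """Simulate a multivariate monitoring panel with known dynamics.

    Each named variable is an independent realisation of the chosen system
    (distinct initial condition/phase), plus optional observation noise and
    missing-completely-at-random gaps.
    """
    spec = spec or SeriesSpec()
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    cols = {}
    for name in spec.variables:
        series = _one_series(rng, spec)
        if spec.noise_sd > 0:
            series = series + rng.normal(0, spec.noise_sd, spec.n_points)
        cols[name] = series
    values = pd.DataFrame(cols)
    mask = pd.DataFrame(True, index=values.index, columns=values.columns)
    if spec.missing_rate > 0:
        holes = rng.random(values.shape) < spec.missing_rate
        mask &= ~holes
        values = values.mask(holes)
    return SeriesPanel(values=values, mask=mask)


def write_cohort_csv(cohort: pd.DataFrame, path) -> None:
    cohort.to_csv(path, index=False)


def read_cohort_csv(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_series_csv(panel: SeriesPanel, path) -> None:
    panel.to_long().to_csv(path, index=False)


def read_series_csv(path) -> SeriesPanel:
    return SeriesPanel.from_long(pd.read_csv(path))
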