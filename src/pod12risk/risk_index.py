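"""Comprehensive POD12 risk index and four-level classification.

Each monitoring variable contributes a single-index risk factor

    W_i(t) = | |x(t)| - x0_bar | / (x_max - x0_bar)

where x0_bar and x_max are the mean and maximum amplitude of the variable
under normal conditions (estimated from a designated reference window).
The composite W_z(t) = sum_i W_i(t) * p_i(t) with nonnegative weights summing
to one maps into four levels: risk, subsidiary risk, subsidiary safe, safe.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .synthetic import SeriesPanel

log = logging.getLogger(__name__)

LEVELS = ("risk", "subsidiary risk", "subsidiary safe", "safe")
DEFAULT_THRESHOLDS = (0.75, 0.5, 0.25)
WEIGHT_TOL = 1e-9


@dataclass
class RiskIndexConfig:
    x0_bar: dict[str, float] = field(default_factory=dict)
    x_max: dict[str, float] = field(default_factory=dict)
    weights: dict[str, float] = field(default_factory=dict)  # empty -> equal
    thresholds: tuple[float, float, float] = DEFAULT_THRESHOLDS

    def validate(self) -> None:
        for name in self.x0_bar:
            if name not in self.x_max:
                raise ValueError(f"x_max missing for {name!r}")
            if self.x_max[name] == self.x0_bar[name]:
                raise ValueError(f"x_max equals x0_bar for {name!r}: "
                                 "single-index risk undefined")
        t1, t2, t3 = self.thresholds
        if not (0 < t3 < t2 < t1 < 1):
            raise ValueError("thresholds must be strictly descending in (0, 1)")
        if self.weights:
            if any(w < 0 for w in self.weights.values()):
                raise ValueError("weights must be nonnegative")
            if abs(sum(self.weights.values()) - 1.0) > WEIGHT_TOL:
                raise ValueError("weights must sum to 1")


@dataclass
class RiskAssessment:
    single: dict[str, float]   # W_i(t), clipped to [0, 1]
    composite: float           # W_z(t)
    level: str


def single_risk(x_t: float, x0_bar: float, x_max: float) -> float:
    """W_i(t) = ||x(t)| - x0_bar| / (x_max - x0_bar), clipped to [0, 1].

    The raw formula is unbounded once |x| exceeds x_max; clipping keeps the
    composite interpretable (logged when it bites).
    """
    denom = x_max - x0_bar
    if denom == 0:
        raise ValueError("x_max must differ from x0_bar")
    w = abs(abs(x_t) - x0_bar) / denom
    if w > 1.0 or w < 0.0:
        log.debug("single risk %.3f clipped into [0, 1]", w)
    return float(np.clip(w, 0.0, 1.0))


def composite_risk(W: dict[str, float], p: dict[str, float] | None = None) -> float:
    """W_z(t) = sum_i W_i(t) * p_i(t); equal weights when p is omitted."""
    if not W:
        raise ValueError("no single-index risks supplied")
    if p is None:
        p = {k: 1.0 / len(W) for k in W}
    if set(p) != set(W):
        raise ValueError("weights and risks must name the same variables")
    if any(v < 0 for v in p.values()):
        raise ValueError("weights must be nonnegative")
    if abs(sum(p.values()) - 1.0) > WEIGHT_TOL:
        raise ValueError("weights must sum to 1")
    return float(sum(W[k] * p[k] for k in W))


def classify_level(w_z: float,
                   thresholds: tuple[float, float, float] = DEFAULT_THRESHOLDS) -> str:
    """Four-level label with '>= threshold' boundaries (defaults .75/.5/.25)."""
    t1, t2, t3 = thresholds
    if not (0 < t3 < t2 < t1 < 1):
        raise ValueError("thresholds must be strictly descending in (0, 1)")
    if w_z >= t1:
        return "risk"
    if w_z >= t2:
        return "subsidiary risk"
    if w_z >= t3:
        return "subsidiary safe"
    return "safe"


def entropy_weights(panel_values: pd.DataFrame) -> dict[str, float]:
    """Extension: entropy-method weights from the observed variability.

    Variables whose (min-max normalised) series carry more information
    entropy get smaller weights; this is an optional alternative to the
    default equal weighting, not part of the published procedure.
    """
    X = panel_values.to_numpy(dtype=float)
    n, k = X.shape
    rng_ = X.max(axis=0) - X.min(axis=0)
    rng_[rng_ == 0] = 1.0
    P = (X - X.min(axis=0)) / rng_
    P = P / np.maximum(P.sum(axis=0), 1e-12)
    with np.errstate(divide="ignore", invalid="ignore"):
        ent = -np.nansum(np.where(P > 0, P * np.log(P), 0.0), axis=0) / np.log(max(n, 2))
    d = 1.0 - ent
    if d.sum() <= 0:
        d = np.ones(k)
    w = d / d.sum()
    return dict(zip(panel_values.columns, map(float, w)))


def reference_stats(panel: SeriesPanel, window: slice | None = None) -> RiskIndexConfig:
    """Estimate x0_bar/x_max per variable from a 'normal' reference window.

    Defaults to the first 90% of the panel (the training portion of the 9:1
    split), using absolute amplitudes as the formula does.
    """
    n = len(panel.values)
    if window is None:
        window = slice(0, max(2, int(n * 0.9)))
    cfg = RiskIndexConfig()
    for col in panel.variables:
        amp = panel.values[col].iloc[window].abs().to_numpy(dtype=float)
        amp = amp[~np.isnan(amp)]
        if amp.size < 2:
            raise ValueError(f"reference window too short for {col!r}")
        cfg.x0_bar[col] = float(amp.mean())
        cfg.x_max[col] = float(amp.max())
        if cfg.x_max[col] == cfg.x0_bar[col]:  # constant reference window
            cfg.x_max[col] += 1.0
            log.warning("constant reference window for %s; widened x_max", col)
    return cfg


def assess(states: dict[str, float], cfg: RiskIndexConfig) -> RiskAssessment:
    """Score one time point's variable states into W_i, W_z and a level."""
    cfg.validate()
    W = {name: single_risk(x, cfg.x0_bar[name], cfg.x_max[name])
         for name, x in states.items()}
    weights = cfg.weights or None
    wz = composite_risk(W, weights)
    return RiskAssessment(single=W, composite=wz,
                          level=classify_level(wz, cfg.thresholds))


def assess_panel(panel: SeriesPanel, cfg: RiskIndexConfig | None = None) -> pd.DataFrame:
    """Per-time-point W_i, W_z and level for a whole (gap-free) panel."""
    cfg = cfg or reference_stats(panel)
    rows = []
    for t, row in panel.values.iterrows():
        a = assess(row.to_dict(), cfg)
        rows.append({"time": t, **{f"W_{k}": v for k, v in a.single.items()},
                     "W_z": a.composite, "level": a.level})
    return pd.DataFrame(rows)
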