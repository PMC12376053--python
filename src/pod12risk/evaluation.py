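"""Forecast-quality metrics: MAPE, MASE, quality bands and model comparison.

MASE here divides the mean absolute forecast error by the mean absolute
deviation of the targets about their own mean — deliberately matching the
definition used in the study, which differs from the conventional
naive-one-step-scaled MASE (available via ``conventional=True``).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

log = logging.getLogger(__name__)

QUALITY_BANDS = ("highly accurate", "good", "reasonable", "weak")


def mape(y, y_hat) -> float:
    """Mean absolute percentage error, in percent.

    Zero targets are excluded (logged), since the relative error is
    undefined there; an all-zero target vector is an error.
    """
    y = np.asarray(y, dtype=float)
    y_hat = np.asarray(y_hat, dtype=float)
    if y.shape != y_hat.shape:
        raise ValueError("y and y_hat must have equal length")
    keep = y != 0
    if not keep.any():
        raise ValueError("MAPE undefined: every target is zero")
    dropped = int((~keep).sum())
    if dropped:
        log.warning("MAPE: excluded %d zero target(s)", dropped)
    return float(np.mean(np.abs((y[keep] - y_hat[keep]) / y[keep])) * 100.0)


def mase(y, y_hat, conventional: bool = False) -> float:
    """Mean absolute scaled error.

    Default denominator: mean absolute deviation of y about its mean.
    ``conventional=True`` scales by the in-sample naive one-step forecast
    error instead (the textbook definition).
    """
    y = np.asarray(y, dtype=float)
    y_hat = np.asarray(y_hat, dtype=float)
    if y.shape != y_hat.shape:
        raise ValueError("y and y_hat must have equal length")
    num = np.mean(np.abs(y - y_hat))
    if conventional:
        if y.size < 2:
            raise ValueError("conventional MASE needs >= 2 targets")
        denom = np.mean(np.abs(np.diff(y)))
    else:
        denom = np.mean(np.abs(y - y.mean()))
    if denom == 0:
        raise ValueError("MASE undefined: constant targets")
    return float(num / denom)


def quality_band(mape_pct: float) -> str:
    """Interpretation scale: <10 highly accurate, [10,20) good,
    [20,50) reasonable, >=50 weak (lower-inclusive boundaries)."""
    if mape_pct < 0:
        raise ValueError("MAPE cannot be negative")
    if mape_pct < 10:
        return "highly accurate"
    if mape_pct < 20:
        return "good"
    if mape_pct < 50:
        return "reasonable"
    return "weak"


@dataclass
class ModelComparison:
    models: list[str]
    mape_values: list[float]
    mase_values: list[float]
    best_model: str
    mape_reduction_pct: float          # (max - min)/max * 100
    mase_ratios: dict[str, float]      # each model's MASE / best model's MASE


def compare_models(reports: dict[str, dict]) -> ModelComparison:
    """Comparison arithmetic over {model: {"mape": .., "mase": ..}} rows.

    Reports the relative reduction of the best model's MAPE against the
    worst, and every model's MASE as a multiple of the best (by MASE).
    """
    if len(reports) < 2:
        raise ValueError("need at least two models to compare")
    models = list(reports)
    mapes = [float(reports[m]["mape"]) for m in models]
    mases = [float(reports[m]["mase"]) for m in models]
    best = models[int(np.argmin(mapes))]
    reduction = (max(mapes) - min(mapes)) / max(mapes) * 100.0 if max(mapes) > 0 else 0.0
    best_mase = min(mases)
    ratios = {m: (v / best_mase if best_mase > 0 else float("nan"))
              for m, v in zip(models, mases)}
    return ModelComparison(models=models, mape_values=mapes, mase_values=mases,
                           best_model=best, mape_reduction_pct=float(reduction),
                           mase_ratios=ratios)
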