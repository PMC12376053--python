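"""Points-based POD12 prediction models and the NCCN-IPI comparator.

Model A assigns 2 points to elevated beta2-microglobulin and 1 point each to
elevated LDH, stage III-IV, ECOG >= 2, NLR >= 1.73 and SII >= 304.2, then
splits patients at a total of 4. Model B stratifies on the two independent
risk factors (ECOG, beta2-MG) into low/medium/high. The NCCN-IPI uses the
published 0-8 point scheme and is dichotomized at >= 4 for comparison.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .diagnostics import (ConfusionTable, DiagnosticSummary, LogisticFit,
                          confusion_metrics, fit_logistic)

MODEL_A_POINTS = {"b2mg": 2, "ldh": 1, "stage": 1, "ecog": 1, "nlr": 1, "sii": 1}
MODEL_A_THRESHOLD = 4


@dataclass(frozen=True)
class ScoreModelSpec:
    points: dict[str, int] = field(default_factory=lambda: dict(MODEL_A_POINTS))
    threshold: int = MODEL_A_THRESHOLD
    name: str = "model_a"

    def validate(self) -> None:
        if any(p < 0 for p in self.points.values()):
            raise ValueError("points must be nonnegative integers")
        if self.threshold > sum(self.points.values()):
            raise ValueError("threshold exceeds the maximum attainable score")


@dataclass(frozen=True)
class RiskStratum:
    label: str  # low | medium | high
    score: int | None = None


def score_model_a(record, spec: ScoreModelSpec | None = None) -> int:
    """Sum of points over positive dichotomized factors (range 0-7 default)."""
    spec = spec or ScoreModelSpec()
    spec.validate()
    total = 0
    for factor, pts in spec.points.items():
        if factor not in record or pd.isna(record[factor]):
            raise KeyError(f"record is missing the dichotomized factor {factor!r}")
        total += pts * int(bool(record[factor]))
    return total


def stratify_a(score: int, threshold: int = MODEL_A_THRESHOLD) -> RiskStratum:
    if score < 0:
        raise ValueError("score must be nonnegative")
    return RiskStratum(label="high" if score >= threshold else "low", score=score)


def stratify_b(ecog_high: bool, b2mg_high: bool) -> RiskStratum:
    """Low/medium/high on the two independent risk factors: both -> high,
    exactly one -> medium, neither -> low."""
    n = int(bool(ecog_high)) + int(bool(b2mg_high))
    return RiskStratum(label=("low", "medium", "high")[n])


# published NCCN-IPI "major extranodal involvement" sites: CNS, liver,
# GI tract, lung, bone marrow
def nccn_ipi(age_years: float, ldh_ratio: float, stage: int,
             extranodal_major: bool, ecog: int) -> tuple[int, str]:
    """Published NCCN-IPI point scheme (0-8) with four risk groups.

    Age 41-60/61-75/>75 scores 1/2/3; LDH ratio >1-3 scores 1, >3 scores 2;
    stage III-IV, major extranodal involvement and ECOG >= 2 score 1 each.
    """
    if not 0 <= ecog <= 5:
        raise ValueError("ECOG performance status must be in 0..5")
    if age_years < 0 or ldh_ratio < 0 or stage not in (1, 2, 3, 4):
        raise ValueError("inputs outside published ranges")
    score = 0
    if age_years > 75:
        score += 3
    elif age_years > 60:
        score += 2
    elif age_years > 40:
        score += 1
    if ldh_ratio > 3:
        score += 2
    elif ldh_ratio > 1:
        score += 1
    if stage >= 3:
        score += 1
    if extranodal_major:
        score += 1
    if ecog >= 2:
        score += 1
    group = ("low" if score <= 1 else
             "low-intermediate" if score <= 3 else
             "high-intermediate" if score <= 5 else "high")
    return score, group


def derive_points_from_fit(fit: LogisticFit) -> dict[str, int]:
    """Extension helper: integer points = round(beta / min positive beta).

    This re-derives a points scheme from a multivariable fit instead of using
    the published assignment; offered for exploration only.
    """
    betas = {r.factor: r.beta for r in fit.rows if r.beta > 0}
    if not betas:
        raise ValueError("no positive coefficients to derive points from")
    base = min(betas.values())
    return {f: max(1, round(b / base)) for f, b in betas.items()}


@dataclass
class ModelEvaluation:
    name: str
    table: ConfusionTable
    metrics: DiagnosticSummary
    or_row: object | None  # LogisticRow for the stratum indicator
    degenerate: bool = False


def _high_indicator(cohort: pd.DataFrame, model: str,
                    spec: ScoreModelSpec | None = None) -> np.ndarray:
    if model == "A":
        spec = spec or ScoreModelSpec()
        scores = cohort.apply(lambda r: score_model_a(r, spec), axis=1)
        return (scores >= spec.threshold).to_numpy().astype(int)
    if model == "B":
        strata = [stratify_b(e, b).label for e, b in
                  zip(cohort["ecog"], cohort["b2mg"])]
        return np.array([s != "low" for s in strata], dtype=int)
    if model == "nccn-ipi":
        return (cohort["nccn_ipi_score"] >= 4).to_numpy().astype(int)
    raise ValueError(f"unknown model {model!r}")


def evaluate_model(cohort: pd.DataFrame, model: str = "A",
                   spec: ScoreModelSpec | None = None,
                   adjust_for=("rituximab",)) -> ModelEvaluation:
    """Confusion metrics + treatment-adjusted logistic OR row for a model's
    high-risk stratum against POD12."""
    if "pod12" not in cohort:
        raise ValueError("cohort must carry a pod12 outcome column")
    high = _high_indicator(cohort, model, spec)
    outcome = cohort["pod12"].to_numpy().astype(int)
    table = ConfusionTable.from_predictions(high.astype(bool), outcome.astype(bool))
    metrics = confusion_metrics(table)

    degenerate = high.min() == high.max()
    or_row = None
    if not degenerate:
        df = cohort.copy()
        df["_high"] = high
        adj = [a for a in adjust_for if a in df.columns]
        or_row = fit_logistic(df, "pod12", ["_high"], adjust_for=adj).rows[0]
    return ModelEvaluation(name=f"model_{model}", table=table, metrics=metrics,
                           or_row=or_row, degenerate=degenerate)
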