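"""The two pipeline halves: cohort scoring and series forecasting/risk.

Every output directory gets a ``manifest.json`` recording the seed, a hash of
the effective configuration and the stage list, so a rerun with the same
manifest is byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cnn_lstm import CNNLSTMForecaster, ForecastConfig, persistence_forecast
from .diagnostics import youden_cutoff
from .evaluation import mape, mase, quality_band
from .grnn import PSOConfig, fit_pso_grnn, predict_future_risk_level
from .phase_space import (embed_panel, impute_before_after_mean, reconstruct,
                          stabilize)
from .risk_index import assess_panel, reference_stats
from .scoring import ScoreModelSpec, evaluate_model, score_model_a, stratify_a
from .synthetic import (CohortSpec, SeriesPanel, SeriesSpec, simulate_cohort,
                        simulate_series)

log = logging.getLogger(__name__)


def _config_hash(obj) -> str:
    return hashlib.sha256(json.dumps(obj, sort_keys=True, default=str)
                          .encode()).hexdigest()[:16]


def _write_manifest(outdir: Path, seed: int, config: dict, stages: list[str]) -> None:
    manifest = {
        "seed": seed,
        "config_hash": _config_hash(config),
        "config": config,
        "stages": stages,
        "version": __version__,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))


def _dump_json(path: Path, obj) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True, default=float))


@dataclass
class ScorePipelineConfig:
    cohort_csv: str | None = None          # None -> simulate the default cohort
    outdir: str = "score_out"
    seed: int = 0
    n: int = 63
    cutoff_variables: tuple[str, ...] = ("nlr", "sii", "plr", "lmr")
    model_spec: ScoreModelSpec = field(default_factory=ScoreModelSpec)


def run_score_pipeline(cfg: ScorePipelineConfig) -> dict:
    """Cut-offs -> scores -> strata -> diagnostics for models A and B."""
    t0 = time.time()
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if cfg.cohort_csv:
        cohort = pd.read_csv(cfg.cohort_csv)
    else:
        cohort = simulate_cohort(CohortSpec(n=cfg.n, seed=cfg.seed))

    # Youden cut-offs on the continuous labs, where present
    cut_rows = []
    for var in cfg.cutoff_variables:
        col = f"{var}_value"
        if col in cohort:
            r = youden_cutoff(cohort[col], cohort["pod12"], variable=var)
            cut_rows.append({"variable": var, "cutoff": r.cutoff,
                             "sensitivity": r.sensitivity,
                             "specificity": r.specificity, "youden_j": r.youden_j})
    pd.DataFrame(cut_rows).to_csv(outdir / "cutoffs.csv", index=False)

    scores = cohort.apply(lambda r: score_model_a(r, cfg.model_spec), axis=1)
    strata = scores.map(lambda s: stratify_a(s, cfg.model_spec.threshold).label)
    pd.DataFrame({"score": scores, "stratum": strata,
                  "pod12": cohort["pod12"]}).to_csv(
        outdir / "scores.csv", index=False)

    results = {}
    for model in ("A", "B"):
        ev = evaluate_model(cohort, model, spec=cfg.model_spec)
        entry = {"confusion": {"tp": ev.table.tp, "fp": ev.table.fp,
                               "fn": ev.table.fn, "tn": ev.table.tn},
                 "metrics": ev.metrics.as_dict(), "degenerate": ev.degenerate}
        if ev.or_row is not None:
            entry["or_row"] = {"beta": ev.or_row.beta, "se": ev.or_row.se,
                               "wald": ev.or_row.wald, "or": ev.or_row.odds_ratio,
                               "ci_low": ev.or_row.ci_low,
                               "ci_high": ev.or_row.ci_high,
                               "p_value": ev.or_row.p_value}
        results[f"model_{model}"] = entry
    _dump_json(outdir / "diagnostics.json", results)
    _write_manifest(outdir, cfg.seed,
                    {**asdict(cfg), "model_spec": asdict(cfg.model_spec)},
                    ["cutoffs", "scores", "diagnostics"])
    log.info("score pipeline finished in %.2fs", time.time() - t0)
    return results


@dataclass
class ForecastPipelineConfig:
    series_csv: str | None = None      # None -> simulate the default panel
    outdir: str = "forecast_out"
    seed: int = 0
    series_spec: SeriesSpec = field(default_factory=lambda: SeriesSpec(
        system="sine", n_points=400, missing_rate=0.02))
    forecast: ForecastConfig = field(default_factory=ForecastConfig)
    pso: PSOConfig = field(default_factory=PSOConfig)
    mu: float = 0.85


def run_forecast_pipeline(cfg: ForecastPipelineConfig) -> dict:
    """Pretreat -> embed -> forecast -> risk index -> PSO-GRNN future level."""
    t0 = time.time()
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if cfg.series_csv:
        panel = SeriesPanel.from_long(pd.read_csv(cfg.series_csv))
    else:
        spec = SeriesSpec(**{**asdict(cfg.series_spec), "seed": cfg.seed})
        panel = simulate_series(spec)

    panel = stabilize(impute_before_after_mean(panel), mu=cfg.mu)
    embedding = embed_panel(panel)
    _dump_json(outdir / "embedding.json", embedding.to_jsonable())

    forecasters: dict[str, CNNLSTMForecaster] = {}
    eval_rows = {}
    for name in panel.variables:
        x = panel.values[name].to_numpy(dtype=float)
        psm = reconstruct(x, embedding.m[name], embedding.tau[name],
                          l=cfg.forecast.horizon, variable=name)
        fc = CNNLSTMForecaster(ForecastConfig(
            **{**asdict(cfg.forecast), "seed": cfg.seed}))
        res = fc.fit_matrix(psm)
        forecasters[name] = fc
        X, y = psm.supervised_pairs()
        n_val = res.val_targets.size
        naive = persistence_forecast(X[-n_val:])
        eval_rows[name] = {
            "mape": res.val_mape, "mase": res.val_mase,
            "band": quality_band(res.val_mape),
            "persistence_mape": mape(y[-n_val:], naive),
            "converged": res.converged, "retrains": res.retrains,
        }
    _dump_json(outdir / "forecast_eval.json", eval_rows)

    risk_cfg = reference_stats(panel)
    risk_table = assess_panel(panel, risk_cfg)
    risk_table.to_csv(outdir / "risk.csv", index=False)

    # PSO-GRNN: regress the state vector onto the composite risk value
    X = panel.values.to_numpy(dtype=float)
    y = risk_table["W_z"].to_numpy(dtype=float)
    grnn_fit = fit_pso_grnn(X, y, PSOConfig(**{**asdict(cfg.pso), "seed": cfg.seed}))
    future = predict_future_risk_level(panel, embedding, forecasters,
                                       grnn_fit, risk_cfg)
    out = {
        "embedding": embedding.to_jsonable(),
        "forecast_eval": eval_rows,
        "grnn": {"sigma": grnn_fit.sigma, "cv_fitness": grnn_fit.cv_fitness,
                 "holdout_mse": grnn_fit.holdout_mse,
                 "pso_iterations": grnn_fit.trace.iterations},
        "future_risk": future,
        "current_level": risk_table["level"].iloc[-1],
    }
    _dump_json(outdir / "future_risk.json",
               {k: v for k, v in out.items() if k != "embedding"})
    _write_manifest(outdir, cfg.seed,
                    {"series_spec": asdict(cfg.series_spec),
                     "forecast": asdict(cfg.forecast), "pso": asdict(cfg.pso),
                     "mu": cfg.mu},
                    ["pretreat", "embed", "forecast", "risk", "pso_grnn"])
    log.info("forecast pipeline finished in %.2fs", time.time() - t0)
    return out
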