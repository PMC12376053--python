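"""Full forecasting half: pretreatment to the t+1 POD12 risk level.

Simulates a six-variable monitoring panel with missing values, imputes and
damps them, embeds each variable, trains per-variable CNN-LSTM forecasters,
scores the composite risk index, fits the PSO-GRNN regressor and prints the
chained prediction of the next time point's risk level.
"""

from pod12risk.cnn_lstm import ForecastConfig
from pod12risk.pipeline import ForecastPipelineConfig, run_forecast_pipeline
from pod12risk.synthetic import SeriesSpec

cfg = ForecastPipelineConfig(
    seed=11, outdir="scratch_example_out",
    series_spec=SeriesSpec(system="sine", n_points=300, missing_rate=0.02),
    forecast=ForecastConfig(epochs=60, max_retrains=1),
)
report = run_forecast_pipeline(cfg)

print("per-variable embedding (tau, m):")
for name in report["embedding"]["tau"]:
    print(f"  {name}: tau={report['embedding']['tau'][name]}, "
          f"m={report['embedding']['m'][name]}")
print("forecast quality:",
      {k: v["band"] for k, v in report["forecast_eval"].items()})
print(f"PSO-selected GRNN smoothing factor: {report['grnn']['sigma']:.4f} "
      f"(CV fitness {report['grnn']['cv_fitness']:.5f})")
fr = report["future_risk"]
print(f"current level: {report['current_level']}")
print(f"t+1 composite risk {fr['composite_risk']:.3f} -> level: {fr['level']}")
# The four levels (risk / subsidiary risk / subsidiary safe / safe) rank the
# predicted next state of the monitoring panel on the composite index scale.
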