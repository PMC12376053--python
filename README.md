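# pod12risk

Risk scoring and risk-level forecasting for early progression of diffuse
large B-cell lymphoma (DLBCL).

About half of DLBCL patients who progress do so within twelve months of
diagnosis (POD12), and those patients respond poorly to salvage therapy —
so identifying them *before* treatment matters. `pod12risk` implements two
complementary tools for that problem:

1. **A points-based clinical risk score** built from six routinely measured,
   dichotomized factors — β2-microglobulin ≥ 3 µmol/L (2 points), LDH ≥ 250
   IU/L, Ann Arbor stage III–IV, ECOG ≥ 2, NLR ≥ 1.73 and SII ≥ 304.2
   (1 point each) — with patients split into low (< 4) and high (≥ 4) risk.
   The package provides the full validation arithmetic around it: Youden-index
   cut-off selection on ROC candidates, 2×2 diagnostics (sensitivity,
   specificity, PPV, NPV, accuracy, odds ratio with Wald CI), adjusted
   logistic regression in the standard "β, SE, Wald, OR, 95% CI, p" layout,
   the one-sample proportion power computation, a three-level companion model
   on the two independent risk factors (ECOG, β2-MG), and the published
   NCCN-IPI comparator.

2. **A chaos-theory forecasting branch** for multivariate monitoring series
   of the same six characteristic variables: before/after-mean imputation
   with a stability correction (μ = 0.85), delay-coordinate phase-space
   reconstruction — delay τ from the first local minimum of the lag mutual
   information, embedding dimension m from the false-nearest-neighbor
   criterion — a one-step CNN-LSTM forecaster (1-D convolution → max-pooling
   → LSTM with 100 units → scalar head, squared-error loss with an L2 weight
   penalty `‖y−ŷ‖² + λ‖W‖²`, Adam, λ = 0.01), a comprehensive risk index

       W_i(t) = ||x(t)| − x̄₀| / (x_max − x̄₀),    W_z(t) = Σ_i W_i(t) p_i(t)

   mapped onto four levels (risk / subsidiary risk / subsidiary safe / safe),
   and a general regression neural network whose smoothing factor σ is
   selected by particle swarm optimization (10 particles, c₁ = c₂ = 0.2,
   inertia 0.7, stop at 100 iterations or error < 0.001) of the fourfold
   cross-validated MSE. Chaining the forecaster, the risk index and the
   PSO-GRNN yields the predicted risk level at time t+1.

The original patient-level data are private, so the package ships a
first-class synthetic-data module: cohorts with the published factor
prevalences and logistic effect structure (POD12 incidence calibrated to
46%), and monitoring panels with known dynamics (Lorenz, Mackey–Glass,
logistic map, sine, constant), observation noise and missingness — every
stage is testable end to end without any download. Forecast quality is
scored by MAPE (with the <10% / <20% / <50% interpretation bands) and a
MASE variant scaled by the mean absolute deviation about the target mean.

The CNN-LSTM is implemented directly in numpy (analytic gradients,
single-threaded Adam), so training is fast on small monitoring panels and
bit-reproducible under a seed.

## Worked example

```sh
python examples/01_cohort_scoring.py
```

```
simulated POD12 incidence: 38.1%
confusion (high-risk vs POD12): tp=16 fp=12 fn=8 tn=27
sensitivity 0.667  specificity 0.692
PPV 57.14%  NPV 77.14%  accuracy 68.25%
treatment-adjusted OR for high vs low stratum: 4.74 (p=0.00594)
```

A simulated 63-patient cohort lands near the calibrated 46% incidence
(binomial noise at this size); the score's high-risk stratum carries a
significantly elevated POD12 odds ratio after adjusting for the first-line
treatment flag. PPV/NPV say what a high/low score means for an individual
patient.

```sh
python examples/04_cnn_lstm_forecast.py
```

```
validation MAPE: 1.49%  -> band: highly accurate
persistence baseline MAPE: 5.44%
converged: True after 0 retrain(s)
next-step prediction from the last state: 1.8291 (truth 1.8436)
```

On a noiseless periodic monitoring signal the one-step CNN-LSTM sits well
inside the "highly accurate" band (MAPE < 10%) and beats the naive
last-value forecast, i.e. it learned the dynamics rather than copying the
previous observation.

The other examples cover cut-off selection (`02`), phase-space embedding of
a Lorenz-driven variable (`03`), and the full forecast half up to the t+1
risk level (`05`). A thin CLI exposes the same pipelines
(`pod12 --help`; e.g. `pod12 run --half score --seed 1`).

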