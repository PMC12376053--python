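# Methods

This note records the models implemented in `pod12risk`, the defaults that
matter, and the places where the design was genuinely open and a choice had
to be made. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Cohort model and synthetic cohorts

POD12 (progression within 12 months of diagnosis) is modelled as a binary
outcome of dichotomized clinical factors through a logistic model. The
synthetic cohort generator draws each binary factor independently with its
prevalence in the 63-patient study cohort (e.g. age > 60: 69.8%, stage
III–IV: 71.4%, ECOG ≥ 2: 46%, β2-MG ≥ 3: 49.2%, LDH ≥ 250: 47.6%,
rituximab: 84.1%) and draws POD12 from

    logit P(POD12) = β₀ + Σ_f β_f · 1[f]

with the six multivariable coefficients (LDH 0.251, β2-MG 2.615, stage
0.991, ECOG 2.299, NLR 0.408, SII 1.371) as generating truth. The intercept
is calibrated by root-finding on the *exact* expected incidence (enumeration
over the 2⁶ factor combinations) so the marginal POD12 rate is 46%, the
study's observed incidence; only that marginal rate is published, which is
why the intercept is calibrated rather than copied.

Prevalences for the four blood-count indices are not printed directly; they
are implied by the published (sensitivity, specificity) pairs at the optimal
cut-offs together with the 29/34 POD12 split, giving NLR 19/63, SII 17/63,
PLR 47/63, LMR 45/63.

Covariates are independent by default — no correlation structure is
published — with an optional single-parameter Gaussian copula for
sensitivity analyses. Continuous lab values (NLR, SII, PLR, LMR) are
log-normal, with the log-scale mean fixed so the exceedance probability over
the dichotomization threshold equals the flag prevalence, and each draw
conditioned on its flag (truncated above/below the threshold). This makes
cut-off selection exercisable end to end; note that because the generating
effects are the *multivariable* coefficients with independent covariates,
the univariate signal of a weak factor (NLR, β = 0.408) is genuinely weak,
and Youden recovery of its threshold is correspondingly noisy — the SII
threshold (β = 1.371) recovers much more tightly.

What the generator does *not* emulate: factor correlations (β2-MG and stage
are correlated in real cohorts), treatment selection effects, survival
times, and any time-dependence of labs. Tests passing on these cohorts
establish the arithmetic and the estimation machinery, not clinical
transportability.

## Diagnostics

Youden's J = sensitivity + specificity − 1 is maximized over candidate
thresholds at midpoints between sorted distinct values, with "value ≥
threshold" coded positive (matching the "≥" factor coding) and ties broken
toward the smaller threshold. 2×2 summaries use the cross-product odds
ratio with Wald CI on the log scale, SE = √(1/tp + 1/fp + 1/fn + 1/tn),
z = 1.96; zero cells flag the OR undefined rather than applying a
continuity correction (no published table has a zero cell). Logistic
regression is maximum likelihood via statsmodels' IRLS; "adjusted
univariate" fits one factor plus the treatment covariate per model. Perfect
separation is detected from the 2×2 margins, warned about, and the fit
falls back to BFGS so coefficients remain reportable (flagged
non-converged). The one-sample proportion power uses the normal
approximation with the null SE in the test statistic and the alternative SE
in the power integral, two-sided by default; the null proportion is a
required argument because no single convention is universal (0.26
reproduces the study's printed 0.927878 under this formula, which the
acceptance script recomputes).

## Points models

Model A hard-codes the published assignment (β2-MG 2 points, five factors 1
point each, threshold 4 configurable) rather than re-deriving points from
refits; a clearly-labelled helper derives integer points from any fitted
model (round β / min β) as an extension. Model B is the low/medium/high
stratification on ECOG and β2-MG. The NCCN-IPI follows the published 0–8
scheme (age 41–60/61–75/>75 → 1/2/3; LDH ratio >1–3/>3 → 1/2; stage III–IV,
major extranodal site — CNS, liver, GI, lung, marrow — and ECOG ≥ 2 → 1
each) and is dichotomized at ≥ 4 as the comparator.

## Pretreatment and phase-space reconstruction

Missing monitoring values are filled by x_i = (x_{i−1} + x_{i+1})/2.
Runs of consecutive gaps iterate the rule to its fixed point, which equals
linear interpolation across the run; boundary gaps take the nearest
observation. Both situations are logged; the original mask is kept so the
stability correction x → μx (μ = 0.85) can target exactly the imputed
entries. That scope — imputed entries only — is the default reading
(`mu_scope="imputed"`), with `"all"` available since the text supports
either reading.

Delay τ is the first local minimum of the lag mutual information, estimated
from equal-width 2-D histograms with ⌈√N⌉ bins. The histogram MI of a
noise-free deterministic signal is nearly flat in the relevant range (the
joint distribution is a thin curve at every lag), so the local-minimum
search runs on a 3-point moving average of the curve; if no local minimum
exists, τ falls back to the first lag where MI < MI(1)/e, then to 1, both
logged. Embedding dimension m uses the false-nearest-neighbor criterion
with ratio tolerance 15 and a 1% false-neighbor threshold, falling back to
the argmin of the curve when the threshold is never crossed. Exactly
recurrent points (zero neighbor distance) count as true neighbors unless
the added coordinate separates them beyond numerical noise. The trajectory
matrix has m rows and N − (m−1)τ columns (column k is the delay vector
starting at x_k); supervised one-step pairs number N − (m−1)τ − l.
Documentation uses 1-based indices to mirror the standard embedding
notation; code is 0-based half-open.

## CNN-LSTM forecaster

Architecture (smallest consistent with convolution → pooling → flatten →
LSTM): 1-D convolution with 16 channels, kernel 3, same padding, ReLU;
max-pool of size 2 (ceil mode); LSTM with 100 units reading the pooled
sequence — the input sequence length is the embedding dimension m of the
variable being forecast — and a linear scalar head. Loss is
`‖y − ŷ‖² + λ‖W‖²` with λ = 0.01 applied to all link weights (not biases),
minimized by full-batch Adam at learning rate 0.01 for 100 epochs. Inputs
and targets are standardized on the chronological 90% training block; the
last 10% is the validation block (the 9:1 split). If validation MAPE misses
the 10% accuracy gate (the "highly accurate" band) the network is
re-initialized and retrained, bounded at 5 attempts, keeping the best — a
termination guarantee for the train-until-accurate loop. One model is
trained per variable; forward and backward passes are hand-written numpy,
which keeps training single-threaded and bit-reproducible under the
configured seed. Weight init is Glorot-uniform with the forget-gate bias
at 1.

The sine generator default includes a +2 offset: MAPE is undefined at zero
targets and explodes near them, and clinical monitoring variables are
positive, so the periodic test signal is kept away from zero by design.

## Risk index

W_i(t) = ||x(t)| − x̄₀| / (x_max − x̄₀) per variable, where x̄₀ and x_max
are the mean and maximum amplitude under normal conditions — operationalized
as a user-designated reference window, by default the chronological first
90% of the panel. The raw formula is unbounded above once |x| exceeds
x_max; W_i is clipped to [0, 1] so the composite W_z = Σ W_i p_i stays
interpretable (clipping is logged). Weights default to equal (no weighting
method is published); an entropy-weight option is provided as a labelled
extension. The four levels use thresholds 0.75 / 0.5 / 0.25 with
"≥"-inclusive boundaries — arbitrary but fixed and surfaced in config.
Weights are validated to sum to 1 within 1e−9.

## PSO-GRNN

The GRNN is Nadaraya–Watson kernel regression,
ŷ(q) = Σ_j y_j e^{−d_j²/2σ²} / Σ_j e^{−d_j²/2σ²} on Euclidean distances,
with a max-shift in the exponent so the weights cannot all underflow —
hence the σ → 0 limit interpolates the nearest pattern and σ → ∞ returns
the target mean, and every prediction is a convex combination of training
targets. σ is selected by PSO: 10 particles, c₁ = c₂ = 0.2 (the single
published "learning factor" read as the symmetric choice), constant inertia
0.7, stop at 100 iterations or best fitness < 0.001, positions clipped to
[10⁻³, 1] on standardized inputs. The published adaptive-inertia formula
increases with iteration while the text says the inertia decreases; the
package therefore defaults to the constant 0.7 and offers the corrected
decreasing form w = W_max − (W_max − W_min)·tan((I/I_max)·π/4) as the
adaptive option. "Fourfold cross-validation with a 9:1 split" is resolved
as an outer 9:1 holdout plus inner 4-fold CV MSE as the PSO fitness, the
final model refit on the full training portion with σ*. Regression targets
are the numeric composite risk values W_z; the discrete level is assigned
afterwards by the threshold classifier, since no numeric coding of "risk
level" is published. The t+1 chain is: per-variable CNN-LSTM next-state →
risk index on predicted states → GRNN regression on the predicted state
vector → level classification, with full provenance in the output.

## Evaluation

MAPE excludes zero targets with a logged count. MASE is implemented exactly
as defined for this analysis — mean absolute error over mean absolute
deviation about the target mean — which differs from the conventional
naive-forecast-scaled MASE; the conventional denominator is available via a
flag, default off. Interpretation bands are lower-inclusive: < 10 highly
accurate, [10, 20) good, [20, 50) reasonable, ≥ 50 weak. Model comparison
reports (max − min)/max MAPE reduction and each model's MASE as a multiple
of the best model's.

## Problem sizes and numerical choices

Default test problem sizes: 400-point series for forecaster training
(≈ 390 supervised pairs), 1000–5000 points for embedding recovery
(Lorenz integrated by RK4 at dt = 0.01 with a 1000-step transient
discarded; logistic map at r = 3.9 with a 100-step burn-in; Mackey–Glass by
RK4 at dt = 0.1 with τ = 17), cohorts of 63 for study-scale behavior and
2000–5000 for estimation checks, 20 seeds for the coefficient-recovery
sweep. These sizes make every stage's behavior measurable while each test
module runs in seconds on one CPU.

Degenerate inputs are handled explicitly throughout: constant series are
rejected where MI is undefined and assigned m = 1 with a warning in FNN;
degenerate stratifications flag the evaluation instead of fitting;
non-finite PSO fitness rejects the candidate rather than aborting; CNN-LSTM
training raises a divergence error naming the epoch if the loss leaves the
finite range.

## Known limitations

The four-level risk scale has no published outcome linkage, so no clinical
validity is claimed for it. The study's absolute forecast figures (MAPE
9.739, PSO fitness 0.0052, smoothing factors ≈ 0.08) depend on the private
hospital monitoring series and are not reproduction targets; the package
reproduces the machinery, its closed-form arithmetic and its property
guarantees on synthetic data. The monitoring series' physical sampling is
unspecified in the source material; the time step is treated as opaque
metadata.
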