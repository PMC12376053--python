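"""General regression neural network with PSO-selected smoothing factor.

The GRNN is kernel regression: prediction = sum_j y_j K_j / sum_j K_j with
Gaussian kernels K_j = exp(-d_j^2 / (2 sigma^2)) on Euclidean distances to
the training patterns. Its single smoothing factor sigma is chosen by
particle swarm optimization of the cross-validated mean squared error:
velocities follow

    v <- w*v + c1*r1*(p_best - l) + c2*r2*(g_best - l),  l <- l + v

with learning factors c1 = c2 = 0.2, inertia 0.7 (or an adaptive,
decreasing tangent schedule), 10 particles, and a stop rule of 100
iterations or training error below 1e-3. Model selection uses an outer 9:1
holdout with inner fourfold cross-validation on the training portion.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .cnn_lstm import CNNLSTMForecaster
from .phase_space import EmbeddingParams
from .risk_index import RiskAssessment, RiskIndexConfig, assess
from .synthetic import SeriesPanel

log = logging.getLogger(__name__)


@dataclass
class GRNNModel:
    X: np.ndarray        # (n_patterns, d) training inputs
    y: np.ndarray        # (n_patterns,) training targets
    sigma: float
    x_mean: np.ndarray | None = None
    x_scale: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.X = np.atleast_2d(np.asarray(self.X, dtype=float))
        self.y = np.asarray(self.y, dtype=float).ravel()
        if self.sigma <= 0:
            raise ValueError("smoothing factor sigma must be positive")
        if self.X.shape[0] != self.y.size or self.X.shape[0] < 1:
            raise ValueError("need >= 1 training pattern aligned with targets")

    def predict(self, query) -> np.ndarray:
        return grnn_predict(self, query)


def grnn_predict(model: GRNNModel, query) -> np.ndarray:
    """Kernel-weighted mean of training targets (max-shift stabilized).

    The exponent is shifted by its per-query maximum before exponentiation so
    the weights cannot all underflow; as sigma -> 0 the prediction therefore
    converges to the nearest pattern's target, and as sigma -> inf to the
    mean of the targets.
    """
    Q = np.atleast_2d(np.asarray(query, dtype=float))
    if Q.shape[1] != model.X.shape[1]:
        raise ValueError(
            f"query dimension {Q.shape[1]} != pattern dimension {model.X.shape[1]}")
    if model.x_mean is not None:
        Q = (Q - model.x_mean) / model.x_scale
        X = (model.X - model.x_mean) / model.x_scale
    else:
        X = model.X
    d2 = np.sum((Q[:, None, :] - X[None, :, :]) ** 2, axis=2)
    expo = -d2 / (2.0 * model.sigma ** 2)
    expo -= expo.max(axis=1, keepdims=True)
    w = np.exp(expo)
    out = (w @ model.y) / w.sum(axis=1)
    return out if out.size > 1 else np.array([out[0]])


@dataclass(frozen=True)
class PSOConfig:
    n_particles: int = 10
    c1: float = 0.2
    c2: float = 0.2
    inertia: float = 0.7
    adaptive_inertia: bool = False
    w_max: float = 0.9
    w_min: float = 0.4
    max_iter: int = 100
    tolerance: float = 0.0010
    bounds: tuple[float, float] = (1e-3, 1.0)
    seed: int = 0
    cv_folds: int = 4
    holdout_fraction: float = 0.1  # outer 9:1 split

    def validate(self) -> None:
        if self.n_particles < 2:
            raise ValueError("need at least 2 particles")
        lo, hi = self.bounds
        if not (0 < lo < hi < np.inf):
            raise ValueError("bounds must be finite, positive and ordered")
        if self.tolerance <= 0 or self.max_iter < 1:
            raise ValueError("invalid stopping rule")
        if self.cv_folds < 2:
            raise ValueError("need >= 2 CV folds")


@dataclass
class PSOTrace:
    best_fitness: list[float] = field(default_factory=list)
    best_position: list[float] = field(default_factory=list)
    iterations: int = 0
    stopped_by_tolerance: bool = False


def _inertia(cfg: PSOConfig, it: int) -> float:
    if not cfg.adaptive_inertia:
        return cfg.inertia
    # decreasing tangent schedule: w_max at the start, w_min at the last step
    frac = it / max(cfg.max_iter - 1, 1)
    return cfg.w_max - (cfg.w_max - cfg.w_min) * np.tan(frac * np.pi / 4.0)


def pso_minimize(fitness, config: PSOConfig | None = None) -> tuple[float, PSOTrace]:
    """Particle swarm minimization of a scalar function over [lo, hi].

    Positions are clipped to the bounds; non-finite fitness values reject
    the candidate (logged). The best-ever fitness trace is non-increasing by
    construction. Stops after max_iter sweeps or once the global best drops
    below the tolerance.
    """
    cfg = config or PSOConfig()
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    lo, hi = cfg.bounds
    pos = rng.uniform(lo, hi, cfg.n_particles)
    vel = rng.uniform(-(hi - lo), hi - lo, cfg.n_particles) * 0.1

    def safe_fit(x: float) -> float:
        v = float(fitness(float(x)))
        if not np.isfinite(v):
            log.warning("non-finite fitness at sigma=%.4g; candidate rejected", x)
            return np.inf
        return v

    pbest_pos = pos.copy()
    pbest_fit = np.array([safe_fit(x) for x in pos])
    g_idx = int(np.argmin(pbest_fit))
    gbest_pos, gbest_fit = float(pbest_pos[g_idx]), float(pbest_fit[g_idx])

    trace = PSOTrace()
    trace.best_fitness.append(gbest_fit)
    trace.best_position.append(gbest_pos)
    if gbest_fit < cfg.tolerance:
        trace.iterations = 1
        trace.stopped_by_tolerance = True
        return gbest_pos, trace

    for it in range(cfg.max_iter):
        w = _inertia(cfg, it)
        r1 = rng.random(cfg.n_particles)
        r2 = rng.random(cfg.n_particles)
        vel = (w * vel + cfg.c1 * r1 * (pbest_pos - pos)
               + cfg.c2 * r2 * (gbest_pos - pos))
        pos = np.clip(pos + vel, lo, hi)
        fits = np.array([safe_fit(x) for x in pos])
        improved = fits < pbest_fit
        pbest_fit[improved] = fits[improved]
        pbest_pos[improved] = pos[improved]
        g_idx = int(np.argmin(pbest_fit))
        if pbest_fit[g_idx] < gbest_fit:
            gbest_fit, gbest_pos = float(pbest_fit[g_idx]), float(pbest_pos[g_idx])
        trace.best_fitness.append(gbest_fit)
        trace.best_position.append(gbest_pos)
        trace.iterations = it + 1
        if gbest_fit < cfg.tolerance:
            trace.stopped_by_tolerance = True
            break
    return gbest_pos, trace


def _cv_mse(X: np.ndarray, y: np.ndarray, sigma: float, folds: int) -> float:
    n = X.shape[0]
    idx = np.arange(n)
    errs = []
    for f in range(folds):
        test = idx[f::folds]
        train = np.setdiff1d(idx, test)
        if train.size == 0 or test.size == 0:
            raise ValueError("degenerate CV fold")
        model = GRNNModel(X[train], y[train], sigma)
        pred = grnn_predict(model, X[test])
        errs.append(float(np.mean((pred - y[test]) ** 2)))
    return float(np.mean(errs))


@dataclass
class PSOGRNNFit:
    model: GRNNModel
    trace: PSOTrace
    sigma: float
    cv_fitness: float
    holdout_mse: float


def fit_pso_grnn(X, y, config: PSOConfig | None = None) -> PSOGRNNFit:
    """Select sigma by PSO over the fourfold-CV MSE, refit, report holdout MSE.

    Inputs are standardized internally (the sigma search bounds are defined
    on standardized coordinates); the outer 9:1 split is chronological so the
    procedure is deterministic under the seed.
    """
    cfg = config or PSOConfig()
    cfg.validate()
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    if X.shape[0] != y.size or X.shape[0] < 8:
        raise ValueError("need >= 8 aligned samples")
    n_hold = max(1, int(round(X.shape[0] * cfg.holdout_fraction)))
    Xtr, Xho = X[:-n_hold], X[-n_hold:]
    ytr, yho = y[:-n_hold], y[-n_hold:]

    x_mean = Xtr.mean(axis=0)
    x_scale = np.maximum(Xtr.std(axis=0), 1e-12)
    Xs = (Xtr - x_mean) / x_scale

    fitness = lambda s: _cv_mse(Xs, ytr, s, cfg.cv_folds)
    sigma, trace = pso_minimize(fitness, cfg)
    model = GRNNModel(Xtr, ytr, sigma, x_mean=x_mean, x_scale=x_scale)
    holdout = float(np.mean((grnn_predict(model, Xho) - yho) ** 2))
    return PSOGRNNFit(model=model, trace=trace, sigma=float(sigma),
                      cv_fitness=float(trace.best_fitness[-1]), holdout_mse=holdout)


def predict_future_risk_level(panel: SeriesPanel, embedding: EmbeddingParams,
                              forecasters: dict[str, CNNLSTMForecaster],
                              grnn_fit: PSOGRNNFit,
                              risk_cfg: RiskIndexConfig) -> dict:
    """Chain forecast -> risk index -> GRNN regression for time t+1.

    Each variable's next state comes from its trained one-step forecaster fed
    with the latest delay vector; the predicted states are scored into W_i
    and W_z, the GRNN regresses the predicted state vector onto the risk
    value, and the final label is the four-level classification of the GRNN
    output. The full provenance is returned.
    """
    states = {}
    for name in panel.variables:
        x = panel.values[name].to_numpy(dtype=float)
        tau, m = embedding.tau[name], embedding.m[name]
        state = x[-1 - (m - 1) * tau::tau] if m > 1 else x[-1:]
        states[name] = forecasters[name].predict_next(state)
    direct: RiskAssessment = assess(states, risk_cfg)
    query = np.array([[states[n] for n in panel.variables]])
    regressed = float(grnn_predict(grnn_fit.model, query)[0])
    from .risk_index import classify_level
    return {
        "predicted_states": states,
        "single_risks": direct.single,
        "composite_risk": direct.composite,
        "direct_level": direct.level,
        "grnn_risk_value": regressed,
        "level": classify_level(float(np.clip(regressed, 0.0, 1.0)),
                                risk_cfg.thresholds),
    }
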