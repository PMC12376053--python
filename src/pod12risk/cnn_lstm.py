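"""One-step CNN-LSTM forecaster for delay-embedded monitoring series.

The network mirrors the hybrid used for the POD12 characteristic variables:
a 1-D convolution extracts spatial features of each reconstructed phase-space
point, max-pooling selects the salient ones, and an LSTM (100 units) models
the temporal evolution, followed by a scalar head. The training objective is
squared error plus an L2 weight penalty, loss = ||y - y_hat||^2 + lambda*||W||^2,
minimized with Adam. The LSTM's input sequence length equals the embedding
dimension m of the variable being forecast.

Implemented directly in numpy (forward + analytic backward) so training is
single-threaded and bit-reproducible under a seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .evaluation import mape, mase
from .phase_space import PhaseSpaceMatrix


@dataclass(frozen=True)
class ForecastConfig:
    conv_channels: int = 16
    kernel_size: int = 3
    pool_size: int = 2
    lstm_units: int = 100
    l2_lambda: float = 0.01
    learning_rate: float = 0.01
    epochs: int = 100
    horizon: int = 1
    accuracy_threshold: float = 10.0  # validation MAPE (%) gate of the retrain loop
    max_retrains: int = 5
    val_fraction: float = 0.1         # 9:1 chronological train/test split
    seed: int = 0

    def validate(self) -> None:
        ints = (self.conv_channels, self.kernel_size, self.pool_size,
                self.lstm_units, self.epochs, self.horizon, self.max_retrains)
        if any(v < 1 for v in ints):
            raise ValueError("architecture/training integers must be positive")
        if self.kernel_size % 2 == 0:
            raise ValueError("kernel_size must be odd (same padding)")
        if not (self.l2_lambda >= 0 and self.learning_rate > 0):
            raise ValueError("invalid l2_lambda or learning_rate")
        if not 0.0 < self.val_fraction < 0.5:
            raise ValueError("val_fraction must be in (0, 0.5)")


@dataclass
class ForecastResult:
    val_predictions: np.ndarray
    val_targets: np.ndarray
    loss_history: np.ndarray
    val_mape: float
    val_mase: float
    converged: bool
    retrains: int


class _Params(dict):
    """Named parameter set with elementwise helpers for Adam."""

    def zeros_like(self):
        return _Params({k: np.zeros_like(v) for k, v in self.items()})


def _init_params(cfg: ForecastConfig, rng: np.random.Generator) -> _Params:
    C, K, H = cfg.conv_channels, cfg.kernel_size, cfg.lstm_units

    def glorot(*shape):
        fan = sum(shape)
        lim = math.sqrt(6.0 / fan)
        return rng.uniform(-lim, lim, shape)

    p = _Params()
    p["Wc"] = glorot(C, K)
    p["bc"] = np.zeros(C)
    p["Wl"] = glorot(4 * H, C + H) * 0.5
    p["bl"] = np.zeros(4 * H)
    p["bl"][H:2 * H] = 1.0  # forget-gate bias init
    p["wo"] = glorot(H, 1)[:, 0]
    p["bo"] = np.zeros(1)
    return p


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-np.clip(x, -60, 60)))


def _forward(p: _Params, X: np.ndarray, cfg: ForecastConfig):
    """X: (B, T) standardized sequences. Returns (y_hat, cache)."""
    B, T = X.shape
    C, K, P, H = cfg.conv_channels, cfg.kernel_size, cfg.pool_size, cfg.lstm_units
    pad = (K - 1) // 2
    Xp = np.pad(X, ((0, 0), (pad, pad)))
    # convolution: pre[b,t,c] = sum_k Wc[c,k] * Xp[b,t+k] + bc[c]
    windows = np.stack([Xp[:, t:t + K] for t in range(T)], axis=1)  # (B,T,K)
    pre = windows @ p["Wc"].T + p["bc"]                             # (B,T,C)
    act = np.maximum(pre, 0.0)
    # max pool (ceil mode)
    S = -(-T // P)
    pooled = np.empty((B, S, C))
    argmax = np.empty((B, S, C), dtype=np.intp)
    for s in range(S):
        seg = act[:, s * P: min((s + 1) * P, T), :]
        idx = seg.argmax(axis=1)
        argmax[:, s, :] = idx + s * P
        pooled[:, s, :] = np.take_along_axis(seg, idx[:, None, :], axis=1)[:, 0, :]
    # LSTM over the pooled sequence
    h = np.zeros((B, H))
    c = np.zeros((B, H))
    steps = []
    for s in range(S):
        z = np.concatenate([pooled[:, s, :], h], axis=1)      # (B, C+H)
        gates = z @ p["Wl"].T + p["bl"]                       # (B, 4H)
        i = _sigmoid(gates[:, :H])
        f = _sigmoid(gates[:, H:2 * H])
        g = np.tanh(gates[:, 2 * H:3 * H])
        o = _sigmoid(gates[:, 3 * H:])
        c_prev = c
        c = f * c_prev + i * g
        tc = np.tanh(c)
        h = o * tc
        steps.append((z, i, f, g, o, c_prev, c, tc))
    y_hat = h @ p["wo"] + p["bo"][0]
    cache = (X, windows, pre, act, pooled, argmax, steps, h)
    return y_hat, cache


def _backward(p: _Params, cache, dy: np.ndarray, cfg: ForecastConfig) -> _Params:
    X, windows, pre, act, pooled, argmax, steps, h_last = cache
    B, T = X.shape
    C, K, P, H = cfg.conv_channels, cfg.kernel_size, cfg.pool_size, cfg.lstm_units
    S = len(steps)
    g_ = p.zeros_like()

    g_["wo"] = h_last.T @ dy
    g_["bo"] = np.array([dy.sum()])
    dh = dy[:, None] * p["wo"][None, :]
    dc = np.zeros((B, H))
    dpooled = np.zeros_like(pooled)
    for s in range(S - 1, -1, -1):
        z, i, f, g, o, c_prev, c, tc = steps[s]
        do = dh * tc
        dc = dc + dh * o * (1.0 - tc * tc)
        di, df, dg = dc * g, dc * c_prev, dc * i
        dgates = np.concatenate([
            di * i * (1 - i), df * f * (1 - f),
            dg * (1 - g * g), do * o * (1 - o)], axis=1)      # (B,4H)
        g_["Wl"] += dgates.T @ z
        g_["bl"] += dgates.sum(axis=0)
        dz = dgates @ p["Wl"]
        dpooled[:, s, :] = dz[:, :C]
        dh = dz[:, C:]
        dc = dc * f
    # unpool
    dact = np.zeros_like(act)
    b_idx = np.arange(B)[:, None, None]
    c_idx = np.arange(C)[None, None, :]
    np.add.at(dact, (b_idx, argmax, c_idx), dpooled)
    dpre = dact * (pre > 0)
    g_["Wc"] = np.einsum("btc,btk->ck", dpre, windows)
    g_["bc"] = dpre.sum(axis=(0, 1))
    return g_


_WEIGHT_KEYS = ("Wc", "Wl", "wo")  # L2 applies to link weights, not biases


class CNNLSTMForecaster:
    """Trainable one-step forecaster over delay vectors of a single variable."""

    def __init__(self, config: ForecastConfig | None = None):
        self.config = config or ForecastConfig()
        self.config.validate()
        self.params: _Params | None = None
        self.x_mean = self.x_std = self.y_mean = self.y_std = None
        self.result: ForecastResult | None = None

    # -- training -----------------------------------------------------------
    def fit(self, X: np.ndarray, y: np.ndarray) -> ForecastResult:
        """Train on supervised pairs (chronological). X: (n, m), y: (n,).

        A 9:1 chronological split yields the validation block; if validation
        MAPE misses the configured accuracy threshold the network is
        re-initialized and retrained (bounded retries), keeping the best.
        """
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if X.ndim != 2 or X.shape[0] != y.size:
            raise ValueError("X must be (n_pairs, m) aligned with y")
        self._seen_len = X.shape[1]
        if X.shape[0] < 20:
            raise ValueError(f"need >= 20 supervised pairs, got {X.shape[0]}")
        cfg = self.config
        n_val = max(1, int(round(X.shape[0] * cfg.val_fraction)))
        Xtr, Xva = X[:-n_val], X[-n_val:]
        ytr, yva = y[:-n_val], y[-n_val:]

        self.x_mean, self.x_std = Xtr.mean(), max(Xtr.std(), 1e-12)
        self.y_mean, self.y_std = ytr.mean(), max(ytr.std(), 1e-12)
        Xs, ys = self._scale_x(Xtr), (ytr - self.y_mean) / self.y_std
        Xvs = self._scale_x(Xva)

        best = None
        histories = []
        attempts = 0
        for attempt in range(cfg.max_retrains):
            attempts += 1
            rng = np.random.default_rng(cfg.seed + 7919 * attempt)
            params, history = self._train_once(Xs, ys, rng)
            histories.append(history)
            pred_va = self._predict_scaled(params, Xvs) * self.y_std + self.y_mean
            va_mape = mape(yva, pred_va)
            if best is None or va_mape < best[0]:
                best = (va_mape, params, pred_va)
            if va_mape <= cfg.accuracy_threshold:
                break
        va_mape, params, pred_va = best
        self.params = params
        self.result = ForecastResult(
            val_predictions=pred_va, val_targets=yva,
            loss_history=np.concatenate(histories),
            val_mape=float(va_mape),
            val_mase=float(mase(yva, pred_va)) if np.std(yva) > 0 else 0.0,
            converged=bool(va_mape <= cfg.accuracy_threshold),
            retrains=attempts - 1)
        return self.result

    def fit_matrix(self, psm: PhaseSpaceMatrix) -> ForecastResult:
        X, y = psm.supervised_pairs()
        return self.fit(X, y)

    def _train_once(self, Xs, ys, rng):
        cfg = self.config
        p = _init_params(cfg, rng)
        m1, v1 = p.zeros_like(), p.zeros_like()
        b1, b2, eps = 0.9, 0.999, 1e-8
        history = np.empty(cfg.epochs)
        B = Xs.shape[0]
        for epoch in range(cfg.epochs):
            y_hat, cache = _forward(p, Xs, cfg)
            err = y_hat - ys
            l2 = sum(float(np.sum(p[k] ** 2)) for k in _WEIGHT_KEYS)
            loss = float(np.mean(err ** 2)) + cfg.l2_lambda * l2
            if not np.isfinite(loss):
                raise FloatingPointError(f"training diverged at epoch {epoch}")
            history[epoch] = loss
            grads = _backward(p, cache, 2.0 * err / B, cfg)
            for k in _WEIGHT_KEYS:
                grads[k] += 2.0 * cfg.l2_lambda * p[k]
            t = epoch + 1
            for k in p:
                m1[k] = b1 * m1[k] + (1 - b1) * grads[k]
                v1[k] = b2 * v1[k] + (1 - b2) * grads[k] ** 2
                mhat = m1[k] / (1 - b1 ** t)
                vhat = v1[k] / (1 - b2 ** t)
                p[k] -= cfg.learning_rate * mhat / (np.sqrt(vhat) + eps)
        return p, history

    # -- inference ----------------------------------------------------------
    def _scale_x(self, X):
        return (X - self.x_mean) / self.x_std

    def _predict_scaled(self, params, Xs):
        y_hat, _ = _forward(params, Xs, self.config)
        return y_hat

    def predict(self, X: np.ndarray) -> np.ndarray:
        if self.params is None:
            raise RuntimeError("model is not trained")
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return self._predict_scaled(self.params, self._scale_x(X)) * self.y_std + self.y_mean

    def predict_next(self, current_state: np.ndarray) -> float:
        """Value at t+horizon from one delay vector (chronological order)."""
        state = np.asarray(current_state, dtype=float).ravel()
        if self.params is None:
            raise RuntimeError("model is not trained")
        if state.size != self._input_len:
            raise ValueError(
                f"state has dimension {state.size}, model expects {self._input_len}")
        return float(self.predict(state[None, :])[0])

    @property
    def _input_len(self) -> int:
        if not hasattr(self, "_seen_len"):
            raise RuntimeError("model is not trained")
        return self._seen_len

    def weight_norm(self) -> float:
        if self.params is None:
            raise RuntimeError("model is not trained")
        return float(math.sqrt(sum(np.sum(self.params[k] ** 2) for k in _WEIGHT_KEYS)))


def persistence_forecast(X: np.ndarray) -> np.ndarray:
    """Naive baseline: predict the last coordinate of each delay vector."""
    return np.asarray(X, dtype=float)[:, -1]
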