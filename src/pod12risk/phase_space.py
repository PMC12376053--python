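"""Pretreatment and delay-coordinate phase-space reconstruction.

Missing monitoring values are filled by the before/after-mean rule
x_i = (x_{i-1} + x_{i+1})/2 and the filled entries damped by a stability
parameter mu (default 0.85). The delay tau of each variable comes from the
first local minimum of the lag mutual information, the embedding dimension m
from the false-nearest-neighbor criterion, and the series is then unfolded
into the m x (N-(m-1)tau) trajectory matrix whose columns are delay vectors.
Documentation indexes series 1-based to mirror the usual embedding notation;
code is 0-based half-open.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .synthetic import SeriesPanel

log = logging.getLogger(__name__)


@dataclass
class EmbeddingParams:
    tau: dict[str, int] = field(default_factory=dict)
    m: dict[str, int] = field(default_factory=dict)
    mi_curve: dict[str, np.ndarray] = field(default_factory=dict)
    fnn_curve: dict[str, np.ndarray] = field(default_factory=dict)

    @property
    def total_dimension(self) -> int:
        """Dimension of the concatenated state space: sum of per-variable m."""
        return sum(self.m.values())

    def to_jsonable(self) -> dict:
        return {
            "tau": self.tau,
            "m": self.m,
            "total_dimension": self.total_dimension,
            "mi_curve": {k: list(map(float, v)) for k, v in self.mi_curve.items()},
            "fnn_curve": {k: list(map(float, v)) for k, v in self.fnn_curve.items()},
        }


@dataclass
class PhaseSpaceMatrix:
    """Delay-embedded trajectory: rows are the m delayed coordinates, columns
    the reconstructed points; row j holds x(k + j*tau) for column k."""

    matrix: np.ndarray           # (m, n_columns)
    targets: np.ndarray | None   # aligned x at horizon l, or None
    variable: str = ""
    tau: int = 1
    m: int = 1
    horizon: int = 1

    @property
    def n_points(self) -> int:
        return self.matrix.shape[1]

    def supervised_pairs(self) -> tuple[np.ndarray, np.ndarray]:
        """(X, y): X rows are chronological delay vectors, y the value l
        steps after each vector's last coordinate."""
        if self.targets is None:
            raise ValueError("matrix was built without targets")
        return self.matrix.T, self.targets


def impute_before_after_mean(panel: SeriesPanel) -> SeriesPanel:
    """Fill interior gaps with the mean of the flanking observations.

    Runs of consecutive missing values are handled by iterating the rule to
    its fixed point (equivalent to linear interpolation across the run);
    missing boundary values take the nearest observed value. The returned
    mask still marks imputed entries as unobserved so they can be damped.
    """
    values = panel.values.copy()
    if len(values) < 3:
        raise ValueError("imputation needs series of length >= 3")
    for col in values.columns:
        x = values[col].to_numpy(dtype=float)
        miss = np.isnan(x)
        if miss.all():
            raise ValueError(f"variable {col!r} has no observed values")
        if not miss.any():
            continue
        n_runs = _count_gap_runs(miss)
        if (miss[0] or miss[-1]):
            log.info("boundary missing values in %s filled with nearest observation", col)
        if n_runs:
            log.info("%s: %d gap(s) filled by before/after mean", col, n_runs)
        # iterate x_i = (x_{i-1}+x_{i+1})/2 to fixed point == linear interp
        idx = np.arange(x.size)
        x[miss] = np.interp(idx[miss], idx[~miss], x[~miss])
        values[col] = x
    return SeriesPanel(values=values, mask=panel.mask.copy(),
                       time_step=panel.time_step)


def _count_gap_runs(miss: np.ndarray) -> int:
    return int(np.sum(np.diff(np.concatenate([[0], miss.view(np.int8)])) == 1))


def stabilize(panel: SeriesPanel, mu: float = 0.85,
              mu_scope: str = "imputed") -> SeriesPanel:
    """Damp values by the control parameter mu (x -> mu*x).

    ``mu_scope='imputed'`` (default) scales only the filled entries —
    the reading that the correction applies to the imputations; ``'all'``
    scales every entry.
    """
    if not 0.0 < mu <= 1.0:
        raise ValueError("mu must lie in (0, 1]")
    if mu_scope not in ("imputed", "all"):
        raise ValueError("mu_scope must be 'imputed' or 'all'")
    values = panel.values.copy()
    if mu_scope == "all":
        values *= mu
    else:
        if values.isna().any().any():
            raise ValueError("impute before stabilizing: panel still has gaps")
        imputed = ~panel.mask.to_numpy()
        arr = values.to_numpy()
        arr[imputed] *= mu
        values = pd.DataFrame(arr, index=values.index, columns=values.columns)
    return SeriesPanel(values=values, mask=panel.mask.copy(),
                       time_step=panel.time_step)


def _mutual_information(x: np.ndarray, y: np.ndarray, n_bins: int) -> float:
    """MI in nats from an equal-width 2-D histogram."""
    joint, _, _ = np.histogram2d(x, y, bins=n_bins)
    joint /= joint.sum()
    px = joint.sum(axis=1, keepdims=True)
    py = joint.sum(axis=0, keepdims=True)
    nz = joint > 0
    return float(np.sum(joint[nz] * np.log(joint[nz] / (px @ py)[nz])))


def delay_by_mutual_information(series, max_lag: int | None = None,
                                n_bins: int | None = None,
                                smooth: int = 3) -> tuple[int, np.ndarray]:
    """Delay tau = first local minimum of the lag mutual-information curve.

    The histogram MI estimate is shallow and slightly wiggly near its
    minimum, so the local-minimum search runs on a short moving average
    (window ``smooth``) of the curve; the returned mi_curve is the raw one.
    If no local minimum exists within max_lag, tau falls back to the first
    lag where MI drops below MI(1)/e (or 1 if it never does); the fallback
    is logged. Bins default to ceil(sqrt(N)) equal-width bins.
    """
    x = np.asarray(series, dtype=float)
    n = x.size
    if max_lag is None:
        max_lag = max(2, n // 10)
    if n < 4 * max_lag:
        raise ValueError("series too short for the requested max_lag")
    if np.nanstd(x) == 0:
        raise ValueError("mutual information undefined for a constant series")
    if n_bins is None:
        n_bins = math.ceil(math.sqrt(n))
    mi = np.array([_mutual_information(x[:-lag], x[lag:], n_bins)
                   for lag in range(1, max_lag + 1)])
    if smooth > 1 and mi.size >= smooth:
        kernel = np.ones(smooth) / smooth
        search = np.convolve(mi, kernel, mode="valid")
        offset = (smooth - 1) // 2
    else:
        search, offset = mi, 0
    for k in range(1, search.size - 1):
        if search[k] < search[k - 1] and search[k] <= search[k + 1]:
            return k + 1 + offset, mi
    below = np.nonzero(mi < mi[0] / math.e)[0]
    tau = int(below[0] + 1) if below.size else 1
    log.info("no local MI minimum up to lag %d; falling back to tau=%d", max_lag, tau)
    return tau, mi


def _embed(x: np.ndarray, m: int, tau: int) -> np.ndarray:
    """(n_vectors, m) delay vectors v_k = (x_k, x_{k+tau}, ..., x_{k+(m-1)tau})."""
    n_vec = x.size - (m - 1) * tau
    if n_vec < 1:
        raise ValueError(
            f"series of length {x.size} too short for m={m}, tau={tau}")
    return np.stack([x[j * tau: j * tau + n_vec] for j in range(m)], axis=1)


def embedding_dim_by_fnn(series, tau: int, max_m: int = 10, r_tol: float = 15.0,
                         threshold: float = 0.01) -> tuple[int, np.ndarray]:
    """Embedding dimension by the false-nearest-neighbor criterion.

    For each candidate dimension the fraction of nearest neighbors whose
    separation grows by more than r_tol when the next delay coordinate is
    appended is computed; m is the smallest dimension where that fraction
    drops below ``threshold``, falling back to the argmin of the curve when
    the threshold is never crossed.
    """
    x = np.asarray(series, dtype=float)
    if x.size - max_m * tau < 10:
        raise ValueError("series too short for FNN up to max_m at this tau")
    if np.std(x) == 0:
        log.warning("constant series: embedding dimension 1 by convention")
        return 1, np.zeros(max_m)

    fractions = np.empty(max_m)
    for m in range(1, max_m + 1):
        emb = _embed(x, m, tau)
        n_usable = x.size - m * tau  # vectors whose next coordinate exists
        emb_u = emb[:n_usable]
        tree = cKDTree(emb_u)
        dist, nbr = tree.query(emb_u, k=2)
        dist, nbr = dist[:, 1], nbr[:, 1]
        nxt = x[np.arange(n_usable) + m * tau]
        growth = np.abs(nxt - nxt[nbr])
        # exactly recurrent points (dist == 0) are true neighbors unless the
        # added coordinate actually separates them beyond numerical noise
        atol = 1e-8 * float(np.std(x))
        false = growth > np.maximum(r_tol * dist, atol)
        fractions[m - 1] = false.mean() if false.size else 0.0
        if fractions[m - 1] < threshold:
            return m, fractions[:m]
    m = int(np.argmin(fractions)) + 1
    log.info("FNN fraction never dropped below %.2g; using argmin m=%d", threshold, m)
    return m, fractions


def reconstruct(series, m: int, tau: int, l: int = 1,
                variable: str = "") -> PhaseSpaceMatrix:
    """Unfold a series into its delay-embedded trajectory matrix.

    The matrix has m rows and N-(m-1)tau columns; column k (1-based) is the
    delay vector (x_k, x_{k+tau}, ..., x_{k+(m-1)tau}). Targets align each
    column with the value l steps past its last coordinate, giving
    N-(m-1)tau-l supervised pairs.
    """
    x = np.asarray(series, dtype=float)
    n = x.size
    if m < 1 or tau < 1 or l < 0:
        raise ValueError("m, tau must be >= 1 and l >= 0")
    if n <= (m - 1) * tau + l:
        raise ValueError(
            f"need N > (m-1)*tau + l; got N={n}, m={m}, tau={tau}, l={l}")
    full = _embed(x, m, tau)           # (N-(m-1)tau, m) chronological vectors
    if l == 0:
        return PhaseSpaceMatrix(matrix=full.T, targets=None, variable=variable,
                                tau=tau, m=m, horizon=l)
    n_pairs = n - (m - 1) * tau - l
    targets = x[(m - 1) * tau + l:]
    return PhaseSpaceMatrix(matrix=full[:n_pairs].T, targets=targets[:n_pairs],
                            variable=variable, tau=tau, m=m, horizon=l)


def embed_panel(panel: SeriesPanel, max_lag: int | None = None,
                max_m: int = 10, r_tol: float = 15.0) -> EmbeddingParams:
    """Per-variable tau (mutual information) and m (FNN) for a whole panel."""
    params = EmbeddingParams()
    for col in panel.variables:
        x = panel.values[col].to_numpy(dtype=float)
        if np.isnan(x).any():
            raise ValueError(f"variable {col!r} has gaps; impute first")
        tau, mi = delay_by_mutual_information(x, max_lag=max_lag)
        m, fnn = embedding_dim_by_fnn(x, tau, max_m=max_m, r_tol=r_tol)
        params.tau[col], params.m[col] = tau, m
        params.mi_curve[col], params.fnn_curve[col] = mi, fnn
    return params
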