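"""Gaussian hidden layer of the RBF network, estimated by fuzzy C-means.

The hidden layer maps a d-dimensional feature vector x to the M-vector

    x~_i = exp(-||x - c_i||^2 / delta_i),   i = 1..M,

where the centers c_i are fuzzy C-means cluster centers and each width
delta_i is the membership-weighted mean squared distance of the data to
its center.  delta_i therefore carries squared-distance units and enters
the exponent un-squared.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

__all__ = ["FCMResult", "HiddenLayer", "fcm_cluster", "build_hidden_layer", "hidden_map"]

#: Relative floor applied to widths, as a fraction of the mean pairwise
#: squared distance of the data; guards the exponent against division by
#: zero for singleton or degenerate clusters.
WIDTH_FLOOR_REL = 1e-8


@dataclass
class FCMResult:
    """State of a converged (or stopped) fuzzy C-means run."""

    memberships: np.ndarray      # n x M, rows sum to 1
    centers: np.ndarray          # M x d
    objective_trace: np.ndarray  # objective after each center update
    n_iter: int
    converged: bool
    fuzzifier: float = 2.0

    @property
    def M(self) -> int:
        return self.centers.shape[0]


@dataclass
class HiddenLayer:
    """M Gaussian basis centers with per-center widths (squared units)."""

    centers: np.ndarray  # M x d
    widths: np.ndarray   # length M, > 0

    def __post_init__(self) -> None:
        self.centers = np.asarray(self.centers, dtype=float)
        self.widths = np.asarray(self.widths, dtype=float)
        if not np.isfinite(self.centers).all():
            raise ValueError("hidden-layer centers must be finite")
        if (self.widths <= 0).any():
            raise ValueError("hidden-layer widths must be strictly positive")

    @property
    def M(self) -> int:
        return self.centers.shape[0]


def _mean_pairwise_sq_dist(X: np.ndarray) -> float:
    # E||x_i - x_j||^2 over ordered pairs = 2 * sum_k biased-var_k * n/(n-1)
    n = X.shape[0]
    if n < 2:
        return 0.0
    return float(2.0 * X.var(axis=0, ddof=0).sum() * n / (n - 1))


def _memberships_from_centers(X: np.ndarray, centers: np.ndarray, m: float) -> np.ndarray:
    D2 = cdist(X, centers, "sqeuclidean")
    exact = D2 <= 0.0
    # crisp assignment for points sitting on a center
    U = np.zeros_like(D2)
    on_center = exact.any(axis=1)
    if on_center.any():
        hit = exact[on_center]
        U[on_center] = hit / hit.sum(axis=1, keepdims=True)
    rest = ~on_center
    if rest.any():
        inv = D2[rest] ** (-1.0 / (m - 1.0))
        U[rest] = inv / inv.sum(axis=1, keepdims=True)
    return U


def fcm_cluster(
    X: np.ndarray,
    M: int,
    fuzzifier: float = 2.0,
    tol: float = 1e-5,
    max_iter: int = 300,
    seed: int = 0,
) -> FCMResult:
    """Standard fuzzy C-means with alternating membership/center updates.

    Centers are initialised as ``M`` distinct sample rows drawn by
    ``seed``; iteration stops when the largest membership change drops
    below ``tol`` or after ``max_iter`` sweeps.  The reported objective is
    sum_ji u_ji^m ||x_j - c_i||^2 evaluated after each center update.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("X must be a 2-D sample matrix")
    n = X.shape[0]
    if not 1 <= M <= n:
        raise ValueError(f"need 1 <= M <= n, got M={M}, n={n}")
    if fuzzifier <= 1.0:
        raise ValueError("fuzzifier must be > 1")

    unique_rows = np.unique(X, axis=0)
    if M > unique_rows.shape[0]:
        raise ValueError(
            f"degenerate data: only {unique_rows.shape[0]} distinct samples "
            f"for M={M} clusters"
        )

    rng = np.random.default_rng(seed)
    # draw distinct rows (as points, not just indices)
    centers = unique_rows[rng.choice(unique_rows.shape[0], size=M, replace=False)]

    U = _memberships_from_centers(X, centers, fuzzifier)
    trace: list[float] = []
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        W = U ** fuzzifier
        mass = W.sum(axis=0)
        if (mass <= 0).any():
            dead = int(np.argmin(mass))
            raise RuntimeError(f"cluster {dead} lost all membership mass")
        centers = (W.T @ X) / mass[:, None]
        D2 = cdist(X, centers, "sqeuclidean")
        trace.append(float((W * D2).sum()))
        U_new = _memberships_from_centers(X, centers, fuzzifier)
        delta = float(np.abs(U_new - U).max())
        U = U_new
        if delta < tol:
            converged = True
            break

    return FCMResult(
        memberships=U,
        centers=centers,
        objective_trace=np.asarray(trace),
        n_iter=it,
        converged=converged,
        fuzzifier=fuzzifier,
    )


def build_hidden_layer(fcm: FCMResult, X: np.ndarray) -> HiddenLayer:
    """Turn an FCM solution into Gaussian centers and widths.

    c_ik = sum_j u_ji x_jk / sum_j u_ji and
    delta_i = sum_j u_ji ||x_j - c_i||^2 / sum_j u_ji, floored at a small
    fraction of the data's mean pairwise squared distance.
    """
    X = np.asarray(X, dtype=float)
    U = fcm.memberships
    if U.shape[0] != X.shape[0]:
        raise ValueError("FCM result is inconsistent with the sample matrix")
    mass = U.sum(axis=0)
    if (mass <= 0).any():
        dead = int(np.argmin(mass))
        raise ValueError(f"cluster {dead} has zero membership mass")
    centers = (U.T @ X) / mass[:, None]
    D2 = cdist(X, centers, "sqeuclidean")
    widths = (U * D2).sum(axis=0) / mass

    floor = WIDTH_FLOOR_REL * _mean_pairwise_sq_dist(X)
    if floor <= 0.0:
        floor = WIDTH_FLOOR_REL
    widths = np.maximum(widths, floor)
    return HiddenLayer(centers=centers, widths=widths)


def hidden_map(layer: HiddenLayer, X: np.ndarray) -> np.ndarray:
    """Map raw features to the hidden representation x~ (n x M, values in (0, 1])."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != layer.centers.shape[1]:
        raise ValueError(
            f"feature dimension {X.shape[1]} does not match hidden layer "
            f"dimension {layer.centers.shape[1]}"
        )
    D2 = cdist(X, layer.centers, "sqeuclidean")
    return np.exp(-D2 / layer.widths[None, :])
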