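"""Independent reference implementations used as test oracles.

Everything here is written deliberately naively (explicit loops, direct
formulas) and independently of the package's vectorised code paths, so
that agreement between the two is meaningful.
"""

from __future__ import annotations

import numpy as np


def textbook_fcm(X, M, fuzzifier=2.0, tol=1e-5, max_iter=300, seed=0):
    """Loop-based fuzzy C-means with the same init scheme as the package.

    Init: M distinct sample rows drawn by ``numpy.random.default_rng(seed)``
    without replacement from the unique rows; alternating updates with
    memberships computed from center distances, stopping on the max
    membership change.  Returns (memberships, centers, objective).
    """
    X = np.asarray(X, dtype=float)
    n, d = X.shape
    uniq = np.unique(X, axis=0)
    rng = np.random.default_rng(seed)
    centers = uniq[rng.choice(uniq.shape[0], size=M, replace=False)].copy()

    def memberships(centers):
        U = np.zeros((n, M))
        for j in range(n):
            d2 = np.array([np.sum((X[j] - centers[i]) ** 2) for i in range(M)])
            zero = d2 <= 0.0
            if zero.any():
                U[j, zero] = 1.0 / zero.sum()
            else:
                for i in range(M):
                    U[j, i] = 1.0 / np.sum((d2[i] / d2) ** (1.0 / (fuzzifier - 1.0)))
        return U

    U = memberships(centers)
    objective = np.inf
    for _ in range(max_iter):
        W = U ** fuzzifier
        for i in range(M):
            centers[i] = (W[:, i][:, None] * X).sum(axis=0) / W[:, i].sum()
        objective = 0.0
        for j in range(n):
            for i in range(M):
                objective += W[j, i] * np.sum((X[j] - centers[i]) ** 2)
        U_new = memberships(centers)
        delta = np.abs(U_new - U).max()
        U = U_new
        if delta < tol:
            break
    return U, centers, float(objective)


def simplex_grid_max(Q, b, step=1e-3):
    """Exhaustively maximise b'x - x'Qx over the simplex grid of 4 variables.

    Enumerates every lattice point x = (i1, i2, i3, i4)/m with
    i1+i2+i3+i4 = m, m = 1/step.  The quadratic is expanded in
    (x1, x2, x3) with x4 eliminated, and the (x1, x2) grid is sorted by
    x1 + x2 so each x3 slice is a prefix — this keeps the 1.7e8-point
    enumeration vectorised and fast.
    """
    Q = np.asarray(Q, dtype=float)
    b = np.asarray(b, dtype=float)
    assert Q.shape == (4, 4) and b.shape == (4,)
    m = int(round(1.0 / step))

    # f(x) = b'x - x'Qx with x4 = 1 - x1 - x2 - x3
    # expand: define e_i basis; substitute symbolically via numpy on coefficients
    # f = c0 + sum_i ci xi + sum_ij cij xi xj   (i, j in {1,2,3})
    Qs = (Q + Q.T) / 2.0
    c0 = b[3] - Qs[3, 3]
    lin = np.array([b[i] - b[3] - 2.0 * Qs[i, 3] + 2.0 * Qs[3, 3] for i in range(3)])
    quad = np.array(
        [[-(Qs[i, j] - Qs[i, 3] - Qs[j, 3] + Qs[3, 3]) for j in range(3)]
         for i in range(3)]
    )

    i1, i2 = np.meshgrid(np.arange(m + 1), np.arange(m + 1), indexing="ij")
    keep = (i1 + i2) <= m
    i1, i2 = i1[keep].astype(np.int64), i2[keep].astype(np.int64)
    order = np.argsort(i1 + i2, kind="stable")
    i1, i2 = i1[order], i2[order]
    s12 = i1 + i2
    # prefix count: number of pairs with i1+i2 <= t
    counts = np.searchsorted(s12, np.arange(m + 1), side="right")

    x1 = i1 / m
    x2 = i2 / m
    qfix = quad[0, 0] * x1 * x1 + quad[1, 1] * x2 * x2 + 2.0 * quad[0, 1] * x1 * x2
    lfix = lin[0] * x1 + lin[1] * x2

    best = -np.inf
    for i3 in range(m + 1):
        x3 = i3 / m
        cnt = counts[m - i3]
        f = (
            c0 + lin[2] * x3 + quad[2, 2] * x3 * x3
            + lfix[:cnt]
            + qfix[:cnt]
            + (2.0 * x3) * (quad[0, 2] * x1[:cnt] + quad[1, 2] * x2[:cnt])
        )
        fm = f.max()
        if fm > best:
            best = fm
    return float(best)


def gradient_descent_ls(Xt, y, lr=None, max_iter=200000, tol=1e-12):
    """Plain gradient descent on 0.5*||Xt w - y||^2, run to convergence."""
    Xt = np.asarray(Xt, dtype=float)
    y = np.asarray(y, dtype=float)
    w = np.zeros(Xt.shape[1])
    if lr is None:
        lr = 1.0 / (np.linalg.norm(Xt, 2) ** 2)
    for _ in range(max_iter):
        g = Xt.T @ (Xt @ w - y)
        w_new = w - lr * g
        if np.abs(w_new - w).max() < tol:
            return w_new
        w = w_new
    return w


def ellipse_pixel_count(center, axes, angle_deg, shape):
    """Count pixels inside a rotated ellipse by direct point-in-ellipse test."""
    th = np.radians(angle_deg)
    count = 0
    for r in range(shape[0]):
        for c in range(shape[1]):
            dr, dc = r - center[0], c - center[1]
            u = np.cos(th) * dr + np.sin(th) * dc
            v = -np.sin(th) * dr + np.cos(th) * dc
            if (u / axes[0]) ** 2 + (v / axes[1]) ** 2 <= 1.0:
                count += 1
    return count
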