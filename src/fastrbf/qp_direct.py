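"""Exact dense solver for the eps-insensitive network dual.

Training the output weights of the RBF network is posed as

    min_{p, eps, xi}  ||p||^2 + 2*lambda*eps + (lambda/(mu*n)) * sum(xi_i^2 + xi*_i^2)
    s.t.              |y_i - p' phi(x~_i)| < eps + slack

whose dual is a QP over the probability simplex in the 2n stacked
variables alpha~ = [alpha; alpha*]:

    max  2*lambda*[y; -y]' alpha~  -  alpha~' Ktilde alpha~
    s.t. alpha~ >= 0,  sum(alpha~) = 1

with the augmented kernel

    Ktilde = [[K + (mu*n/lambda) I,  -K],
              [-K,  K + (mu*n/lambda) I]]

and K the Gaussian base kernel on hidden representations.  This module
solves that dual densely; it doubles as the "traditional" full-data
trainer and as the correctness oracle for the core-set solver.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

from .simplex_qp import solve_simplex_qp

__all__ = [
    "DIRECT_SOLVER_MAX_N",
    "EpsQPProblem",
    "DualSolution",
    "base_kernel",
    "build_augmented_kernel",
    "solve_dual_direct",
]

#: Largest sample count the dense 2n x 2n solver accepts.
DIRECT_SOLVER_MAX_N = 5000


@dataclass
class EpsQPProblem:
    """One binary training problem in hidden space."""

    Xtilde: np.ndarray   # n x M hidden features
    y: np.ndarray        # length n, entries +1/-1
    lam: float           # eps trade-off weight lambda
    mu: float            # balance factor mu (mean slack per sample)
    sigma2: float        # Gaussian base-kernel bandwidth

    def __post_init__(self) -> None:
        self.Xtilde = np.atleast_2d(np.asarray(self.Xtilde, dtype=float))
        self.y = np.asarray(self.y, dtype=float).ravel()
        if self.y.shape[0] != self.Xtilde.shape[0]:
            raise ValueError("label length does not match sample count")
        if not np.isin(self.y, (-1.0, 1.0)).all():
            raise ValueError("labels must be +1/-1")
        for name in ("lam", "mu", "sigma2"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")

    @property
    def n(self) -> int:
        return self.Xtilde.shape[0]

    @property
    def ridge(self) -> float:
        """Diagonal term mu*n/lambda added to both diagonal blocks."""
        return self.mu * self.n / self.lam

    @property
    def ytilde(self) -> np.ndarray:
        return np.concatenate([self.y, -self.y])


@dataclass
class DualSolution:
    """Simplex-feasible dual weights with recovered primal slacks."""

    alpha: np.ndarray
    alpha_star: np.ndarray
    objective: float
    xi: np.ndarray
    xi_star: np.ndarray
    expansion: np.ndarray    # lambda * (alpha - alpha*), coefficients of p
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if (self.alpha < -1e-12).any() or (self.alpha_star < -1e-12).any():
            raise ValueError("dual weights must be non-negative")
        total = self.alpha.sum() + self.alpha_star.sum()
        if abs(total - 1.0) > 1e-8:
            raise ValueError(f"dual weights must sum to 1, got {total!r}")


def base_kernel(Xtilde_a: np.ndarray, Xtilde_b: np.ndarray, sigma2: float) -> np.ndarray:
    """Gaussian kernel K_ij = exp(-||a_i - b_j||^2 / (2 sigma2)) on hidden rows."""
    if sigma2 <= 0:
        raise ValueError("sigma2 must be strictly positive")
    A = np.atleast_2d(np.asarray(Xtilde_a, dtype=float))
    B = np.atleast_2d(np.asarray(Xtilde_b, dtype=float))
    if A.shape[1] != B.shape[1]:
        raise ValueError("hidden dimensions do not match")
    return np.exp(-cdist(A, B, "sqeuclidean") / (2.0 * sigma2))


def build_augmented_kernel(problem: EpsQPProblem) -> np.ndarray:
    """Materialise the 2n x 2n augmented kernel Ktilde (dense)."""
    K = base_kernel(problem.Xtilde, problem.Xtilde, problem.sigma2)
    n = problem.n
    c = problem.ridge
    Kt = np.empty((2 * n, 2 * n))
    Kt[:n, :n] = K
    Kt[n:, n:] = K
    Kt[:n, n:] = -K
    Kt[n:, :n] = -K
    Kt[np.arange(2 * n), np.arange(2 * n)] += c
    return Kt


def solve_dual_direct(problem: EpsQPProblem, kkt_tol: float = 1e-8) -> DualSolution:
    """Solve the simplex dual exactly with the dense active-set QP.

    Guarded to n <= 5000; beyond that the 2n x 2n kernel no longer fits a
    sensible dense solve and the core-set path must be used instead.
    """
    n = problem.n
    if n > DIRECT_SOLVER_MAX_N:
        raise ValueError(
            f"direct solver is limited to n <= {DIRECT_SOLVER_MAX_N} samples "
            f"(got n = {n}); use the core-set solver"
        )
    Kt = build_augmented_kernel(problem)
    d = 2.0 * problem.lam * problem.ytilde
    res = solve_simplex_qp(Kt, d, kkt_tol=kkt_tol)
    alpha_tilde = res.x
    alpha = alpha_tilde[:n].copy()
    alpha_star = alpha_tilde[n:].copy()
    mun = problem.mu * n
    # implied eps-tube half-width (derived, diagnostic only): the smallest
    # eps making the primal constraints hold at the recovered solution
    K = Kt[:n, :n] - np.diag(np.full(n, problem.ridge))
    f = K @ (problem.lam * (alpha - alpha_star))
    resid = problem.y - f
    implied_eps = max(
        0.0,
        float((resid - alpha * mun).max()),
        float((-resid - alpha_star * mun).max()),
    )
    return DualSolution(
        alpha=alpha,
        alpha_star=alpha_star,
        objective=-res.objective,          # solver minimised the negated dual
        xi=alpha * mun,
        xi_star=alpha_star * mun,
        expansion=problem.lam * (alpha - alpha_star),
        diagnostics={
            "solver": "direct",
            "n_iter": res.n_iter,
            "kkt_residual": res.kkt_residual,
            "implied_eps": implied_eps,
        },
    )
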