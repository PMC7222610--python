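"""Center-constrained minimum-enclosing-ball reformulation and core-set solver.

The simplex dual of the eps-insensitive network QP,

    max  2*lambda*[y; -y]' a  -  a' Ktilde a,   a on the 2n-simplex,

is, after adding a per-point augmentation distance

    Delta_i = -Ktilde_ii + eta + 2*lambda*ytilde_i   (eta chosen so Delta >= 0),

exactly the dual of a center-constrained minimum enclosing ball (MEB)
over 2n augmented feature points.  That ball can be approximated to a
(1 + eps_tol) factor by growing a small *core set*: repeatedly solve the
ball restricted to the current subset, look for a point falling outside
the (1 + eps_tol)-inflated ball, and add the farthest such violator.
Termination is certified by one exhaustive scan, so the returned subset
provably covers every augmented point at the inflated radius.

Kernel entries are produced lazily from the hidden representations, so
the 2n x 2n matrix is never materialised for large n.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

from .qp_direct import DualSolution, EpsQPProblem
from .simplex_qp import solve_simplex_qp

__all__ = [
    "AugmentedKernel",
    "DenseAugmentedKernel",
    "LazyAugmentedKernel",
    "CCMEBProblem",
    "CoreSet",
    "CoreSetError",
    "build_delta",
    "ccmeb_problem_from_qp",
    "ccmeb_radius",
    "ccmeb_distance2",
    "solve_coreset",
    "coreset_to_alpha",
    "solve_dual_coreset",
]

#: Row-chunk size used when scanning all augmented points for violators.
_SCAN_CHUNK = 16384


class CoreSetError(RuntimeError):
    """Core-set iteration failed; carries the (|S|, R) trace."""

    def __init__(self, message: str, trace: list[tuple[int, float]]):
        super().__init__(message)
        self.trace = trace


class AugmentedKernel:
    """Value-oriented view of the augmented kernel Ktilde.

    Index convention: augmented index l in [0, 2n) refers to base sample
    l mod n with sign +1 for l < n and -1 otherwise;
    Ktilde[l, m] = s_l s_m K(b_l, b_m) + ridge * [l == m].
    """

    size: int

    def diag(self) -> np.ndarray:
        raise NotImplementedError

    def block(self, rows: np.ndarray | None, cols: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class DenseAugmentedKernel(AugmentedKernel):
    def __init__(self, matrix: np.ndarray):
        matrix = np.asarray(matrix, dtype=float)
        if matrix.ndim != 2 or matrix.shape[0] != matrix.shape[1]:
            raise ValueError("augmented kernel must be square")
        if matrix.shape[0] % 2 != 0:
            raise ValueError("augmented kernel must have even size 2n")
        self.matrix = matrix
        self.size = matrix.shape[0]

    def diag(self) -> np.ndarray:
        return np.diag(self.matrix).copy()

    def block(self, rows: np.ndarray | None, cols: np.ndarray) -> np.ndarray:
        if rows is None:
            return self.matrix[:, cols]
        return self.matrix[np.ix_(np.asarray(rows), np.asarray(cols))]


class LazyAugmentedKernel(AugmentedKernel):
    """Computes Ktilde entries on demand from hidden features."""

    def __init__(self, Xtilde: np.ndarray, sigma2: float, ridge: float):
        if sigma2 <= 0:
            raise ValueError("sigma2 must be strictly positive")
        self.Xtilde = np.atleast_2d(np.asarray(Xtilde, dtype=float))
        self.sigma2 = float(sigma2)
        self.ridge = float(ridge)
        self.n = self.Xtilde.shape[0]
        self.size = 2 * self.n

    def diag(self) -> np.ndarray:
        return np.full(self.size, 1.0 + self.ridge)

    def block(self, rows: np.ndarray | None, cols: np.ndarray) -> np.ndarray:
        cols = np.asarray(cols)
        rows = np.arange(self.size) if rows is None else np.asarray(rows)
        br, bc = rows % self.n, cols % self.n
        sr = np.where(rows < self.n, 1.0, -1.0)
        sc = np.where(cols < self.n, 1.0, -1.0)
        K = np.exp(
            -cdist(self.Xtilde[br], self.Xtilde[bc], "sqeuclidean") / (2.0 * self.sigma2)
        )
        K *= sr[:, None] * sc[None, :]
        same = rows[:, None] == cols[None, :]
        if same.any():
            K[same] += self.ridge
        return K


def _as_kernel(Ktilde) -> AugmentedKernel:
    if isinstance(Ktilde, AugmentedKernel):
        return Ktilde
    return DenseAugmentedKernel(np.asarray(Ktilde))


@dataclass
class CCMEBProblem:
    """Augmented kernel plus the MEB augmentation distances."""

    kernel: AugmentedKernel
    Delta: np.ndarray     # length 2n, >= 0 with min exactly 0
    eta: float
    ytilde: np.ndarray    # [y; -y]
    lam: float

    @property
    def size(self) -> int:
        return self.kernel.size

    @property
    def linear(self) -> np.ndarray:
        """Linear dual coefficients diag(Ktilde) + Delta - eta = 2*lambda*ytilde."""
        return 2.0 * self.lam * self.ytilde


@dataclass
class CoreSet:
    """Core-set state: indices into the 2n augmented points and MEB dual."""

    indices: np.ndarray
    beta: np.ndarray
    radius: float
    center_norm2: float
    n_iter: int
    trace: list[tuple[int, float]] = field(default_factory=list)
    objective: float = float("nan")   # restricted dual value, network-dual scale
    certified: bool = False

    def __post_init__(self) -> None:
        self.indices = np.asarray(self.indices, dtype=int)
        self.beta = np.asarray(self.beta, dtype=float)
        if (self.beta < -1e-12).any() or abs(self.beta.sum() - 1.0) > 1e-8:
            raise ValueError("beta must be simplex-feasible on the core set")

    @property
    def size(self) -> int:
        return self.indices.size


def build_delta(Ktilde, y: np.ndarray, lam: float) -> CCMEBProblem:
    """Construct the augmentation Delta and shift eta for a given dual.

    eta is the smallest value with Delta = -diag(Ktilde) + eta + 2*lambda*
    [y; -y] >= 0 elementwise (min Delta = 0); the dual argmax is invariant
    to eta, so the smallest admissible shift is used.
    """
    kernel = _as_kernel(Ktilde)
    y = np.asarray(y, dtype=float).ravel()
    if y.size == 0:
        raise ValueError("empty problem")
    if 2 * y.size != kernel.size:
        raise ValueError("label length inconsistent with augmented kernel size")
    ytilde = np.concatenate([y, -y])
    diag = kernel.diag()
    eta = float((diag - 2.0 * lam * ytilde).max())
    Delta = -diag + eta + 2.0 * lam * ytilde
    Delta = np.maximum(Delta, 0.0)  # clip roundoff at the touching point
    return CCMEBProblem(kernel=kernel, Delta=Delta, eta=eta, ytilde=ytilde, lam=lam)


def ccmeb_problem_from_qp(problem: EpsQPProblem, lazy: bool = True) -> CCMEBProblem:
    """Build the CC-MEB form of a network dual, with a lazy kernel by default."""
    if lazy:
        kernel = LazyAugmentedKernel(problem.Xtilde, problem.sigma2, problem.ridge)
        return build_delta(kernel, problem.y, problem.lam)
    from .qp_direct import build_augmented_kernel

    return build_delta(build_augmented_kernel(problem), problem.y, problem.lam)


def ccmeb_radius(coreset: CoreSet, Ktilde, Delta: np.ndarray) -> float:
    """Ball radius from the dual weights: R^2 = b'(diag+Delta) - b'K b."""
    kernel = _as_kernel(Ktilde)
    S, beta = coreset.indices, coreset.beta
    KSS = kernel.block(S, S)
    diag = kernel.diag()[S]
    r2 = float(beta @ (diag + np.asarray(Delta)[S]) - beta @ KSS @ beta)
    if r2 < -1e-10:
        raise ArithmeticError(f"negative squared radius {r2}")
    return float(np.sqrt(max(r2, 0.0)))


def ccmeb_distance2(coreset: CoreSet, Ktilde, Delta: np.ndarray, l) -> np.ndarray | float:
    """Augmented squared distance of point(s) l to the ball center.

    ||c - phi(x_l)||^2 + delta_l^2 = ||c||^2 - 2 (Ktilde beta)_l
                                     + Ktilde_ll + Delta_l.
    """
    kernel = _as_kernel(Ktilde)
    S, beta = coreset.indices, coreset.beta
    ls = np.atleast_1d(np.asarray(l, dtype=int))
    KSS = kernel.block(S, S)
    cn2 = float(beta @ KSS @ beta)
    Kb = kernel.block(ls, S) @ beta
    diag = kernel.diag()
    out = cn2 - 2.0 * Kb + diag[ls] + np.asarray(Delta)[ls]
    return out if np.ndim(l) else float(out[0])


def _scan_distances2(
    problem: CCMEBProblem,
    S: np.ndarray,
    beta: np.ndarray,
    cn2: float,
    rows: np.ndarray | None,
) -> np.ndarray:
    """Distances^2 to the center for `rows` (all points when None), chunked."""
    kernel = problem.kernel
    dplus = kernel.diag() + problem.Delta  # = eta + 2*lambda*ytilde
    if rows is None:
        rows = np.arange(problem.size)
    out = np.empty(rows.size)
    for lo in range(0, rows.size, _SCAN_CHUNK):
        chunk = rows[lo:lo + _SCAN_CHUNK]
        Kb = kernel.block(chunk, S) @ beta
        out[lo:lo + chunk.size] = cn2 - 2.0 * Kb + dplus[chunk]
    return out


def solve_coreset(
    problem: CCMEBProblem,
    eps_tol: float = 1e-6,
    sample_size: int = 59,
    seed: int = 0,
    max_iter: int | None = None,
    qp_tol: float = 1e-10,
) -> CoreSet:
    """Grow a core set until the (1 + eps_tol)-inflated ball covers all points.

    Each iteration solves the MEB dual restricted to the current core set
    (warm-started active-set QP), then looks for a violator — first in a
    random probe of ``sample_size`` points, and if none is found there, in
    one exhaustive scan which doubles as the termination certificate.
    ``sample_size = 0`` forces exhaustive scans throughout.
    """
    if eps_tol <= 0:
        raise ValueError("eps_tol must be strictly positive")
    N = problem.size
    if N == 0:
        raise ValueError("empty problem")
    if max_iter is None:
        max_iter = min(5000, max(10, int(10.0 * np.sqrt(1.0 / eps_tol))))

    rng = np.random.default_rng(seed)
    kernel = problem.kernel
    dplus = kernel.diag() + problem.Delta

    # initialise with the farthest pair among 100 seeded candidates
    cand = rng.choice(N, size=min(100, N), replace=False)
    B = kernel.block(cand, cand)
    pair_d2 = dplus[cand][:, None] + dplus[cand][None, :] - 2.0 * B
    i, j = np.unravel_index(int(np.argmax(pair_d2)), pair_d2.shape)
    if pair_d2[i, j] <= 1e-12:
        S = np.array([int(cand[0])])       # all candidates coincide: start from one
    else:
        S = np.unique([cand[i], cand[j]])
    beta = np.full(S.size, 1.0 / S.size)

    trace: list[tuple[int, float]] = []
    inflate = (1.0 + eps_tol) ** 2
    certified = False
    obj = float("nan")
    r2 = 0.0
    cn2 = 0.0
    it = 0
    while it < max_iter:
        it += 1
        KSS = kernel.block(S, S)
        lin = problem.linear[S]
        res = solve_simplex_qp(KSS, lin, x0=beta, kkt_tol=qp_tol)
        beta = res.x
        obj = -res.objective                       # network-dual objective value
        cn2 = float(beta @ KSS @ beta)
        r2 = float(beta @ (dplus[S]) - cn2)
        r2 = max(r2, 0.0)
        trace.append((S.size, float(np.sqrt(r2))))

        thresh = inflate * r2 + 1e-12 * max(1.0, r2)

        new_idx = None
        if sample_size > 0:
            probe = rng.choice(N, size=min(sample_size, N), replace=False)
            d2 = _scan_distances2(problem, S, beta, cn2, probe)
            mask = (d2 > thresh) & ~np.isin(probe, S)
            if mask.any():
                new_idx = int(probe[np.argmax(np.where(mask, d2, -np.inf))])
        if new_idx is None:
            d2 = _scan_distances2(problem, S, beta, cn2, None)
            d2[S] = -np.inf  # core-set members cannot be re-added
            far = int(np.argmax(d2))
            if d2[far] > thresh:
                new_idx = far
            else:
                certified = True
                break
        S = np.append(S, new_idx)
        beta = np.append(beta, 0.0)

    if not certified:
        raise CoreSetError(
            f"no certified cover after {it} iterations (|S| = {S.size})", trace
        )

    return CoreSet(
        indices=S,
        beta=beta,
        radius=float(np.sqrt(r2)),
        center_norm2=cn2,
        n_iter=it,
        trace=trace,
        objective=obj,
        certified=True,
    )


def coreset_to_alpha(coreset: CoreSet, n: int) -> tuple[np.ndarray, np.ndarray]:
    """Scatter core-set weights back to the full (alpha, alpha*) vectors."""
    alpha = np.zeros(n)
    alpha_star = np.zeros(n)
    for idx, b in zip(coreset.indices, coreset.beta):
        if idx < n:
            alpha[idx] += b
        else:
            alpha_star[idx - n] += b
    return alpha, alpha_star


def solve_dual_coreset(
    problem: EpsQPProblem,
    eps_tol: float = 1e-6,
    sample_size: int = 59,
    seed: int = 0,
    max_iter: int | None = None,
) -> tuple[DualSolution, CoreSet]:
    """Solve the network dual through the CC-MEB core-set path."""
    ccmeb = ccmeb_problem_from_qp(problem, lazy=True)
    coreset = solve_coreset(
        ccmeb, eps_tol=eps_tol, sample_size=sample_size, seed=seed, max_iter=max_iter
    )
    alpha, alpha_star = coreset_to_alpha(coreset, problem.n)
    mun = problem.mu * problem.n
    solution = DualSolution(
        alpha=alpha,
        alpha_star=alpha_star,
        objective=coreset.objective,
        xi=alpha * mun,
        xi_star=alpha_star * mun,
        expansion=problem.lam * (alpha - alpha_star),
        diagnostics={
            "solver": "coreset",
            "coreset_size": int(coreset.size),
            "n_iter": int(coreset.n_iter),
            "radius": float(coreset.radius),
        },
    )
    return solution, coreset
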