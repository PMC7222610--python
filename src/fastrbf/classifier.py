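"""Binary and one-vs-one organ classifiers built on the fast RBF trainer.

A binary classifier is trained by: z-scoring the six pixel features,
estimating a Gaussian hidden layer by fuzzy C-means, mapping samples to
hidden space, and solving the eps-insensitive simplex dual — either
densely (small n) or through the core-set minimum-enclosing-ball path.
The decision function is

    f(x) = sum_i lambda * (alpha_i - alpha*_i) * k(x~_i, x~_test)

with k the base Gaussian kernel; f > 0 votes for the positive tissue,
f <= 0 for the negative one (an exact zero counts as positive).  Three
pairwise classifiers — (liver, kidney), (liver, other), (kidney, other) —
are combined by one-vote-per-winner voting.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from .ccmeb import solve_dual_coreset
from .features import FeatureTable
from .qp_direct import EpsQPProblem, base_kernel, solve_dual_direct
from .rbf_layer import HiddenLayer, build_hidden_layer, fcm_cluster, hidden_map

__all__ = [
    "TrainConfig",
    "Standardizer",
    "BinaryFastRBF",
    "BaselineRBF",
    "OvOModel",
    "train_binary",
    "train_rbf_baseline",
    "decision_value",
    "predict_binary",
    "train_ovo",
    "predict_ovo",
    "accuracy",
    "save_ovo",
    "load_ovo",
]

MODEL_SCHEMA_VERSION = 1

#: Class letters of the one-vs-one scheme, in the order the votes are cast.
OVO_PAIRS = (("liver", "kidney"), ("liver", "other"), ("kidney", "other"))
_TIE_PRIORITY = ("liver", "kidney", "other")


@dataclass
class TrainConfig:
    """Hyperparameters of one training run.

    ``mu`` is the balance factor (the mean per-sample slack).  When left
    ``None`` it is derived from ``dual_ridge`` as mu = dual_ridge *
    lam / n, which keeps the dual diagonal term mu*n/lam — the quantity
    that actually enters the kernel — independent of the training-set
    size.  ``sigma2 = None`` selects the median heuristic on hidden
    representations, scaled by ``sigma2_scale``.
    """

    M: int = 10
    fuzzifier: float = 1.5
    lam: float = 10.0
    mu: float | None = None
    sigma2: float | None = None
    eps_tol: float = 1e-6
    sample_size: int = 59
    seed: int = 0
    solver: str = "coreset"          # coreset | direct | baseline
    dual_ridge: float = 0.001
    sigma2_scale: float = 1.0
    fcm_tol: float = 1e-5
    fcm_max_iter: int = 300
    baseline_ridge: float = 1e-8

    def __post_init__(self) -> None:
        if self.solver not in ("coreset", "direct", "baseline"):
            raise ValueError(f"unknown solver {self.solver!r}")
        for name in ("M", "lam", "eps_tol", "dual_ridge", "sigma2_scale"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.mu is not None and self.mu <= 0:
            raise ValueError("mu must be positive")
        if self.sigma2 is not None and self.sigma2 <= 0:
            raise ValueError("sigma2 must be positive")


@dataclass
class Standardizer:
    """Per-column z-scoring constants estimated on the training set."""

    mean: np.ndarray
    std: np.ndarray

    @classmethod
    def fit(cls, X: np.ndarray) -> "Standardizer":
        mean = X.mean(axis=0)
        std = X.std(axis=0)
        std = np.where(std < 1e-12, 1.0, std)
        return cls(mean=mean, std=std)

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X, dtype=float) - self.mean) / self.std


@dataclass
class BinaryFastRBF:
    """A trained binary classifier with its kernel expansion."""

    hidden: HiddenLayer
    scaler: Standardizer
    support_Xtilde: np.ndarray   # hidden-space rows with nonzero expansion
    expansion: np.ndarray        # lambda * (alpha_i - alpha*_i) on supports
    lam: float
    mu: float
    sigma2: float
    pos_label: str
    neg_label: str
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.expansion.size == 0:
            raise ValueError("model has an empty expansion")
        if not np.isfinite(self.expansion).all():
            raise ValueError("expansion coefficients must be finite")

    def _hidden_rows(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.scaler.mean.size:
            raise ValueError(
                f"expected {self.scaler.mean.size} features, got {X.shape[1]}"
            )
        return hidden_map(self.hidden, self.scaler.transform(X))

    def decision_values(self, X: np.ndarray) -> np.ndarray:
        Xt = self._hidden_rows(X)
        return base_kernel(Xt, self.support_Xtilde, self.sigma2) @ self.expansion


@dataclass
class BaselineRBF:
    """Traditional RBF network: same hidden layer, least-squares weights."""

    hidden: HiddenLayer
    scaler: Standardizer
    weights: np.ndarray
    pos_label: str
    neg_label: str
    diagnostics: dict = field(default_factory=dict)

    def decision_values(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.scaler.mean.size:
            raise ValueError(
                f"expected {self.scaler.mean.size} features, got {X.shape[1]}"
            )
        return hidden_map(self.hidden, self.scaler.transform(X)) @ self.weights


def _median_sq_dist(Xt: np.ndarray, seed: int, cap: int = 2000) -> float:
    """Median pairwise squared distance on a seeded subsample (kernel bandwidth)."""
    from scipy.spatial.distance import pdist

    rng = np.random.default_rng(seed)
    if Xt.shape[0] > cap:
        Xt = Xt[rng.choice(Xt.shape[0], cap, replace=False)]
    d2 = pdist(Xt, "sqeuclidean")
    med = float(np.median(d2)) if d2.size else 0.0
    return med if med > 1e-12 else 1.0


def _two_class_arrays(
    table: FeatureTable, pos_label: str | None, neg_label: str | None
) -> tuple[np.ndarray, np.ndarray, str, str]:
    if table.labels is None:
        raise ValueError("training table has no labels")
    labels = table.labels.astype(str)
    present = sorted(set(labels))
    if len(present) != 2:
        raise ValueError(f"binary training needs exactly two classes, got {present}")
    if pos_label is None or neg_label is None:
        pos_label, neg_label = present
    if {pos_label, neg_label} != set(present):
        raise ValueError(
            f"labels {present} do not match requested pair ({pos_label}, {neg_label})"
        )
    y = np.where(labels == pos_label, 1.0, -1.0)
    return table.X, y, pos_label, neg_label


def _prepare_hidden(
    X: np.ndarray, cfg: TrainConfig
) -> tuple[Standardizer, HiddenLayer, np.ndarray]:
    scaler = Standardizer.fit(X)
    Z = scaler.transform(X)
    fcm = fcm_cluster(
        Z, cfg.M, fuzzifier=cfg.fuzzifier, tol=cfg.fcm_tol,
        max_iter=cfg.fcm_max_iter, seed=cfg.seed,
    )
    layer = build_hidden_layer(fcm, Z)
    return scaler, layer, hidden_map(layer, Z)


def train_binary(
    table: FeatureTable,
    cfg: TrainConfig,
    pos_label: str | None = None,
    neg_label: str | None = None,
) -> BinaryFastRBF | BaselineRBF:
    """Train one binary classifier according to ``cfg.solver``."""
    if cfg.solver == "baseline":
        return train_rbf_baseline(table, cfg, pos_label, neg_label)

    X, y, pos_label, neg_label = _two_class_arrays(table, pos_label, neg_label)
    n = X.shape[0]
    if n < cfg.M:
        raise ValueError(f"need at least M={cfg.M} samples, got {n}")
    scaler, layer, Xt = _prepare_hidden(X, cfg)

    sigma2 = cfg.sigma2
    if sigma2 is None:
        sigma2 = cfg.sigma2_scale * _median_sq_dist(Xt, cfg.seed)
    mu = cfg.mu if cfg.mu is not None else cfg.dual_ridge * cfg.lam / n

    problem = EpsQPProblem(Xtilde=Xt, y=y, lam=cfg.lam, mu=mu, sigma2=sigma2)
    if cfg.solver == "direct":
        solution = solve_dual_direct(problem)
        diagnostics = dict(solution.diagnostics)
    else:
        solution, coreset = solve_dual_coreset(
            problem,
            eps_tol=cfg.eps_tol,
            sample_size=cfg.sample_size,
            seed=cfg.seed,
        )
        diagnostics = dict(solution.diagnostics)
        diagnostics["radius_trace"] = [r for _, r in coreset.trace]

    support = np.flatnonzero(solution.expansion != 0.0)
    if support.size == 0:
        # alpha == alpha* everywhere is only possible in degenerate ties;
        # keep the largest-mass sample so the expansion stays non-empty
        support = np.array([int(np.argmax(solution.alpha + solution.alpha_star))])
    diagnostics.update(
        {"objective": solution.objective, "n_support": int(support.size), "n_train": n}
    )
    return BinaryFastRBF(
        hidden=layer,
        scaler=scaler,
        support_Xtilde=Xt[support],
        expansion=solution.expansion[support],
        lam=cfg.lam,
        mu=mu,
        sigma2=sigma2,
        pos_label=pos_label,
        neg_label=neg_label,
        diagnostics=diagnostics,
    )


def train_rbf_baseline(
    table: FeatureTable,
    cfg: TrainConfig,
    pos_label: str | None = None,
    neg_label: str | None = None,
) -> BaselineRBF:
    """Traditional RBF comparator: FCM hidden layer + regularized least squares.

    The output weights solve (Xt'Xt + ridge I) w = Xt'y — the fixed point
    of gradient descent on the squared output error.
    """
    X, y, pos_label, neg_label = _two_class_arrays(table, pos_label, neg_label)
    if X.shape[0] < cfg.M:
        raise ValueError(f"need at least M={cfg.M} samples, got {X.shape[0]}")
    scaler, layer, Xt = _prepare_hidden(X, cfg)
    A = Xt.T @ Xt + cfg.baseline_ridge * np.eye(Xt.shape[1])
    w = np.linalg.solve(A, Xt.T @ y)
    return BaselineRBF(
        hidden=layer,
        scaler=scaler,
        weights=w,
        pos_label=pos_label,
        neg_label=neg_label,
        diagnostics={"solver": "baseline", "n_train": int(X.shape[0])},
    )


def decision_value(model, X: np.ndarray) -> np.ndarray:
    """Raw decision values f(x); positive means ``model.pos_label``."""
    return model.decision_values(X)


def predict_binary(model, X: np.ndarray) -> np.ndarray:
    """Sign rule: f > 0 -> positive label, f < 0 -> negative, f == 0 -> positive."""
    f = decision_value(model, X)
    return np.where(f >= 0.0, model.pos_label, model.neg_label).astype(object)


@dataclass
class OvOModel:
    """Three pairwise classifiers plus the voting rule."""

    clf_AB: BinaryFastRBF | BaselineRBF   # liver (pos) vs kidney
    clf_AC: BinaryFastRBF | BaselineRBF   # liver (pos) vs other
    clf_BC: BinaryFastRBF | BaselineRBF   # kidney (pos) vs other
    tie_break: str = "margin-then-priority"

    def __post_init__(self) -> None:
        pairs = {
            (self.clf_AB.pos_label, self.clf_AB.neg_label),
            (self.clf_AC.pos_label, self.clf_AC.neg_label),
            (self.clf_BC.pos_label, self.clf_BC.neg_label),
        }
        if pairs != set(OVO_PAIRS):
            raise ValueError(f"pairwise classifiers must cover {OVO_PAIRS}, got {pairs}")

    @property
    def classifiers(self):
        return (self.clf_AB, self.clf_AC, self.clf_BC)


def train_ovo(table: FeatureTable, cfg: TrainConfig) -> OvOModel:
    """Train the three pairwise tissue classifiers on label-restricted subsets."""
    if table.labels is None:
        raise ValueError("training table has no labels")
    counts = table.label_counts()
    for cls in ("liver", "kidney", "other"):
        if counts.get(cls, 0) == 0:
            raise ValueError(f"missing class: {cls}")
    models = []
    for k, (pos, neg) in enumerate(OVO_PAIRS):
        sub = table.restrict_labels([pos, neg])
        pair_cfg = TrainConfig(**{**asdict(cfg), "seed": (cfg.seed * 3 + k) % (2**31)})
        models.append(train_binary(sub, pair_cfg, pos_label=pos, neg_label=neg))
    return OvOModel(*models)


def predict_ovo(model: OvOModel, X: np.ndarray) -> np.ndarray:
    """One-vs-one voting over {liver, kidney, other}.

    Each pairwise winner receives one vote; the class with the most votes
    wins.  A cyclic 1-1-1 tie is resolved by the largest sum of absolute
    decision values over the two classifiers involving each class, and a
    residual tie by the fixed priority liver > kidney > other.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    m = X.shape[0]
    f_ab = model.clf_AB.decision_values(X)
    f_ac = model.clf_AC.decision_values(X)
    f_bc = model.clf_BC.decision_values(X)

    votes = {cls: np.zeros(m) for cls in _TIE_PRIORITY}
    votes["liver"] += (f_ab >= 0.0)
    votes["kidney"] += (f_ab < 0.0)
    votes["liver"] += (f_ac >= 0.0)
    votes["other"] += (f_ac < 0.0)
    votes["kidney"] += (f_bc >= 0.0)
    votes["other"] += (f_bc < 0.0)

    margins = {
        "liver": np.abs(f_ab) + np.abs(f_ac),
        "kidney": np.abs(f_ab) + np.abs(f_bc),
        "other": np.abs(f_ac) + np.abs(f_bc),
    }

    vote_mat = np.stack([votes[c] for c in _TIE_PRIORITY], axis=1)
    margin_mat = np.stack([margins[c] for c in _TIE_PRIORITY], axis=1)
    out = np.empty(m, dtype=object)
    best_votes = vote_mat.max(axis=1, keepdims=True)
    is_best = vote_mat == best_votes
    # rank by (vote, margin) with earlier priority winning exact ties
    score = np.where(is_best, margin_mat, -np.inf)
    winner = np.argmax(score, axis=1)  # argmax takes the first max -> priority order
    for i, w in enumerate(winner):
        out[i] = _TIE_PRIORITY[w]
    return out


def accuracy(pred, truth) -> float:
    """Fraction of correctly classified samples."""
    pred = np.asarray(pred, dtype=object)
    truth = np.asarray(truth, dtype=object)
    if pred.shape != truth.shape:
        raise ValueError("prediction/truth length mismatch")
    if pred.size == 0:
        raise ValueError("empty input")
    return float((pred.astype(str) == truth.astype(str)).mean())


def _pack_binary(prefix: str, model: BinaryFastRBF | BaselineRBF, arrays: dict, meta: dict):
    meta[prefix] = {
        "kind": "baseline" if isinstance(model, BaselineRBF) else "fastrbf",
        "pos_label": model.pos_label,
        "neg_label": model.neg_label,
        "diagnostics": {
            k: v for k, v in model.diagnostics.items() if not isinstance(v, np.ndarray)
        },
    }
    arrays[f"{prefix}_centers"] = model.hidden.centers
    arrays[f"{prefix}_widths"] = model.hidden.widths
    arrays[f"{prefix}_scaler_mean"] = model.scaler.mean
    arrays[f"{prefix}_scaler_std"] = model.scaler.std
    if isinstance(model, BaselineRBF):
        arrays[f"{prefix}_weights"] = model.weights
    else:
        arrays[f"{prefix}_support"] = model.support_Xtilde
        arrays[f"{prefix}_expansion"] = model.expansion
        meta[prefix]["lam"] = model.lam
        meta[prefix]["mu"] = model.mu
        meta[prefix]["sigma2"] = model.sigma2


def _unpack_binary(prefix: str, arrays, meta: dict):
    layer = HiddenLayer(arrays[f"{prefix}_centers"], arrays[f"{prefix}_widths"])
    scaler = Standardizer(arrays[f"{prefix}_scaler_mean"], arrays[f"{prefix}_scaler_std"])
    info = meta[prefix]
    if info["kind"] == "baseline":
        return BaselineRBF(
            hidden=layer, scaler=scaler, weights=arrays[f"{prefix}_weights"],
            pos_label=info["pos_label"], neg_label=info["neg_label"],
            diagnostics=info.get("diagnostics", {}),
        )
    return BinaryFastRBF(
        hidden=layer, scaler=scaler,
        support_Xtilde=arrays[f"{prefix}_support"],
        expansion=arrays[f"{prefix}_expansion"],
        lam=info["lam"], mu=info["mu"], sigma2=info["sigma2"],
        pos_label=info["pos_label"], neg_label=info["neg_label"],
        diagnostics=info.get("diagnostics", {}),
    )


def save_ovo(model: OvOModel, path) -> None:
    """Serialize an OvO model: one archive with JSON metadata + arrays."""
    arrays: dict = {}
    meta: dict = {"schema_version": MODEL_SCHEMA_VERSION, "tie_break": model.tie_break}
    for prefix, clf in zip(("ab", "ac", "bc"), model.classifiers):
        _pack_binary(prefix, clf, arrays, meta)
    arrays["meta_json"] = np.frombuffer(
        json.dumps(meta).encode("utf-8"), dtype=np.uint8
    )
    np.savez(path, **arrays)


def load_ovo(path) -> OvOModel:
    with np.load(path, allow_pickle=False) as arrays:
        meta = json.loads(bytes(arrays["meta_json"].tobytes()).decode("utf-8"))
        if meta.get("schema_version") != MODEL_SCHEMA_VERSION:
            raise ValueError(f"unsupported model schema: {meta.get('schema_version')}")
        clfs = [_unpack_binary(p, arrays, meta) for p in ("ab", "ac", "bc")]
    return OvOModel(*clfs, tie_break=meta["tie_break"])
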