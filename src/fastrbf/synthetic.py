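"""Synthetic abdominal phantoms and feature-space fixtures.

The phantom emulates the statistical structure the feature pipeline
assumes of Dixon MR slices: four channels whose intensities are
tissue-dependent means plus i.i.d. Gaussian noise, with elliptical
liver/kidney shapes on an "other tissue" background.  Channel means are
chosen so every tissue pair is well separated on at least two of the
four channels and overlaps on the rest, which places default test
accuracy in the mid-0.9 range rather than at a trivial 1.0.

All randomness in an operation flows from its single integer seed
through one ``numpy.random.default_rng`` stream; draw order is fixed
(channels in fat, water, ip, op order).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .features import CHANNEL_NAMES, MRVolumeSet, ROI, FeatureTable, LABEL_PALETTE, extract_features

__all__ = [
    "Ellipse",
    "PhantomSpec",
    "default_phantom_spec",
    "generate_phantom",
    "generate_blobs",
    "default_benchmark",
    "BENCHMARK_TEST_SIZE",
]

#: Fixed hold-out size used by the phantom benchmark when the pool allows.
BENCHMARK_TEST_SIZE = 16896

#: Per-tissue mean intensity of each channel (arbitrary MR units).
#: Contrasts are moderate relative to the default noise so that every
#: tissue pair separates clearly on two channels (fat and water) while
#: overlapping on the in-phase/opposed-phase pair.
DEFAULT_CHANNEL_MEANS = {
    ("liver", "fat"): 37.7, ("liver", "water"): 64.0,
    ("liver", "ip"): 80.4, ("liver", "op"): 53.1,
    ("kidney", "fat"): 35.9, ("kidney", "water"): 66.9,
    ("kidney", "ip"): 79.6, ("kidney", "op"): 54.2,
    ("other", "fat"): 44.5, ("other", "water"): 57.1,
    ("other", "ip"): 80.0, ("other", "op"): 50.7,
}

DEFAULT_NOISE_SD = 10.0


@dataclass(frozen=True)
class Ellipse:
    """Rotated ellipse in pixel coordinates (row/col center, semi-axes)."""

    label: str
    center: tuple[float, float]      # (row, col)
    axes: tuple[float, float]        # semi-axes (along rotated row/col)
    angle_deg: float = 0.0

    def mask(self, shape: tuple[int, int]) -> np.ndarray:
        rr, cc = np.mgrid[0:shape[0], 0:shape[1]]
        th = math.radians(self.angle_deg)
        dr, dc = rr - self.center[0], cc - self.center[1]
        u = math.cos(th) * dr + math.sin(th) * dc
        v = -math.sin(th) * dr + math.cos(th) * dc
        return (u / self.axes[0]) ** 2 + (v / self.axes[1]) ** 2 <= 1.0

    def fits_in(self, shape: tuple[int, int]) -> bool:
        reach = max(self.axes)
        r, c = self.center
        return (reach <= r <= shape[0] - 1 - reach) and (reach <= c <= shape[1] - 1 - reach)


@dataclass
class PhantomSpec:
    """Geometry, intensity and noise description of one phantom case."""

    height: int = 128
    width: int = 128
    organs: list[Ellipse] = field(default_factory=list)
    channel_means: dict = field(default_factory=lambda: dict(DEFAULT_CHANNEL_MEANS))
    noise_sd: float = DEFAULT_NOISE_SD
    pixel_spacing: tuple[float, float] = (1.5, 1.5)
    seed: int = 0
    case_id: str = "phantom"

    def __post_init__(self) -> None:
        if self.height < 3 or self.width < 3:
            raise ValueError("phantom must be at least 3x3")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


def default_phantom_spec(seed: int = 0, noise_sd: float = DEFAULT_NOISE_SD) -> PhantomSpec:
    """Default 128x128 case: one large liver, two small kidneys."""
    organs = [
        Ellipse("liver", center=(45.0, 48.0), axes=(30.0, 26.0), angle_deg=20.0),
        Ellipse("kidney", center=(98.0, 32.0), axes=(11.0, 7.0), angle_deg=-15.0),
        Ellipse("kidney", center=(98.0, 92.0), axes=(11.0, 7.0), angle_deg=15.0),
    ]
    return PhantomSpec(organs=organs, noise_sd=noise_sd, seed=seed)


def generate_phantom(spec: PhantomSpec) -> tuple[MRVolumeSet, np.ndarray]:
    """Rasterize a phantom case: four noisy channels plus a truth mask.

    Returns the channel set and an integer label mask using the fixed
    palette (other=0, liver=1, kidney=2).
    """
    shape = (spec.height, spec.width)
    for organ in spec.organs:
        if organ.label not in ("liver", "kidney"):
            raise ValueError(f"unknown organ label {organ.label!r}")
        if not organ.fits_in(shape):
            raise ValueError(f"organ {organ} does not fit inside image {shape}")

    masks = [(organ.label, organ.mask(shape)) for organ in spec.organs]
    for a in range(len(masks)):
        for b in range(a + 1, len(masks)):
            if (masks[a][1] & masks[b][1]).any():
                raise ValueError(
                    f"overlapping organ ellipses: {spec.organs[a]} and {spec.organs[b]}"
                )

    label = np.full(shape, LABEL_PALETTE["other"], dtype=np.uint8)
    tissue = np.full(shape, "other", dtype=object)
    for name, m in masks:
        label[m] = LABEL_PALETTE[name]
        tissue[m] = name

    rng = np.random.default_rng(spec.seed)
    channels = {}
    for ch in CHANNEL_NAMES:
        means = np.zeros(shape)
        for t in ("other", "liver", "kidney"):
            means[tissue == t] = spec.channel_means[(t, ch)]
        noise = rng.normal(0.0, spec.noise_sd, size=shape) if spec.noise_sd > 0 else 0.0
        channels[ch] = means + noise

    vol = MRVolumeSet(channels, spec.pixel_spacing, case_id=spec.case_id)
    return vol, label


def generate_blobs(
    n_per_class: int,
    d: int,
    centers: np.ndarray,
    sd: float,
    seed: int = 0,
    labels: list[str] | None = None,
) -> FeatureTable:
    """Isotropic Gaussian clusters as a labelled feature table.

    ``centers`` is (k, d) with k >= 2 classes.  Features occupy the first
    ``d`` of the six table columns; any remaining columns are zero, so
    the table stays a valid six-dimensional exchange object.
    """
    centers = np.atleast_2d(np.asarray(centers, dtype=float))
    k = centers.shape[0]
    if k < 2:
        raise ValueError("need at least 2 classes")
    if centers.shape[1] != d or d < 1 or d > 6:
        raise ValueError("centers must be (k, d) with 1 <= d <= 6")
    rng = np.random.default_rng(seed)
    if labels is None:
        labels = [f"c{i}" for i in range(k)]
    if len(labels) != k:
        raise ValueError("one label per class required")
    X = np.zeros((n_per_class * k, 6))
    lab = np.empty(n_per_class * k, dtype=object)
    for i in range(k):
        rows = slice(i * n_per_class, (i + 1) * n_per_class)
        X[rows, :d] = centers[i] + rng.normal(0.0, sd, size=(n_per_class, d))
        lab[rows] = labels[i]
    return FeatureTable(X, lab, provenance={"generator": "blobs", "seed": seed})


def _jittered_case_spec(rng: np.random.Generator, case_index: int, noise_sd: float) -> PhantomSpec:
    """Per-case geometry jitter so the benchmark pool spans several anatomies."""
    base = default_phantom_spec()
    for _ in range(50):
        organs = []
        for organ in base.organs:
            organs.append(
                Ellipse(
                    organ.label,
                    center=(
                        organ.center[0] + rng.uniform(-3.0, 3.0),
                        organ.center[1] + rng.uniform(-3.0, 3.0),
                    ),
                    axes=(
                        organ.axes[0] + rng.uniform(-2.0, 2.0),
                        organ.axes[1] + rng.uniform(-2.0, 2.0),
                    ),
                    angle_deg=organ.angle_deg + rng.uniform(-5.0, 5.0),
                )
            )
        case_seed = int(rng.integers(0, 2**31 - 1))
        spec = replace(
            base,
            organs=organs,
            noise_sd=noise_sd,
            seed=case_seed,
            case_id=f"case{case_index}",
        )
        shape = (spec.height, spec.width)
        masks = [o.mask(shape) for o in organs]
        ok = all(o.fits_in(shape) for o in organs) and not any(
            (masks[a] & masks[b]).any()
            for a in range(len(masks))
            for b in range(a + 1, len(masks))
        )
        if ok:
            return spec
    raise RuntimeError("could not draw a valid jittered phantom geometry")


def default_benchmark(
    n_total: int,
    seed: int = 0,
    noise_sd: float = DEFAULT_NOISE_SD,
) -> tuple[FeatureTable, FeatureTable]:
    """Phantom-derived train/test split of the standard benchmark.

    Generates enough jittered 128x128 phantom cases to hold ``n_total``
    training rows plus the fixed hold-out, extracts per-pixel features
    from each full case, pools them, and samples ``n_total`` training
    rows uniformly without replacement together with a disjoint test set
    of 16,896 rows (20% of the pool if fewer remain).
    """
    if n_total < 600:
        raise ValueError("n_total must be at least 600")
    rng = np.random.default_rng(seed)
    per_case = 128 * 128
    n_cases = max(5, math.ceil((n_total + BENCHMARK_TEST_SIZE) / per_case))
    tables = []
    for k in range(n_cases):
        spec = _jittered_case_spec(rng, k, noise_sd)
        vol, mask = generate_phantom(spec)
        roi = ROI(0, 0, spec.height, spec.width)
        tables.append(extract_features(vol, roi, mask))
    X = np.concatenate([t.X for t in tables])
    labels = np.concatenate([t.labels for t in tables])
    pool = FeatureTable(X, labels, provenance={"generator": "benchmark", "seed": seed})

    perm = rng.permutation(pool.n)
    if pool.n - n_total < 1:
        raise ValueError("pool too small for the requested training size")
    train_idx = perm[:n_total]
    rest = perm[n_total:]
    test_size = BENCHMARK_TEST_SIZE if rest.size >= BENCHMARK_TEST_SIZE else max(
        1, min(rest.size, int(0.2 * pool.n))
    )
    test_idx = rest[:test_size]
    return pool.subset(train_idx), pool.subset(test_idx)
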