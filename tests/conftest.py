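from __future__ import annotations

import numpy as np
import pytest

from fastrbf.features import MRVolumeSet, ROI
from fastrbf.qp_direct import EpsQPProblem
from fastrbf.rbf_layer import build_hidden_layer, fcm_cluster, hidden_map
from fastrbf.synthetic import generate_blobs


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_volume():
    """Four 12x12 channels with distinct deterministic content."""
    rng = np.random.default_rng(7)
    channels = {
        name: 50.0 + 10.0 * k + rng.normal(0, 3.0, size=(12, 12))
        for k, name in enumerate(("fat", "water", "ip", "op"))
    }
    return MRVolumeSet(channels, pixel_spacing=(1.5, 2.0), case_id="fixture")


@pytest.fixture
def blob_table():
    """Two well-separated Gaussian classes in the first two feature columns."""
    return generate_blobs(
        100, 2, centers=[[0.0, 0.0], [10.0, 10.0]], sd=1.0, seed=5,
        labels=["liver", "other"],
    )


def make_problem(n=40, seed=0, lam=2.0, mu=None, sigma2=None, M=6, overlap=2.0):
    """Random binary hidden-space problem for the dual solvers."""
    rng = np.random.default_rng(seed)
    half = n // 2
    X = np.concatenate([
        rng.normal(0.0, 1.0, size=(half, 3)),
        rng.normal(overlap, 1.0, size=(n - half, 3)),
    ])
    y = np.concatenate([np.ones(half), -np.ones(n - half)])
    fcm = fcm_cluster(X, M, fuzzifier=1.5, seed=seed)
    layer = build_hidden_layer(fcm, X)
    Xt = hidden_map(layer, X)
    if mu is None:
        mu = 1e-3 * lam / n
    if sigma2 is None:
        sigma2 = 0.5
    return EpsQPProblem(Xtilde=Xt, y=y, lam=lam, mu=mu, sigma2=sigma2)


@pytest.fixture
def dual_problem():
    return make_problem()


@pytest.fixture
def roi_4x4():
    return ROI(2, 3, 4, 4)
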