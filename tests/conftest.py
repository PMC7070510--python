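import numpy as np
import pytest

from smileasym import (
    CohortSpec,
    FiducialSet,
    LandmarkSet,
    default_region_map,
    template_face,
)


@pytest.fixture
def template() -> LandmarkSet:
    return template_face()


@pytest.fixture
def region_map():
    return default_region_map()


@pytest.fixture
def fiducials() -> FiducialSet:
    return FiducialSet()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def random_similarity(rng: np.random.Generator, max_deg: float = 180.0):
    """A random proper similarity transform (R, t, s) for recovery tests."""
    from scipy.spatial.transform import Rotation

    R = Rotation.random(random_state=rng).as_matrix()
    t = rng.uniform(-50, 50, 3)
    s = rng.uniform(0.8, 1.25)
    return R, t, s


def weighted_objective(P, Q, w, R, t, s) -> float:
    """The registration objective Σ wᵢ‖s·R·pᵢ + t − qᵢ‖²."""
    resid = s * (P @ R.T) + t - Q
    return float((w * (resid**2).sum(axis=1)).sum())


def brute_force_min_objective(P, Q, w, n_rotations=10_000, seed=0) -> float:
    """Independent oracle: best objective over sampled rotations.

    For each sampled rotation the translation and (positive) scale are set
    to their closed-form optima, so the only approximation is the rotation
    grid.  The SVD solution must never do worse than this minimum.
    """
    from scipy.spatial.transform import Rotation

    Rs = Rotation.random(n_rotations, random_state=seed).as_matrix()
    wsum = w.sum()
    pbar = (w[:, None] * P).sum(0) / wsum
    qbar = (w[:, None] * Q).sum(0) / wsum
    X = P - pbar
    Y = Q - qbar
    RX = np.einsum("rij,kj->rki", Rs, X)
    num = np.einsum("rki,k,ki->r", RX, w, Y)
    den = (w * (X**2).sum(1)).sum()
    s = np.maximum(num / den, 1e-9)
    obj = np.einsum(
        "rk,k->r", ((s[:, None, None] * RX - Y) ** 2).sum(2), w
    )
    return float(obj.min())


@pytest.fixture
def small_cohort_spec() -> CohortSpec:
    return CohortSpec(n_subjects=4, frames_per_condition=6, seed=11)
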