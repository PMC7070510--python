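"""Fiducial-anchored rigid-body + scale registration of landmark sets.

Smile-expression frames are registered onto the subject's neutral
reference using only expression-stable fiducial landmarks (nose bridge and
inner eye corners by default), so that subsequent per-landmark
displacements measure expression, not head pose.  The solver is the
weighted least-squares similarity transform: rotation from the SVD of the
weighted cross-covariance of centred fiducials with the determinant
correction diag(1, 1, det(VUᵀ)) that excludes reflections, translation
t = q̄ − s·R·p̄, and the least-squares (Umeyama) scale.  It minimises

    Σᵢ wᵢ ‖ s·R·pᵢ + t − qᵢ ‖²

over proper rotations R, translations t and (optionally) uniform scale s.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .face import FiducialSet, LandmarkSet, validate_landmark_set

__all__ = [
    "AlignmentResult",
    "DegenerateFiducialsError",
    "weighted_centroids",
    "solve_rigid_transform",
    "apply_transform",
    "batch_align",
    "alignment_results_to_tsv",
]

logger = logging.getLogger(__name__)

_ORTHO_TOL = 1e-9

#: Frames below this detector confidence are excluded from alignment.
DEFAULT_CONFIDENCE_THRESHOLD = 0.75


class DegenerateFiducialsError(ValueError):
    """Fiducial configuration too degenerate to determine a rotation."""


@dataclass(frozen=True)
class AlignmentResult:
    """A solved source→target similarity transform and its fit quality.

    Attributes
    ----------
    rotation : (3, 3) ndarray
        Proper rotation matrix (det = +1).
    translation : (3,) ndarray, mm
    scale : float
        Uniform scale factor (1.0 when scaling is disabled).
    fiducial_residuals : (k,) ndarray, mm
        Per-fiducial Euclidean distance after the transform.
    mean_residual : float, mm
    frame_id : int
        Frame the transform was solved for (-1 if synthetic/unspecified).
    """

    rotation: np.ndarray
    translation: np.ndarray
    scale: float
    fiducial_residuals: np.ndarray
    mean_residual: float
    frame_id: int = -1

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=float)
        if np.abs(R.T @ R - np.eye(3)).max() > 1e-6:
            raise ValueError("rotation is not orthogonal")
        if abs(np.linalg.det(R) - 1.0) > 1e-6:
            raise ValueError("rotation determinant is not +1")
        if not self.scale > 0:
            raise ValueError("scale must be positive")
        object.__setattr__(self, "rotation", R)
        object.__setattr__(
            self, "translation", np.asarray(self.translation, dtype=float)
        )
        object.__setattr__(
            self,
            "fiducial_residuals",
            np.asarray(self.fiducial_residuals, dtype=float),
        )

    @classmethod
    def identity(cls, frame_id: int = -1) -> "AlignmentResult":
        return cls(np.eye(3), np.zeros(3), 1.0, np.zeros(0), 0.0, frame_id)


def weighted_centroids(
    source: LandmarkSet, target: LandmarkSet, fid: FiducialSet
) -> tuple[np.ndarray, np.ndarray]:
    """Weighted centroids p̄, q̄ of the fiducial points of both sets."""
    idx = fid.index_array
    w = fid.weight_array
    p = source.points[idx]
    q = target.points[idx]
    wsum = w.sum()
    return (w[:, None] * p).sum(0) / wsum, (w[:, None] * q).sum(0) / wsum


def _solve_core(
    P: np.ndarray, Q: np.ndarray, w: np.ndarray, with_scale: bool
) -> tuple[np.ndarray, np.ndarray, float]:
    """Weighted similarity fit of fiducial arrays P → Q (k×3 each)."""
    wsum = w.sum()
    p_bar = (w[:, None] * P).sum(0) / wsum
    q_bar = (w[:, None] * Q).sum(0) / wsum
    X = P - p_bar  # centred source, rows
    Y = Q - q_bar
    C = X.T @ (w[:, None] * Y)  # 3×3 cross-covariance, source×target
    U, S, Vt = np.linalg.svd(C)
    V = Vt.T
    d = np.sign(np.linalg.det(V @ U.T))
    if d == 0:  # numerically rank-deficient beyond repair
        d = 1.0
    D = np.diag([1.0, 1.0, d])
    R = V @ D @ U.T
    if with_scale:
        var_p = (w * (X**2).sum(1)).sum()
        if var_p <= 0:
            raise DegenerateFiducialsError("zero-variance source fiducials")
        s = float((S * np.diag(D)).sum() / var_p)
        if s <= 0:
            raise DegenerateFiducialsError("non-positive least-squares scale")
    else:
        s = 1.0
    t = q_bar - s * (R @ p_bar)
    return R, t, s


def solve_rigid_transform(
    source: LandmarkSet,
    target: LandmarkSet,
    fid: FiducialSet | None = None,
    with_scale: bool = True,
) -> AlignmentResult:
    """Solve the weighted least-squares similarity transform source → target.

    Uses only the fiducial landmarks.  Requires at least three
    non-collinear fiducials; raises :class:`DegenerateFiducialsError` for
    collinear configurations (the in-plane rotation would be undetermined).
    """
    fid = fid or FiducialSet()
    if len(fid.indexes) < 3:
        raise ValueError("at least 3 fiducial points are required")
    idx = fid.index_array
    w = fid.weight_array
    P = source.points[idx]
    Q = target.points[idx]
    for name, A in (("source", P), ("target", Q)):
        centred = A - A.mean(0)
        if np.linalg.matrix_rank(centred, tol=1e-9 * max(1.0, np.abs(A).max())) < 2:
            raise DegenerateFiducialsError(
                f"{name} fiducials are collinear; rotation is undetermined"
            )
    R, t, s = _solve_core(P, Q, w, with_scale)
    res = np.linalg.norm((s * (P @ R.T)) + t - Q, axis=1)
    return AlignmentResult(R, t, s, res, float(res.mean()), source.frame_id)


def apply_transform(ls: LandmarkSet, ar: AlignmentResult) -> LandmarkSet:
    """Map every landmark (all 68) by x ↦ s·R·x + t; ids preserved."""
    pts = ar.scale * (ls.points @ ar.rotation.T) + ar.translation
    return ls.with_points(pts)


def _batch_solve_arrays(
    frames: np.ndarray,
    reference: np.ndarray,
    fid: FiducialSet,
    with_scale: bool = True,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Vectorised solver: frames (F, 68, 3) each registered onto reference.

    Returns (aligned_points, R, t, s, mean_residuals).  Stacked 3×3 SVDs
    keep per-frame cost trivial, which matters when a cohort contributes
    hundreds of thousands of frame pairs.
    """
    idx = fid.index_array
    w = fid.weight_array
    wsum = w.sum()
    P = frames[:, idx, :]  # (F, k, 3) source fiducials
    Q = reference[idx]  # (k, 3)
    p_bar = (w[None, :, None] * P).sum(1) / wsum  # (F, 3)
    q_bar = (w[:, None] * Q).sum(0) / wsum  # (3,)
    X = P - p_bar[:, None, :]
    Y = Q - q_bar
    C = np.einsum("fki,k,kj->fij", X, w, Y)  # (F, 3, 3)
    U, S, Vt = np.linalg.svd(C)
    V = np.swapaxes(Vt, 1, 2)
    det = np.linalg.det(np.einsum("fij,fkj->fik", V, U))
    d3 = np.where(det < 0, -1.0, 1.0)
    # R = V @ diag(1,1,d3) @ U^T
    Vc = V.copy()
    Vc[:, :, 2] *= d3[:, None]
    R = np.einsum("fij,fkj->fik", Vc, U)
    if with_scale:
        var_p = np.einsum("fki,k,fki->f", X, w, X)
        s = (S[:, 0] + S[:, 1] + d3 * S[:, 2]) / var_p
    else:
        s = np.ones(len(frames))
    t = q_bar[None, :] - s[:, None] * np.einsum("fij,fj->fi", R, p_bar)
    aligned = s[:, None, None] * np.einsum("fij,fkj->fki", R, frames) + t[:, None, :]
    res = np.linalg.norm(aligned[:, idx, :] - Q[None, :, :], axis=2)
    return aligned, R, t, s, res.mean(axis=1)


def batch_align(
    frames: Sequence[LandmarkSet],
    reference: LandmarkSet,
    fid: FiducialSet | None = None,
    with_scale: bool = True,
    confidence_threshold: float = DEFAULT_CONFIDENCE_THRESHOLD,
) -> list[tuple[LandmarkSet, AlignmentResult]]:
    """Independently register each frame onto the neutral reference.

    Frames whose detector flagged failure (``success=False``) or whose
    confidence falls below ``confidence_threshold`` are skipped and logged.
    Returns (aligned frame, alignment result) pairs for the kept frames.
    """
    frames = list(frames)
    if not frames:
        raise ValueError("empty frame sequence")
    validate_landmark_set(reference)
    fid = fid or FiducialSet()
    kept = []
    for f in frames:
        validate_landmark_set(f)
        if not f.success or f.confidence < confidence_threshold:
            logger.info(
                "skipping frame %d (success=%s, confidence=%.3f)",
                f.frame_id, f.success, f.confidence,
            )
            continue
        kept.append(f)
    if not kept:
        return []
    stack = np.stack([f.points for f in kept])
    aligned, R, t, s, mean_res = _batch_solve_arrays(
        stack, reference.points, fid, with_scale
    )
    idx = fid.index_array
    out = []
    for i, f in enumerate(kept):
        res = np.linalg.norm(aligned[i, idx, :] - reference.points[idx], axis=1)
        ar = AlignmentResult(R[i], t[i], float(s[i]), res, float(mean_res[i]),
                             f.frame_id)
        out.append((f.with_points(aligned[i]), ar))
    return out


def alignment_results_to_tsv(results: Iterable[AlignmentResult], path) -> None:
    """Write per-frame transforms as TSV (frame_id, R row-major, t, s, residual)."""
    cols = (
        ["frame_id"]
        + [f"r{i}{j}" for i in range(3) for j in range(3)]
        + ["tx", "ty", "tz", "scale", "mean_residual"]
    )
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for ar in results:
            row = (
                [str(ar.frame_id)]
                + [f"{v:.12g}" for v in ar.rotation.ravel()]
                + [f"{v:.12g}" for v in ar.translation]
                + [f"{ar.scale:.12g}", f"{ar.mean_residual:.12g}"]
            )
            fh.write("\t".join(row) + "\n")
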