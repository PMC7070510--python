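"""Domain types for 68-point 3D facial landmark analysis.

The fixed topology follows the iBUG-68 annotation scheme that OpenFace
emits: jaw outline 0-16, eyebrows 17-26, nose 27-35, eyes 36-47, mouth
48-67.  "Left" and "right" are the *subject's* anatomical sides (a frontal,
non-mirrored camera puts the subject's left on image-right); the map is
configurable so observer-perspective data can be flipped.

Landmark coordinates are millimetres in the camera coordinate system.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import yaml

__all__ = [
    "N_LANDMARKS",
    "DEFAULT_FIDUCIAL_INDEXES",
    "LandmarkSet",
    "FiducialSet",
    "RegionMap",
    "LandmarkValidationError",
    "default_region_map",
    "validate_landmark_set",
    "mirror_index",
]

N_LANDMARKS = 68

#: Expression-stable anchor landmarks: nose bridge (27-30) and the two
#: inner eye corners (39 right, 42 left).
DEFAULT_FIDUCIAL_INDEXES = (27, 28, 29, 30, 39, 42)


class LandmarkValidationError(ValueError):
    """A landmark set violates one of its structural invariants."""


@dataclass(frozen=True)
class LandmarkSet:
    """One frame's 68 labelled 3D points.

    Parameters
    ----------
    frame_id : int
        Frame index within its recording.
    points : (68, 3) ndarray
        Landmark coordinates in mm, camera coordinate system.
    confidence : float
        Detector confidence in [0, 1].
    success : bool
        Detector success flag.
    """

    frame_id: int
    points: np.ndarray
    confidence: float = 1.0
    success: bool = True

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        object.__setattr__(self, "points", pts)

    def with_points(self, points: np.ndarray) -> "LandmarkSet":
        return LandmarkSet(self.frame_id, points, self.confidence, self.success)


def validate_landmark_set(ls: LandmarkSet) -> LandmarkSet:
    """Return ``ls`` unchanged if all invariants hold, else raise.

    Checks, in order: point-array shape (68, 3), coordinate finiteness,
    confidence in [0, 1].
    """
    pts = ls.points
    if pts.shape != (N_LANDMARKS, 3):
        raise LandmarkValidationError(
            f"expected {N_LANDMARKS} 3D points, got array of shape {pts.shape}"
        )
    if not np.all(np.isfinite(pts)):
        bad = int(np.argwhere(~np.isfinite(pts))[0, 0])
        raise LandmarkValidationError(f"non-finite coordinate at landmark {bad}")
    if not (0.0 <= ls.confidence <= 1.0):
        raise LandmarkValidationError(
            f"confidence {ls.confidence!r} outside [0, 1]"
        )
    return ls


@dataclass(frozen=True)
class FiducialSet:
    """Anchor landmarks and weights for rigid registration."""

    indexes: tuple = DEFAULT_FIDUCIAL_INDEXES
    weights: tuple = None

    def __post_init__(self) -> None:
        idx = tuple(int(i) for i in self.indexes)
        if len(idx) == 0:
            raise ValueError("fiducial set must not be empty")
        if len(set(idx)) != len(idx):
            raise ValueError("fiducial indexes must be unique")
        if any(i < 0 or i >= N_LANDMARKS for i in idx):
            raise ValueError("fiducial index outside 0..67")
        w = self.weights
        w = tuple(1.0 for _ in idx) if w is None else tuple(float(x) for x in w)
        if len(w) != len(idx):
            raise ValueError("weights length must match indexes")
        if any(x <= 0 for x in w):
            raise ValueError("fiducial weights must be strictly positive")
        object.__setattr__(self, "indexes", idx)
        object.__setattr__(self, "weights", w)

    @property
    def index_array(self) -> np.ndarray:
        return np.asarray(self.indexes, dtype=int)

    @property
    def weight_array(self) -> np.ndarray:
        return np.asarray(self.weights, dtype=float)

    def to_dict(self) -> dict:
        return {"indexes": list(self.indexes), "weights": list(self.weights)}

    @classmethod
    def from_dict(cls, d: Mapping) -> "FiducialSet":
        return cls(tuple(d["indexes"]), tuple(d.get("weights") or []) or None)


# --- iBUG-68 topology ------------------------------------------------------

_PRIMITIVE = {
    "outline": range(0, 17),
    "eyebrow_right": range(17, 22),
    "eyebrow_left": range(22, 27),
    "eye_right": range(36, 42),
    "eye_left": range(42, 48),
    "nose": range(27, 36),
    "mouth": range(48, 68),
}

# Subject-perspective hemiface assignment; strictly midline landmarks
# (chin tip 8, nose bridge 27-30, nose base centre 33, mid-lip 51/57/62/66)
# belong to neither side so left/right cardinalities stay equal.
_RIGHT = frozenset(
    list(range(0, 8)) + list(range(17, 22)) + [31, 32]
    + list(range(36, 42)) + [48, 49, 50, 58, 59, 60, 61, 67]
)
_LEFT = frozenset(
    list(range(9, 17)) + list(range(22, 27)) + [34, 35]
    + list(range(42, 48)) + [52, 53, 54, 55, 56, 63, 64, 65]
)

# Anatomical left/right counterpart of each landmark (midline maps to itself).
_MIRROR = {}
for _i in range(0, 17):
    _MIRROR[_i] = 16 - _i
for _i in range(17, 27):
    _MIRROR[_i] = 43 - _i
for _i in (27, 28, 29, 30, 33):
    _MIRROR[_i] = _i
for _i in (31, 32, 34, 35):
    _MIRROR[_i] = 66 - _i
for _i in range(36, 40):
    _MIRROR[_i] = 81 - _i
for _i in (40, 41, 46, 47):
    _MIRROR[_i] = 87 - _i
for _i in range(42, 46):
    _MIRROR[_i] = 81 - _i
for _i in range(48, 55):
    _MIRROR[_i] = 102 - _i
for _i in (55, 56, 58, 59):
    _MIRROR[_i] = 114 - _i
for _i in (57,):
    _MIRROR[_i] = 57
for _i in (60, 61, 63, 64):
    _MIRROR[_i] = 124 - _i
for _i in (62, 66):
    _MIRROR[_i] = _i
for _i in (65, 67):
    _MIRROR[_i] = 132 - _i


def mirror_index(i: int) -> int:
    """Anatomical left/right counterpart of landmark ``i`` (midline: itself)."""
    return _MIRROR[int(i)]


@dataclass(frozen=True)
class RegionMap:
    """Named landmark regions, composites, and the hemiface partition.

    ``regions`` maps primitive region names to index sets; composites are
    derived (eyebrow, eye, upper_face = eyebrow ∪ eye, lower_face = nose ∪
    mouth ∪ outline).  ``left``/``right`` hold the hemiface partition;
    midline landmarks belong to neither.
    """

    regions: Mapping[str, frozenset] = field(default_factory=dict)
    left: frozenset = frozenset()
    right: frozenset = frozenset()

    COMPOSITES = {
        "eyebrow": ("eyebrow_left", "eyebrow_right"),
        "eye": ("eye_left", "eye_right"),
        "upper_face": ("eyebrow_left", "eyebrow_right", "eye_left", "eye_right"),
        "lower_face": ("nose", "mouth", "outline"),
    }

    #: Region names reported in the asymmetry analysis, coarsest last.
    ANALYSIS_REGIONS = (
        "eyebrow", "eye", "nose", "mouth", "outline", "upper_face", "lower_face",
    )

    def __post_init__(self) -> None:
        regions = {k: frozenset(int(i) for i in v) for k, v in self.regions.items()}
        object.__setattr__(self, "regions", regions)
        object.__setattr__(self, "left", frozenset(int(i) for i in self.left))
        object.__setattr__(self, "right", frozenset(int(i) for i in self.right))
        self._validate()

    def _validate(self) -> None:
        all_idx = sorted(i for v in self.regions.values() for i in v)
        if all_idx != list(range(N_LANDMARKS)):
            raise ValueError("primitive regions must partition 0..67")
        if self.left & self.right:
            raise ValueError("left and right hemiface sets overlap")
        # paired regions (and side splits of bilateral ones) must balance
        for lname, rname in (("eyebrow_left", "eyebrow_right"),
                             ("eye_left", "eye_right")):
            if lname in self.regions and rname in self.regions:
                if len(self.regions[lname]) != len(self.regions[rname]):
                    raise ValueError(
                        f"{lname}/{rname}: unequal cardinality"
                    )
        for region in ("outline", "nose", "mouth"):
            if region in self.regions:
                idx = self.regions[region]
                if len(idx & self.left) != len(idx & self.right):
                    raise ValueError(
                        f"region {region!r}: unequal left/right cardinality"
                    )

    def region_indexes(self, region: str) -> frozenset:
        """Index set of a primitive or composite region."""
        if region in self.regions:
            return self.regions[region]
        if region in self.COMPOSITES:
            out: frozenset = frozenset()
            for part in self.COMPOSITES[region]:
                out |= self.regions[part]
            return out
        raise KeyError(f"unknown region {region!r}")

    def indexes(self, region: str, side: str = "both") -> np.ndarray:
        """Sorted landmark indexes of ``region`` restricted to ``side``."""
        idx = self.region_indexes(region)
        if side == "both":
            pass
        elif side == "left":
            idx = idx & self.left
        elif side == "right":
            idx = idx & self.right
        else:
            raise KeyError(f"unknown side {side!r}")
        return np.asarray(sorted(idx), dtype=int)

    def primitive_parts(self, region: str) -> tuple:
        """Primitive regions composing ``region`` (itself if primitive)."""
        if region in self.regions:
            return (region,)
        return self.COMPOSITES[region]

    def flipped(self) -> "RegionMap":
        """Swap left/right semantics (observer- vs subject-perspective)."""
        return RegionMap(self.regions, left=self.right, right=self.left)

    # --- serialization ----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "regions": {k: sorted(v) for k, v in self.regions.items()},
            "left": sorted(self.left),
            "right": sorted(self.right),
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "RegionMap":
        return cls(d["regions"], frozenset(d["left"]), frozenset(d["right"]))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh)

    @classmethod
    def from_yaml(cls, path) -> "RegionMap":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def default_region_map() -> RegionMap:
    """The iBUG-68 region map with subject-perspective hemiface sides."""
    return RegionMap(
        {k: frozenset(v) for k, v in _PRIMITIVE.items()},
        left=_LEFT,
        right=_RIGHT,
    )
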