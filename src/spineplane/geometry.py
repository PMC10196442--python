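"""Boxes, plane triplets, angles, 3D IoU and non-max suppression.

Coordinate conventions
----------------------
Voxel indices are 0-based; ``world = index * spacing + origin`` (mm).
Boxes are axis-aligned and carry a ``frame`` tag: ``"world"`` (mm) or
``"normalized"`` (all six values in ``[0, 1]`` relative to the patch).

A vertebra's three anatomical standard planes (axial, coronal, sagittal)
are mutually orthogonal.  Internally a :class:`PlaneTriplet` stores a
rotation matrix whose *columns* are the sagittal, coronal and axial plane
normals (the images of the x, y, z axes), so the identity matrix is the
un-tilted patient frame.  Each plane is spanned by the normals of the
other two planes, ordered so that ``u x v = n``.

Plane normals are unoriented: a plane and its flipped normal describe the
same anatomical plane, so all angle errors use the absolute dot product.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Box3D",
    "PlaneTriplet",
    "VertebraAnnotation",
    "orthonormalize_triplet",
    "plane_angle_error",
    "point_to_plane_distance",
    "box_iou3d",
    "nms3d",
]

PLANE_NAMES = ("axial", "coronal", "sagittal")

# column index of each plane's normal in PlaneTriplet.rot
_NORMAL_COL = {"axial": 2, "coronal": 1, "sagittal": 0}
# spanning vectors (u, v) of each plane, as columns of rot, with u x v = n
_SPAN_COLS = {"axial": (0, 1), "coronal": (2, 0), "sagittal": (1, 2)}


def _as_vec3(v) -> np.ndarray:
    a = np.asarray(v, dtype=float).reshape(3)
    if not np.all(np.isfinite(a)):
        raise ValueError(f"non-finite vector: {v!r}")
    return a


@dataclass(frozen=True)
class Box3D:
    """Axis-aligned box given by center and full extents (w, h, d)."""

    center: np.ndarray
    extents: np.ndarray
    frame: str = "world"

    def __post_init__(self):
        object.__setattr__(self, "center", _as_vec3(self.center))
        object.__setattr__(self, "extents", _as_vec3(self.extents))
        if self.frame not in ("world", "normalized"):
            raise ValueError(f"unknown frame {self.frame!r}")
        if np.any(self.extents <= 0):
            raise ValueError("box extents must be strictly positive")

    @property
    def low(self) -> np.ndarray:
        return self.center - self.extents / 2.0

    @property
    def high(self) -> np.ndarray:
        return self.center + self.extents / 2.0

    @property
    def volume(self) -> float:
        return float(np.prod(self.extents))


class PlaneTriplet:
    """Orthonormal axial/coronal/sagittal plane triplet of one vertebra."""

    __slots__ = ("rot",)

    def __init__(self, rot: np.ndarray):
        rot = np.asarray(rot, dtype=float).reshape(3, 3)
        if not np.allclose(rot @ rot.T, np.eye(3), atol=1e-6):
            raise ValueError("PlaneTriplet requires an orthonormal matrix")
        if np.linalg.det(rot) < 0:
            raise ValueError("PlaneTriplet requires a right-handed basis")
        self.rot = rot

    @classmethod
    def identity(cls) -> "PlaneTriplet":
        return cls(np.eye(3))

    @classmethod
    def from_rotation(cls, rot: np.ndarray) -> "PlaneTriplet":
        return cls(rot)

    def normal(self, plane: str) -> np.ndarray:
        return self.rot[:, _NORMAL_COL[plane]].copy()

    @property
    def normals(self) -> np.ndarray:
        """(3, 3) array of rows (axial, coronal, sagittal) normals."""
        return np.stack([self.normal(p) for p in PLANE_NAMES])

    def spanning(self, plane: str) -> tuple[np.ndarray, np.ndarray]:
        iu, iv = _SPAN_COLS[plane]
        return self.rot[:, iu].copy(), self.rot[:, iv].copy()

    def to_params(self) -> np.ndarray:
        """Flatten to the 18 regression targets: (u, v) per plane."""
        out = np.empty(18)
        for i, p in enumerate(PLANE_NAMES):
            u, v = self.spanning(p)
            out[6 * i : 6 * i + 3] = u
            out[6 * i + 3 : 6 * i + 6] = v
        return out

    @classmethod
    def from_params(cls, params: np.ndarray) -> "PlaneTriplet":
        """Build the nearest valid triplet from 18 raw spanning components."""
        return orthonormalize_triplet(np.asarray(params, dtype=float).reshape(18))

    def to_dict(self) -> dict:
        d = {}
        for p in PLANE_NAMES:
            u, v = self.spanning(p)
            d[p] = {"u": u.tolist(), "v": v.tolist()}
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PlaneTriplet":
        params = np.concatenate(
            [np.concatenate([_as_vec3(d[p]["u"]), _as_vec3(d[p]["v"])]) for p in PLANE_NAMES]
        )
        return cls.from_params(params)

    def __repr__(self):
        return f"PlaneTriplet(rot={self.rot.tolist()})"


@dataclass
class VertebraAnnotation:
    """One vertebra: box, standard-plane triplet and region class.

    ``class_id`` is 1 for cervical, 2 for thoracic, 3 for lumbar.
    """

    box: Box3D
    planes: PlaneTriplet
    class_id: int

    def __post_init__(self):
        if self.class_id not in (1, 2, 3):
            raise ValueError(f"class_id must be in {{1,2,3}}, got {self.class_id}")

    @property
    def center(self) -> np.ndarray:
        return self.box.center

    def to_dict(self) -> dict:
        return {
            "class_id": int(self.class_id),
            "center_mm": self.box.center.tolist(),
            "extent_mm": self.box.extents.tolist(),
            "planes": self.planes.to_dict(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "VertebraAnnotation":
        return cls(
            box=Box3D(d["center_mm"], d["extent_mm"], frame="world"),
            planes=PlaneTriplet.from_dict(d["planes"]),
            class_id=int(d["class_id"]),
        )


def orthonormalize_triplet(raw) -> PlaneTriplet:
    """Project raw (possibly non-orthonormal) spanning vectors onto a valid triplet.

    ``raw`` is either an 18-vector of (u, v) pairs per plane or a
    :class:`PlaneTriplet`.  The normal of each plane is taken as ``u x v``;
    the stacked normal matrix is projected onto the rotation group by
    singular-value decomposition, and the spanning vectors are rebuilt from
    the projected normals.  Idempotent on already-valid triplets.
    """
    if isinstance(raw, PlaneTriplet):
        return PlaneTriplet(raw.rot.copy())
    params = np.asarray(raw, dtype=float).reshape(18)
    cols = np.empty((3, 3))
    for p in PLANE_NAMES:
        i = PLANE_NAMES.index(p)
        u = params[6 * i : 6 * i + 3]
        v = params[6 * i + 3 : 6 * i + 6]
        n = np.cross(u, v)
        norm = np.linalg.norm(n)
        if norm < 1e-12:
            raise ValueError(f"degenerate spanning vectors for {p} plane")
        cols[:, _NORMAL_COL[p]] = n / norm
    U, s, Vt = np.linalg.svd(cols)
    if s[-1] < 1e-9:
        raise ValueError("rank-deficient normal matrix; cannot orthonormalize")
    rot = U @ Vt
    if np.linalg.det(rot) < 0:
        rot = U @ np.diag([1.0, 1.0, -1.0]) @ Vt
    return PlaneTriplet(rot)


def plane_angle_error(n_pred, n_gt) -> float:
    """Unoriented angle between two plane normals, in degrees, in [0, 90]."""
    a = _as_vec3(n_pred)
    b = _as_vec3(n_gt)
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na < 1e-12 or nb < 1e-12:
        raise ValueError("zero vector has no direction")
    c = abs(float(a @ b) / (na * nb))
    return float(np.degrees(np.arccos(min(c, 1.0))))


def point_to_plane_distance(p, plane_point, n) -> float:
    """Unsigned distance (mm) from point ``p`` to the plane through
    ``plane_point`` with normal ``n``."""
    nv = _as_vec3(n)
    norm = np.linalg.norm(nv)
    if norm < 1e-12:
        raise ValueError("zero normal vector")
    return float(abs((_as_vec3(p) - _as_vec3(plane_point)) @ nv) / norm)


def box_iou3d(a: Box3D, b: Box3D) -> float:
    """Intersection-over-union of two axis-aligned boxes in the same frame."""
    if a.frame != b.frame:
        raise ValueError(f"boxes in different frames: {a.frame} vs {b.frame}")
    lo = np.maximum(a.low, b.low)
    hi = np.minimum(a.high, b.high)
    inter = float(np.prod(np.clip(hi - lo, 0.0, None)))
    union = a.volume + b.volume - inter
    return inter / union if union > 0 else 0.0


def nms3d(dets, iou_threshold: float) -> list:
    """Greedy per-class non-max suppression.

    ``dets`` is a sequence of objects exposing ``box`` (:class:`Box3D`),
    ``score`` (scalar) and ``class_id``.  Detections are visited in
    descending score order (ties broken by lexicographic box center, for
    determinism); a detection is suppressed if its IoU with an
    already-kept detection *of the same class* exceeds ``iou_threshold``.
    Returns the surviving detections sorted by descending score.
    """
    dets = list(dets)
    if not dets:
        return []

    def key(d):
        return (-float(d.score), tuple(np.asarray(d.box.center, dtype=float)))

    order = sorted(range(len(dets)), key=lambda i: key(dets[i]))
    kept: list[int] = []
    for i in order:
        di = dets[i]
        ok = True
        for j in kept:
            dj = dets[j]
            if getattr(di, "class_id", None) == getattr(dj, "class_id", None):
                if box_iou3d(di.box, dj.box) > iou_threshold:
                    ok = False
                    break
        if ok:
            kept.append(i)
    return [dets[i] for i in kept]
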