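"""Seeded synthetic spine phantoms with complete ground truth.

Generates CBCT-like volumes containing 1-10 vertebrae stacked along a
smoothly curved axis, with class-dependent extents (cervical 8-13 mm,
thoracic 17-24 mm, lumbar 21-24 mm), per-vertebra plane triplets tilted
off the stacking direction, optional Gaussian noise and bright streak
artifacts emulating metal implants.  Vertebra shapes are deliberately
simple — a flattened superellipsoid body with bright cortical endplates
plus a posterior ring — the phantoms exist to test algorithmic
correctness, not anatomical realism.

The field of view is fixed at 160.256 mm (512 voxels at 0.313 mm); the
voxel spacing follows from the requested grid size.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .geometry import Box3D, PlaneTriplet, VertebraAnnotation, box_iou3d
from .segplane import CylinderSpec, choose_cylinder_size, rasterize_plane_cylinders

logger = logging.getLogger(__name__)

__all__ = ["PhantomSpec", "PhantomSample", "sample_spine_geometry", "render_volume", "generate"]

FOV_MM = 512 * 0.313  # the acquisition field of view emulated at every grid size

#: per-class vertebra size ranges (mm): cervical, thoracic, lumbar
SIZE_RANGES = {1: (8.0, 13.0), 2: (17.0, 24.0), 3: (21.0, 24.0)}

_REGION_TO_CLASS = {"cervical": 1, "thoracic": 2, "lumbar": 3}


@dataclass(frozen=True)
class PhantomSpec:
    grid_size: int = 160
    n_vertebrae: int | None = None  # None: draw 1-10 (clipped to what fits)
    region: str = "mixed"  # cervical | thoracic | lumbar | mixed
    gap_range_mm: tuple[float, float] = (4.0, 8.0)  # intervertebral disc heights
    max_tilt_deg: float = 15.0
    noise: float = 0.02
    artifact_severity: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.n_vertebrae is not None and not 1 <= self.n_vertebrae <= 10:
            raise ValueError("n_vertebrae must be in [1, 10]")
        if self.region not in ("mixed", *_REGION_TO_CLASS):
            raise ValueError(f"unknown region {self.region!r}")

    @property
    def spacing(self) -> float:
        return FOV_MM / self.grid_size

    @property
    def shape(self) -> tuple[int, int, int]:
        return (self.grid_size,) * 3


@dataclass
class PhantomSample:
    volume: np.ndarray
    annotations: list[VertebraAnnotation]
    masks: np.ndarray
    spec: PhantomSpec
    cylinders: CylinderSpec


def _rotate_about(v: np.ndarray, axis: np.ndarray, angle: float) -> np.ndarray:
    axis = axis / np.linalg.norm(axis)
    c, s = np.cos(angle), np.sin(angle)
    return v * c + np.cross(axis, v) * s + axis * (axis @ v) * (1 - c)


def _triplet_from_axial(n_axial: np.ndarray, roll: float) -> PlaneTriplet:
    """Right-handed triplet with the given axial normal and in-plane roll."""
    na = n_axial / np.linalg.norm(n_axial)
    ref = np.array([0.0, 1.0, 0.0])
    ns = np.cross(ref, na)
    if np.linalg.norm(ns) < 1e-6:
        ns = np.array([1.0, 0.0, 0.0])
    ns = ns / np.linalg.norm(ns)
    ns = _rotate_about(ns, na, roll)
    nc = np.cross(na, ns)
    return PlaneTriplet(np.stack([ns, nc, na], axis=1))


def _class_sequence(n: int, region: str, rng: np.random.Generator) -> list[int]:
    if region != "mixed":
        return [_REGION_TO_CLASS[region]] * n
    # contiguous runs advancing cervical -> thoracic -> lumbar
    cls = int(rng.choice([1, 2, 3], p=[0.40, 0.35, 0.25]))
    out = []
    for _ in range(n):
        out.append(cls)
        if cls < 3 and rng.random() < 0.25:
            cls += 1
    return out


def sample_spine_geometry(
    spec: PhantomSpec, rng: np.random.Generator | None = None
) -> list[VertebraAnnotation]:
    """Draw vertebra boxes and plane triplets along a curved spine axis.

    The requested count is truncated to the prefix of the drawn spine
    that fits the field of view (truncating, rather than rejecting and
    redrawing, keeps the region-class mix unbiased).
    """
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(spec.seed)
    n = spec.n_vertebrae if spec.n_vertebrae is not None else int(rng.integers(1, 11))
    fov = FOV_MM
    margin = 3.0

    for attempt in range(20):
        classes = _class_sequence(n, spec.region, rng)
        sizes = [float(rng.uniform(*SIZE_RANGES[c])) for c in classes]
        gaps = [float(rng.uniform(*spec.gap_range_mm)) for _ in range(max(n - 1, 0))]
        # truncate to what fits vertically (with room for lean/curvature)
        budget = (fov - 2 * margin) * 0.92
        length, keep = sizes[0], 1
        for i in range(1, n):
            step = gaps[i - 1] + sizes[i]
            if length + step > budget:
                break
            length += step
            keep += 1
        if keep < n:
            logger.warning("field of view holds %d of %d requested vertebrae", keep, n)
        classes, sizes = classes[:keep], sizes[:keep]

        # stacking direction: mostly +z with a random lateral lean
        direction = np.array([rng.normal(0, 0.12), rng.normal(0, 0.12), 1.0])
        direction /= np.linalg.norm(direction)
        start_z = margin + sizes[0] / 2 + rng.uniform(
            0, max(fov - 2 * margin - length, 1e-3)
        )
        center = np.array(
            [fov / 2 + rng.uniform(-8, 8), fov / 2 + rng.uniform(-8, 8), start_z]
        )
        anns: list[VertebraAnnotation] = []
        ok = True
        for i, (cls, s) in enumerate(zip(classes, sizes)):
            lo, hi = center - s / 2, center + s / 2
            if np.any(lo < margin) or np.any(hi > fov - margin):
                ok = False
                break
            tilt = np.radians(rng.uniform(0, spec.max_tilt_deg))
            perp = np.cross(direction, rng.normal(size=3))
            while np.linalg.norm(perp) < 1e-6:
                perp = np.cross(direction, rng.normal(size=3))
            n_axial = _rotate_about(direction, perp / np.linalg.norm(perp), tilt)
            roll = np.radians(rng.uniform(-spec.max_tilt_deg, spec.max_tilt_deg))
            anns.append(
                VertebraAnnotation(
                    box=Box3D(center.copy(), np.full(3, s), frame="world"),
                    planes=_triplet_from_axial(n_axial, roll),
                    class_id=cls,
                )
            )
            if i + 1 < len(classes):
                step = s / 2 + gaps[i] + sizes[i + 1] / 2
                # smooth curvature: small random bend of the stacking axis
                bend = np.radians(rng.uniform(0, 4.0))
                perp = np.cross(direction, rng.normal(size=3))
                if np.linalg.norm(perp) > 1e-6:
                    direction = _rotate_about(direction, perp / np.linalg.norm(perp), bend)
                    direction /= np.linalg.norm(direction)
                center = center + direction * step
        if ok:
            overlap = any(
                box_iou3d(a.box, b.box) > 0
                for ai, a in enumerate(anns)
                for b in anns[ai + 1 :]
            )
            if not overlap:
                return anns
    raise RuntimeError("failed to sample a non-overlapping spine geometry")


def render_volume(
    annotations: list[VertebraAnnotation],
    spec: PhantomSpec,
    rng: np.random.Generator | None = None,
) -> PhantomSample:
    """Render annotations into a gray-value volume and label masks."""
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(spec.seed + 1)
    shape = spec.shape
    sp = spec.spacing
    vol = np.full(shape, 0.15, dtype=np.float32)
    # smooth soft-tissue background variation
    coarse = rng.normal(0, 1.0, size=(8, 8, 8))
    from scipy.ndimage import zoom

    bg = zoom(coarse, np.array(shape) / 8.0, order=1)
    vol += 0.04 * bg[: shape[0], : shape[1], : shape[2]].astype(np.float32)
    vol = np.clip(vol, 0.05, 0.25)

    for ann in annotations:
        c = ann.box.center
        e = float(np.mean(ann.box.extents))
        R = ann.planes.rot
        half = 0.8 * e  # sub-volume reach around the center
        lo = np.maximum(np.floor((c - half) / sp).astype(int), 0)
        hi = np.minimum(np.ceil((c + half) / sp).astype(int), np.asarray(shape) - 1)
        grids = np.meshgrid(*[np.arange(lo[a], hi[a] + 1) for a in range(3)], indexing="ij")
        pts = np.stack(grids, axis=-1) * sp - c
        local = pts @ R  # coordinates in the vertebra frame
        # vertebral bodies are wider than tall: flattened along the axial
        # normal, with near-flat endplates (high even exponent axially)
        semi = 0.45 * np.asarray(ann.box.extents) * np.array([1.0, 1.0, 0.78])
        q = local / semi
        body = q[..., 0] ** 2 + q[..., 1] ** 2 + q[..., 2] ** 6 <= 1.0
        # posterior ring (neural arch): torus in the axial plane behind the body
        arch_c = 0.55 * e * np.array([0.0, 1.0, 0.0])  # +coronal normal direction
        q = local - arch_c
        r_ring, r_tube = 0.28 * e, 0.10 * e
        ring = (np.sqrt(q[..., 0] ** 2 + q[..., 1] ** 2) - r_ring) ** 2 + q[..., 2] ** 2 <= r_tube**2
        sub = vol[lo[0] : hi[0] + 1, lo[1] : hi[1] + 1, lo[2] : hi[2] + 1]
        level = 0.75 + float(rng.uniform(-0.05, 0.05))
        sub[body] = np.maximum(sub[body], level)
        # bright cortical endplates: the top/bottom caps of the body
        plates = body & (np.abs(local[..., 2]) >= 0.75 * semi[2])
        sub[plates] = np.maximum(sub[plates], level + 0.17)
        sub[ring] = np.maximum(sub[ring], level - 0.05)

    if spec.artifact_severity > 0:
        n_streaks = int(np.ceil(spec.artifact_severity * 5))
        for _ in range(n_streaks):
            anchor = annotations[int(rng.integers(len(annotations)))].box.center if annotations else (
                np.array(shape) / 2 * sp
            )
            d = rng.normal(size=3)
            d /= np.linalg.norm(d)
            ts = np.linspace(-FOV_MM, FOV_MM, 4 * spec.grid_size)
            pts = (anchor + ts[:, None] * d) / sp
            idx = np.round(pts).astype(int)
            good = np.all((idx >= 0) & (idx < np.asarray(shape)), axis=1)
            idx = idx[good]
            vol[idx[:, 0], idx[:, 1], idx[:, 2]] = 1.2 + 0.3 * spec.artifact_severity

    if spec.noise > 0:
        vol = vol + rng.normal(0.0, spec.noise, size=shape).astype(np.float32)

    if annotations:
        cyl = choose_cylinder_size(annotations)
        masks = rasterize_plane_cylinders(annotations, cyl, shape, sp)
    else:
        cyl = CylinderSpec.from_diameter(1.0)
        masks = np.zeros((3,) + shape, dtype=np.uint8)
    return PhantomSample(
        volume=vol.astype(np.float32), annotations=annotations, masks=masks, spec=spec, cylinders=cyl
    )


def generate(spec: PhantomSpec) -> PhantomSample:
    """Geometry + rendering under the PhantomSpec seed (fully deterministic)."""
    rng = np.random.default_rng(spec.seed)
    anns = sample_spine_geometry(spec, rng)
    return render_volume(anns, spec, rng)
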