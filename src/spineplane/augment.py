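"""On-the-fly training augmentations for volumes + vertebra labels.

Seven transforms, applied in a fixed order with independent firing
draws: combined rotation/scaling, additive Gaussian noise, Gaussian
blur, brightness, contrast (with clipping to the original value range),
simulated low resolution (nearest-neighbor down, cubic up), and gamma.
Geometric transforms are applied consistently to the volume (linear
interpolation), the label masks (nearest) and the annotations (centers,
axis-aligned extents and plane spanning vectors); intensity transforms
leave labels untouched.  Intensities are assumed normalized to [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage
from skimage.transform import resize

from .geometry import Box3D, PlaneTriplet, VertebraAnnotation

__all__ = ["AugmentConfig", "TransformPlan", "sample_transform_plan", "augment_sample"]


@dataclass(frozen=True)
class AugmentConfig:
    p_rotation: float = 0.16
    p_scaling: float = 0.16
    p_rotation_and_scaling: float = 0.08
    angle_range_deg: tuple[float, float] = (-30.0, 30.0)
    scale_range: tuple[float, float] = (0.7, 1.4)
    p_noise: float = 0.15
    noise_var_range: tuple[float, float] = (0.0, 0.1)
    p_blur: float = 0.2
    blur_sigma_range: tuple[float, float] = (0.5, 1.5)
    p_brightness: float = 0.15
    brightness_range: tuple[float, float] = (0.7, 1.3)
    p_contrast: float = 0.15
    contrast_range: tuple[float, float] = (0.65, 1.5)
    p_lowres: float = 0.25
    lowres_factor_range: tuple[float, float] = (1.0, 2.0)
    p_gamma: float = 0.15
    gamma_range: tuple[float, float] = (0.7, 1.5)

    def __post_init__(self):
        for name in (
            "p_rotation", "p_scaling", "p_rotation_and_scaling", "p_noise",
            "p_blur", "p_brightness", "p_contrast", "p_lowres", "p_gamma",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0,1], got {v}")


@dataclass
class TransformPlan:
    """Which transforms fire this draw, and with which parameters."""

    rotate: bool = False
    scale: bool = False
    angles_deg: np.ndarray = field(default_factory=lambda: np.zeros(3))
    scale_factor: float = 1.0
    noise_var: float | None = None
    blur_sigma: float | None = None
    brightness: float | None = None
    contrast: float | None = None
    lowres_factor: float | None = None
    gamma: float | None = None


def sample_transform_plan(cfg: AugmentConfig, rng: np.random.Generator) -> TransformPlan:
    """Draw the firing decisions and parameters for one sample."""
    plan = TransformPlan()
    u = rng.random()
    if u < cfg.p_rotation:
        plan.rotate = True
    elif u < cfg.p_rotation + cfg.p_scaling:
        plan.scale = True
    elif u < cfg.p_rotation + cfg.p_scaling + cfg.p_rotation_and_scaling:
        plan.rotate = plan.scale = True
    if plan.rotate:
        plan.angles_deg = rng.uniform(*cfg.angle_range_deg, size=3)
    if plan.scale:
        plan.scale_factor = float(rng.uniform(*cfg.scale_range))
    if rng.random() < cfg.p_noise:
        plan.noise_var = float(rng.uniform(*cfg.noise_var_range))
    if rng.random() < cfg.p_blur:
        plan.blur_sigma = float(rng.uniform(*cfg.blur_sigma_range))
    if rng.random() < cfg.p_brightness:
        plan.brightness = float(rng.uniform(*cfg.brightness_range))
    if rng.random() < cfg.p_contrast:
        plan.contrast = float(rng.uniform(*cfg.contrast_range))
    if rng.random() < cfg.p_lowres:
        plan.lowres_factor = float(rng.uniform(*cfg.lowres_factor_range))
    if rng.random() < cfg.p_gamma:
        plan.gamma = float(rng.uniform(*cfg.gamma_range))
    return plan


def _rotation_matrix(angles_deg: np.ndarray) -> np.ndarray:
    ax, ay, az = np.radians(angles_deg)
    cx, sx = np.cos(ax), np.sin(ax)
    cy, sy = np.cos(ay), np.sin(ay)
    cz, sz = np.cos(az), np.sin(az)
    Rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    Ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    Rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
    return Rz @ Ry @ Rx


def _apply_geometric(volume, annotations, masks, plan, spacing, origin):
    R = _rotation_matrix(plan.angles_deg) if plan.rotate else np.eye(3)
    s = plan.scale_factor if plan.scale else 1.0
    A = R * s
    Ainv = np.linalg.inv(A)
    center_idx = (np.asarray(volume.shape) - 1) / 2.0
    offset = center_idx - Ainv @ center_idx
    fill = float(volume.min())
    vol_t = ndimage.affine_transform(
        volume, Ainv, offset=offset, order=1, mode="constant", cval=fill
    )
    masks_t = None
    if masks is not None:
        masks_t = np.stack(
            [
                ndimage.affine_transform(m, Ainv, offset=offset, order=0, mode="constant", cval=0)
                for m in masks
            ]
        )
    origin = np.asarray(origin, dtype=float)
    center_mm = origin + center_idx * spacing
    anns_t = []
    for ann in annotations:
        c = A @ (ann.box.center - center_mm) + center_mm
        e = (np.abs(R) @ ann.box.extents) * s  # AABB of the transformed box
        anns_t.append(
            VertebraAnnotation(
                box=Box3D(c, e, frame=ann.box.frame),
                planes=PlaneTriplet(R @ ann.planes.rot),
                class_id=ann.class_id,
            )
        )
    return vol_t, anns_t, masks_t


def augment_sample(
    volume: np.ndarray,
    annotations: list[VertebraAnnotation],
    masks: np.ndarray | None = None,
    cfg: AugmentConfig = AugmentConfig(),
    rng: np.random.Generator | int | None = None,
    spacing: float = 1.0,
    origin=(0.0, 0.0, 0.0),
    plan: TransformPlan | None = None,
):
    """Apply one augmentation draw to a (volume, annotations, masks) sample.

    Returns ``(volume', annotations', masks')``; ``masks'`` is None when
    no masks were given.  Pass ``plan`` to force specific transforms
    (used by tests); otherwise a plan is drawn from ``rng``.
    """
    if plan is None:
        if not isinstance(rng, np.random.Generator):
            rng = np.random.default_rng(rng)
        plan = sample_transform_plan(cfg, rng)
    vol = np.asarray(volume, dtype=np.float32)
    anns = list(annotations)

    if plan.rotate or plan.scale:
        vol, anns, masks = _apply_geometric(vol, anns, masks, plan, spacing, origin)

    if plan.noise_var is not None:
        noise_rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
        vol = vol + noise_rng.normal(0.0, np.sqrt(plan.noise_var), size=vol.shape).astype(
            np.float32
        )
    if plan.blur_sigma is not None:
        vol = ndimage.gaussian_filter(vol, plan.blur_sigma)
    if plan.brightness is not None:
        vol = vol * plan.brightness
    if plan.contrast is not None:
        lo, hi = float(vol.min()), float(vol.max())
        vol = np.clip(vol * plan.contrast, lo, hi)
    if plan.lowres_factor is not None and plan.lowres_factor > 1.0:
        small = tuple(max(1, int(round(n / plan.lowres_factor))) for n in vol.shape)
        down = resize(vol, small, order=0, anti_aliasing=False, preserve_range=True)
        vol = resize(down, vol.shape, order=3, anti_aliasing=False, preserve_range=True).astype(
            np.float32
        )
    if plan.gamma is not None:
        lo, hi = float(vol.min()), float(vol.max())
        if hi > lo:
            vol = ((vol - lo) / (hi - lo)) ** plan.gamma * (hi - lo) + lo

    return vol.astype(np.float32), anns, masks
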