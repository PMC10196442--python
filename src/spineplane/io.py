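"""Volume and annotation I/O.

Volumes are read with SimpleITK (NIfTI ``.nii/.nii.gz`` and MetaImage
``.mha/.mhd``) into ``(x, y, z)``-indexed arrays with spacing and origin
in mm.  Annotations use one JSON file per volume::

    {"spacing_mm": f, "origin_mm": [f, f, f],
     "vertebrae": [{"class_id": 1|2|3, "center_mm": [...],
                    "extent_mm": [...],
                    "planes": {"axial": {"u": [...], "v": [...]},
                               "coronal": {...}, "sagittal": {...}}}]}
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import SimpleITK as sitk
from scipy.ndimage import zoom

from .geometry import VertebraAnnotation

logger = logging.getLogger(__name__)

__all__ = [
    "VolumeHandle",
    "load_volume",
    "save_volume",
    "resample_isotropic",
    "load_annotations",
    "save_annotations",
]

_EXTS = (".nii", ".nii.gz", ".mha", ".mhd")


@dataclass
class VolumeHandle:
    array: np.ndarray  # (x, y, z)
    spacing: np.ndarray  # mm per axis
    origin: np.ndarray  # mm
    orientation: str = "identity"

    def __post_init__(self):
        self.array = np.asarray(self.array)
        if self.array.ndim != 3:
            raise ValueError(f"expected a 3-D volume, got shape {self.array.shape}")
        self.spacing = np.broadcast_to(np.asarray(self.spacing, dtype=float), (3,)).copy()
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)
        if np.any(self.spacing <= 0):
            raise ValueError("spacing must be positive")

    @property
    def fov_mm(self) -> np.ndarray:
        return self.spacing * np.asarray(self.array.shape)

    @property
    def is_isotropic(self) -> bool:
        return bool(np.allclose(self.spacing, self.spacing[0], rtol=1e-3))


def _check_ext(path: Path):
    name = path.name.lower()
    if not any(name.endswith(e) for e in _EXTS):
        raise ValueError(f"unsupported volume format: {path} (expected {_EXTS})")


def load_volume(path) -> VolumeHandle:
    path = Path(path)
    _check_ext(path)
    try:
        img = sitk.ReadImage(str(path))
    except Exception as e:  # noqa: BLE001 - surface the failing file
        raise IOError(f"failed to read volume {path}: {e}") from e
    if img.GetDimension() != 3:
        raise ValueError(f"{path}: expected 3-D data, got {img.GetDimension()}-D")
    arr = sitk.GetArrayFromImage(img).transpose(2, 1, 0)  # (z,y,x) -> (x,y,z)
    return VolumeHandle(
        array=arr, spacing=np.array(img.GetSpacing()), origin=np.array(img.GetOrigin())
    )


def save_volume(path, handle: VolumeHandle):
    path = Path(path)
    _check_ext(path)
    img = sitk.GetImageFromArray(np.ascontiguousarray(handle.array.transpose(2, 1, 0)))
    img.SetSpacing(tuple(float(s) for s in handle.spacing))
    img.SetOrigin(tuple(float(o) for o in handle.origin))
    sitk.WriteImage(img, str(path))


def resample_isotropic(handle: VolumeHandle) -> VolumeHandle:
    """Resample an anisotropic volume to its finest spacing (trilinear)."""
    if handle.is_isotropic:
        return handle
    logger.warning("anisotropic spacing %s; resampling isotropic", handle.spacing)
    target = float(handle.spacing.min())
    factors = handle.spacing / target
    arr = zoom(handle.array.astype(np.float32), factors, order=1)
    return VolumeHandle(array=arr, spacing=np.full(3, target), origin=handle.origin)


def save_annotations(path, annotations: list[VertebraAnnotation], spacing: float, origin=(0, 0, 0)):
    doc = {
        "spacing_mm": float(np.mean(spacing)),
        "origin_mm": [float(v) for v in np.broadcast_to(np.asarray(origin, dtype=float), (3,))],
        "vertebrae": [a.to_dict() for a in annotations],
    }
    Path(path).write_text(json.dumps(doc, indent=1))


def load_annotations(path) -> tuple[list[VertebraAnnotation], float, np.ndarray]:
    doc = json.loads(Path(path).read_text())
    anns = [VertebraAnnotation.from_dict(d) for d in doc["vertebrae"]]
    return anns, float(doc["spacing_mm"]), np.asarray(doc["origin_mm"], dtype=float)
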