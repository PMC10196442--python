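"""Segmentation-based standard-plane regression.

Each vertebra's three standard planes are represented as flat cylinders
(diameter = 4 x height) centered on the vertebra, with the cylinder base
normal equal to the plane normal.  A 3D U-Net segments the three plane
channels (axial/coronal/sagittal), with the vertebra region class encoded
as the label value; plane parameters are then recovered by DBSCAN
clustering, a half-of-largest cluster-size filter, grouping of
intersecting clusters, mean-centroid centers and PCA normals (smallest
principal component of the flat cluster).

Volume arrays are indexed (x, y, z): ``world = index * spacing + origin``.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
from sklearn.cluster import DBSCAN

from . import nn
from .geometry import (
    PLANE_NAMES,
    Box3D,
    PlaneTriplet,
    VertebraAnnotation,
)

logger = logging.getLogger(__name__)

__all__ = [
    "CylinderSpec",
    "Cluster",
    "choose_cylinder_size",
    "rasterize_plane_cylinders",
    "UNet3D",
    "build_segnet",
    "seg_loss",
    "seg_loss_and_grad",
    "cluster_masks",
    "filter_clusters",
    "group_clusters",
    "vertebra_center_from_clusters",
    "plane_normals_from_cluster",
    "extract_annotations",
]


@dataclass(frozen=True)
class CylinderSpec:
    """Cylinder geometry shared by all vertebrae of one volume (mm)."""

    diameter: float
    height: float

    def __post_init__(self):
        if abs(self.diameter - 4.0 * self.height) > 1e-9:
            raise ValueError("cylinder must satisfy d = 4*h")
        if self.diameter <= 0:
            raise ValueError("cylinder diameter must be positive")

    @classmethod
    def from_diameter(cls, d: float) -> "CylinderSpec":
        return cls(diameter=d, height=d / 4.0)


@dataclass
class Cluster:
    channel: str
    voxels: np.ndarray  # (n, 3) integer indices
    centroid: np.ndarray  # mm
    class_id: int

    @property
    def size(self) -> int:
        return int(self.voxels.shape[0])

    @property
    def bbox(self) -> tuple[np.ndarray, np.ndarray]:
        return self.voxels.min(axis=0), self.voxels.max(axis=0)


def choose_cylinder_size(annotations: list[VertebraAnnotation]) -> CylinderSpec:
    """Largest cylinder that keeps the cylinders of distinct vertebrae apart.

    d = min(0.9 * minimum pairwise center distance, 1.5 * median vertebra
    extent); a single vertebra falls back to 1.5 * its extent.  h = d/4.
    """
    if not annotations:
        raise ValueError("need at least one vertebra")
    sizes = [float(np.mean(a.box.extents)) for a in annotations]
    if len(annotations) == 1:
        return CylinderSpec.from_diameter(1.5 * sizes[0])
    centers = np.stack([a.box.center for a in annotations])
    dmin = min(
        float(np.linalg.norm(centers[i] - centers[j]))
        for i, j in itertools.combinations(range(len(annotations)), 2)
    )
    d = min(0.9 * dmin, 1.5 * float(np.median(sizes)))
    return CylinderSpec.from_diameter(d)


def rasterize_plane_cylinders(
    annotations: list[VertebraAnnotation],
    spec: CylinderSpec,
    shape: tuple[int, int, int],
    spacing: float,
    origin=(0.0, 0.0, 0.0),
) -> np.ndarray:
    """Rasterize per-plane cylinder labels: (3, *shape) array in {0,1,2,3}.

    A voxel belongs to vertebra i's plane-p cylinder iff its axial offset
    along the plane normal is <= h/2 and its radial offset is <= d/2.
    Planes of the *same* vertebra may overlap across channels; cylinders
    of different vertebrae must not overlap (guaranteed by the spec
    choice, checked by the caller's tests).
    """
    masks = np.zeros((3,) + tuple(shape), dtype=np.uint8)
    origin = np.asarray(origin, dtype=float)
    r, hh = spec.diameter / 2.0, spec.height / 2.0
    reach = np.sqrt(r**2 + hh**2)
    for ann in annotations:
        c = ann.box.center
        lo_i = np.floor((c - reach - origin) / spacing).astype(int)
        hi_i = np.ceil((c + reach - origin) / spacing).astype(int)
        clipped = np.any(lo_i < 0) or np.any(hi_i > np.asarray(shape) - 1)
        if clipped:
            logger.warning("cylinder of vertebra at %s clipped to volume bounds", c)
        lo_i = np.maximum(lo_i, 0)
        hi_i = np.minimum(hi_i, np.asarray(shape) - 1)
        if np.any(hi_i < lo_i):
            continue
        grids = np.meshgrid(
            *[np.arange(lo_i[a], hi_i[a] + 1, dtype=np.float32) for a in range(3)],
            indexing="ij",
        )
        pts = np.stack(grids, axis=-1) * spacing + (origin - c)  # offsets from center
        pts = pts.astype(np.float32)
        for ci, plane in enumerate(PLANE_NAMES):
            n = ann.planes.normal(plane)
            ax = pts @ n
            rad2 = (pts * pts).sum(axis=-1) - ax * ax
            inside = (np.abs(ax) <= hh) & (rad2 <= r * r)
            sub = masks[ci][
                lo_i[0] : hi_i[0] + 1, lo_i[1] : hi_i[1] + 1, lo_i[2] : hi_i[2] + 1
            ]
            sub[inside] = ann.class_id
    return masks


class UNet3D(nn.Module):
    """Encoder-decoder segmentation network with skip connections.

    Maps a 1-channel patch to 3 plane channels x 4 class logits each
    (background + cervical/thoracic/lumbar), same spatial size.
    """

    def __init__(self, depth: int = 3, base_width: int = 16, seed: int = 0):
        self.depth, self.base_width = depth, base_width
        rng = np.random.default_rng(seed)
        B = lambda ci, co, k, s, n: nn.ConvBlock(ci, co, kernel=k, stride=s, rng=rng, name=n)
        w = [base_width * 2**i for i in range(depth + 1)]
        self.enc = [
            nn.Sequential(B(1 if i == 0 else w[i], w[i], 3, 1, f"enc{i}a"),
                          B(w[i], w[i], 3, 1, f"enc{i}b"))
            for i in range(depth)
        ]
        self.down = [B(w[i], w[i + 1], 3, 2, f"down{i}") for i in range(depth)]
        self.bottom = nn.Sequential(
            B(w[depth], w[depth], 3, 1, "bottom_a"), B(w[depth], w[depth], 3, 1, "bottom_b")
        )
        self.ups = [nn.Upsample3d(2) for _ in range(depth)]
        self.upconv = [B(w[i + 1], w[i], 1, 1, f"up{i}") for i in range(depth)]
        self.dec = [
            nn.Sequential(B(2 * w[i], w[i], 3, 1, f"dec{i}a"), B(w[i], w[i], 3, 1, f"dec{i}b"))
            for i in range(depth)
        ]
        self.head = nn.Conv3d(w[0], 12, kernel=1, bias=True, rng=rng, name="head")
        self.children = self.enc + self.down + [self.bottom] + self.upconv + self.dec + [self.head]

    def parameters(self):
        return [p for m in self.children for p in m.parameters()]

    def check_patch(self, size: int):
        if size % (2**self.depth):
            raise ValueError(f"patch size {size} not divisible by 2^{self.depth}")

    def forward(self, x):
        self.check_patch(x.shape[2])
        skips = []
        t = x.astype(np.float32)
        for i in range(self.depth):
            t = self.enc[i](t)
            skips.append(t)
            t = self.down[i](t)
        t = self.bottom(t)
        self._skip_ch = [s.shape[1] for s in skips]
        for i in reversed(range(self.depth)):
            t = self.upconv[i](self.ups[i](t))
            t = np.concatenate([t, skips[i]], axis=1)
            t = self.dec[i](t)
        logits = self.head(t)
        B = logits.shape[0]
        return logits.reshape(B, 3, 4, *logits.shape[2:])

    def backward(self, dlogits):
        B = dlogits.shape[0]
        d = self.head.backward(dlogits.reshape(B, 12, *dlogits.shape[3:]))
        d_skips = [None] * self.depth
        for i in range(self.depth):
            d = self.dec[i].backward(d)
            ch = self._skip_ch[i]
            d, ds = d[:, :-ch], d[:, -ch:]
            d_skips[i] = ds
            d = self.ups[i].backward(self.upconv[i].backward(d))
        d = self.bottom.backward(d)
        for i in reversed(range(self.depth)):
            d = self.down[i].backward(d)
            d = self.enc[i].backward(d + d_skips[i])
        return d


def build_segnet(depth: int = 3, base_width: int = 16, seed: int = 0) -> UNet3D:
    return UNet3D(depth=depth, base_width=base_width, seed=seed)


def _softmax(x, axis):
    x = x - x.max(axis=axis, keepdims=True)
    e = np.exp(x)
    return e / e.sum(axis=axis, keepdims=True)


def seg_loss_and_grad(logits: np.ndarray, masks: np.ndarray, w_CE: float = 1.0, w_DC: float = 1.0):
    """Sum over the three plane channels of cross-entropy + Dice loss.

    ``logits``: (B, 3, 4, D, H, W); ``masks``: (3, D, H, W) or
    (B, 3, D, H, W) integer labels in {0..3}.  The Dice loss is
    1 - mean soft Dice over the three foreground classes.
    """
    if masks.ndim == 4:
        masks = np.broadcast_to(masks[None], (logits.shape[0],) + masks.shape)
    B = logits.shape[0]
    nvox = B * int(np.prod(logits.shape[3:]))
    total = 0.0
    grad = np.zeros_like(logits)
    eps = 1e-6
    for c in range(3):
        lg = logits[:, c]  # (B, 4, D, H, W)
        y = masks[:, c]
        p = _softmax(lg, axis=1)
        onehot = np.stack([(y == k) for k in range(4)], axis=1).astype(np.float32)
        ce = float(-(onehot * np.log(np.clip(p, 1e-12, None))).sum()) / nvox
        d_ce = (p - onehot) / nvox

        dice_sum = 0.0
        d_dice = np.zeros_like(p)
        for k in range(1, 4):
            pk, yk = p[:, k], onehot[:, k]
            inter = float((pk * yk).sum())
            denom = float(pk.sum() + yk.sum())
            dice = (2 * inter + eps) / (denom + eps)
            dice_sum += dice
            # d dice/d pk = (2*yk*(denom+eps) - (2*inter+eps)) / (denom+eps)^2
            d_dice[:, k] = -(2 * yk * (denom + eps) - (2 * inter + eps)) / (denom + eps) ** 2 / 3.0
        dc = 1.0 - dice_sum / 3.0
        # chain through softmax: dL/dlg = J_softmax^T d_dice
        s_dot = (d_dice * p).sum(axis=1, keepdims=True)
        d_dc = p * (d_dice - s_dot)
        total += w_CE * ce + w_DC * dc
        grad[:, c] = w_CE * d_ce + w_DC * d_dc
    return total, grad


def seg_loss(logits: np.ndarray, masks: np.ndarray, w_CE: float = 1.0, w_DC: float = 1.0) -> float:
    return seg_loss_and_grad(logits, masks, w_CE, w_DC)[0]


def cluster_masks(
    masks: np.ndarray,
    eps: float = 2.0,
    min_samples: int = 10,
    spacing: float = 1.0,
    origin=(0.0, 0.0, 0.0),
) -> list[Cluster]:
    """DBSCAN over foreground voxels of each plane channel.

    Voxels flagged as noise are discarded.  Deterministic: voxels are
    visited in sorted (row-major) order.
    """
    origin = np.asarray(origin, dtype=float)
    clusters: list[Cluster] = []
    for ci, name in enumerate(PLANE_NAMES):
        coords = np.argwhere(masks[ci] > 0)
        if coords.shape[0] == 0:
            continue
        labels = DBSCAN(
            eps=eps, min_samples=min_samples, algorithm="ball_tree", leaf_size=64
        ).fit_predict(coords.astype(np.float32))
        vals = masks[ci][tuple(coords.T)]
        for lab in np.unique(labels):
            if lab < 0:
                continue
            sel = labels == lab
            vox = coords[sel]
            cls_vals, counts = np.unique(vals[sel], return_counts=True)
            clusters.append(
                Cluster(
                    channel=name,
                    voxels=vox,
                    centroid=vox.mean(axis=0) * spacing + origin,
                    class_id=int(cls_vals[np.argmax(counts)]),
                )
            )
    return clusters


def filter_clusters(clusters: list[Cluster]) -> list[Cluster]:
    """Keep clusters with at least half the voxels of the largest cluster.

    The threshold theta = n_max / 2 is computed per channel.
    """
    out: list[Cluster] = []
    for name in PLANE_NAMES:
        ch = [c for c in clusters if c.channel == name]
        if not ch:
            continue
        theta = max(c.size for c in ch) / 2.0
        out.extend(c for c in ch if c.size >= theta)
    return out


def _bbox_overlap(a: Cluster, b: Cluster) -> bool:
    alo, ahi = a.bbox
    blo, bhi = b.bbox
    return bool(np.all(ahi >= blo) and np.all(bhi >= alo))


def group_clusters(clusters: list[Cluster]) -> list[tuple[Cluster, Cluster, Cluster]]:
    """Group intersecting axial/coronal/sagittal clusters into vertebrae.

    Intersection is tested on voxel bounding boxes; multi-way ambiguities
    are resolved by nearest centroids.  Groups missing a channel are
    dropped with a warning.
    """
    by_ch = {name: [c for c in clusters if c.channel == name] for name in PLANE_NAMES}
    for name in PLANE_NAMES:
        by_ch[name].sort(key=lambda c: tuple(c.centroid))
    used = {name: set() for name in PLANE_NAMES}
    triples = []
    for ia, ax in enumerate(by_ch["axial"]):
        pick = {}
        ok = True
        for name in ("coronal", "sagittal"):
            cands = [
                (j, c)
                for j, c in enumerate(by_ch[name])
                if j not in used[name] and _bbox_overlap(ax, c)
            ]
            if not cands:
                ok = False
                break
            if len(cands) > 1:
                logger.info("ambiguous %s clusters for axial cluster %d; using nearest", name, ia)
            j, c = min(cands, key=lambda jc: float(np.linalg.norm(jc[1].centroid - ax.centroid)))
            pick[name] = (j, c)
        if not ok:
            logger.warning("axial cluster %d lacks a full channel triple; dropped", ia)
            continue
        if not _bbox_overlap(pick["coronal"][1], pick["sagittal"][1]):
            logger.warning("clusters for axial cluster %d do not mutually intersect; dropped", ia)
            continue
        used["coronal"].add(pick["coronal"][0])
        used["sagittal"].add(pick["sagittal"][0])
        triples.append((ax, pick["coronal"][1], pick["sagittal"][1]))
    n_left = sum(len(by_ch[n]) - len(used[n]) for n in ("coronal", "sagittal"))
    if n_left:
        logger.warning("%d coronal/sagittal clusters left ungrouped", n_left)
    return triples


def vertebra_center_from_clusters(triple) -> np.ndarray:
    """Vertebra center = mean of the three cluster centroids."""
    return np.mean([c.centroid for c in triple], axis=0)


def plane_normals_from_cluster(c: Cluster, min_voxels: int = 4) -> np.ndarray:
    """Plane normal = smallest principal component of the cluster voxels.

    Flat cylinders with d = 4h have axial variance h^2/12 < radial
    variance d^2/16, so the smallest-variance direction is the base
    normal.  The sign is canonicalized to a positive dot product with
    the most-aligned volume axis.
    """
    if c.size < min_voxels:
        raise ValueError(f"cluster too small for PCA ({c.size} voxels)")
    x = c.voxels - c.voxels.mean(axis=0)
    cov = x.T @ x / c.size
    evals, evecs = np.linalg.eigh(cov)
    if evals[1] < 1e-12:
        raise ValueError("rank-deficient cluster; cannot estimate a normal")
    n = evecs[:, 0]
    k = int(np.argmax(np.abs(n)))
    if n[k] < 0:
        n = -n
    return n / np.linalg.norm(n)


def extract_annotations(
    masks: np.ndarray,
    spacing: float,
    origin=(0.0, 0.0, 0.0),
    eps: float = 2.0,
    min_samples: int = 10,
    nominal_extent: float | None = None,
) -> list[VertebraAnnotation]:
    """Full post-processing chain: masks -> vertebra annotations.

    DBSCAN clustering, half-of-largest filtering, channel grouping, mean
    centroid centers and PCA normals, assembled into annotations.  The
    box extent is not observable from the cylinders; a nominal cubic
    extent (default: the inferred cylinder diameter) is reported.
    """
    clusters = cluster_masks(masks, eps=eps, min_samples=min_samples, spacing=spacing, origin=origin)
    logger.info("clustering found %d clusters", len(clusters))
    kept = filter_clusters(clusters)
    logger.info("%d clusters survive the half-of-largest filter", len(kept))
    triples = group_clusters(kept)
    logger.info("%d complete vertebra triples", len(triples))
    out = []
    for triple in triples:
        center = vertebra_center_from_clusters(triple)
        normals = {c.channel: plane_normals_from_cluster(c) for c in triple}
        rot = np.stack(
            [normals["sagittal"], normals["coronal"], normals["axial"]], axis=1
        )
        U, _, Vt = np.linalg.svd(rot)
        R = U @ Vt
        if np.linalg.det(R) < 0:
            R = U @ np.diag([1.0, 1.0, -1.0]) @ Vt
        if nominal_extent is None:
            # widest bounding-box side across the triple approximates the
            # cylinder diameter, the only size observable from the masks
            ext = max(float((c.bbox[1] - c.bbox[0]).max() + 1) for c in triple) * spacing
        else:
            ext = nominal_extent
        cls_ids = [c.class_id for c in triple]
        cls = int(np.bincount(cls_ids).argmax())
        out.append(
            VertebraAnnotation(
                box=Box3D(center, np.full(3, ext), frame="world"),
                planes=PlaneTriplet(R),
                class_id=max(cls, 1),
            )
        )
    return out
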