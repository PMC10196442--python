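"""Detection-based standard-plane regression: a 3D YOLOv3.

The network consumes a single-channel volume resampled to
``input_size**3`` voxels (default 160) and predicts, at three grid
scales (``input/32``, ``input/16``, ``input/8`` cells per axis), one
candidate per cell with 28 channels:

====================  ========================================
channels 0-2          center offsets within the cell (sigmoid)
channels 3-5          log extent ratios w.r.t. the scale anchor
channel 6             objectness logit
channels 7-9          class logits (cervical, thoracic, lumbar)
channels 10-27        spanning vectors u, v of the axial,
                      coronal and sagittal planes (linear)
====================  ========================================

One cubic anchor is attached per scale (0.15, 0.11, 0.07 of the patch
size), matching the typical normalized extents of lumbar, thoracic and
cervical vertebrae on a 160 mm patch.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from . import nn
from .geometry import Box3D, PlaneTriplet, VertebraAnnotation, nms3d, orthonormalize_triplet

logger = logging.getLogger(__name__)

__all__ = [
    "AnchorSpec",
    "YoloConfig",
    "LossWeights",
    "LossBreakdown",
    "Detection",
    "Yolo3DNet",
    "build_yolo3d",
    "encode_yolo_targets",
    "stack_targets",
    "raw_from_targets",
    "decode_yolo_output",
    "yolo_loss",
    "yolo_loss_and_grad",
    "select_detections",
]

# per-candidate channel layout
_XYZ = slice(0, 3)
_WHD = slice(3, 6)
_OBJ = 6
_CLS = slice(7, 10)
_PLN = slice(10, 28)
N_CHANNELS = 28


@dataclass(frozen=True)
class AnchorSpec:
    """Cubic anchor edge length (normalized) per detection scale."""

    scale1: float = 0.15
    scale2: float = 0.11
    scale3: float = 0.07

    def __post_init__(self):
        if not (0 < self.scale3 < self.scale2 < self.scale1 < 1):
            raise ValueError("anchors must satisfy 0 < scale3 < scale2 < scale1 < 1")

    def as_array(self) -> np.ndarray:
        return np.array([self.scale1, self.scale2, self.scale3])


@dataclass
class YoloConfig:
    input_size: int = 160
    width_multiplier: float = 1.0
    n_classes: int = 3
    anchor: AnchorSpec = field(default_factory=AnchorSpec)

    def __post_init__(self):
        if self.input_size % 32:
            raise ValueError("input_size must be divisible by 32 (five stride-2 stages)")

    @property
    def grid_sizes(self) -> tuple[int, int, int]:
        s = self.input_size
        return (s // 32, s // 16, s // 8)

    @property
    def n_candidates(self) -> int:
        return sum(g**3 for g in self.grid_sizes)


@dataclass(frozen=True)
class LossWeights:
    w_OL: float = 1.0
    w_NOL: float = 10.0
    w_BL: float = 10.0
    w_CL: float = 1.0
    w_APL: float = 1.0
    w_CPL: float = 1.0
    w_SPL: float = 1.0


@dataclass
class LossBreakdown:
    OL: float
    NOL: float
    BL: float
    CL: float
    APL: float
    CPL: float
    SPL: float
    total: float


@dataclass
class Detection:
    """One decoded candidate (normalized patch frame)."""

    box: Box3D
    objectness: float
    class_probs: np.ndarray
    planes: PlaneTriplet
    scale: int
    cell: tuple[int, int, int]

    @property
    def score(self) -> float:
        return self.objectness

    @property
    def class_id(self) -> int:
        return int(np.argmax(self.class_probs)) + 1


class _Residual(nn.Module):
    def __init__(self, c, rng, name):
        self.block = nn.Sequential(
            nn.ConvBlock(c, max(c // 2, 4), kernel=1, rng=rng, name=f"{name}.a"),
            nn.ConvBlock(max(c // 2, 4), c, kernel=3, rng=rng, name=f"{name}.b"),
        )
        self.children = [self.block]

    def parameters(self):
        return self.block.parameters()

    def forward(self, x):
        return x + self.block(x)

    def backward(self, dy):
        return dy + self.block.backward(dy)


class _DetectBlock(nn.Module):
    """SPD block: 1x1 squeeze, 3x3 expand, 1x1 prediction head."""

    def __init__(self, cin, rng, name):
        mid = max(cin // 2, 4)
        self.body = nn.Sequential(
            nn.ConvBlock(cin, mid, kernel=1, rng=rng, name=f"{name}.a"),
            nn.ConvBlock(mid, cin, kernel=3, rng=rng, name=f"{name}.b"),
        )
        self.head = nn.Conv3d(cin, N_CHANNELS, kernel=1, bias=True, rng=rng, name=f"{name}.head")
        # head bias priors: background objectness, canonical plane triplet
        # (regression then starts from the population mean, not from noise)
        self.head.bias.value[_OBJ] = -2.0
        self.head.bias.value[_PLN] = PlaneTriplet.identity().to_params().astype(np.float32)
        self.children = [self.body, self.head]

    def parameters(self):
        return self.body.parameters() + self.head.parameters()

    def forward(self, x):
        return self.head(self.body(x))

    def backward(self, dy):
        return self.body.backward(self.head.backward(dy))


class Yolo3DNet(nn.Module):
    """The adapted volumetric YOLOv3 graph (see module docstring).

    ``width_multiplier`` scales every internal channel count; the printed
    architecture corresponds to 1.0.
    """

    def __init__(self, cfg: YoloConfig, seed: int = 0):
        self.cfg = cfg
        rng = np.random.default_rng(seed)
        ch = lambda c: max(4, int(round(c * cfg.width_multiplier)))
        C = {k: ch(k) for k in (32, 64, 128, 256, 512, 1024)}

        B = lambda ci, co, k, s, n: nn.ConvBlock(ci, co, kernel=k, stride=s, rng=rng, name=n)
        self.cnn1 = B(1, C[32], 3, 1, "cnn1")
        self.cnn2 = B(C[32], C[64], 3, 2, "cnn2")
        self.res1 = _Residual(C[64], rng, "res1")
        self.cnn3 = B(C[64], C[128], 3, 2, "cnn3")
        self.res2 = _Residual(C[128], rng, "res2")
        self.cnn4 = B(C[128], C[256], 3, 2, "cnn4")
        self.res3 = _Residual(C[256], rng, "res3")
        self.cnn5 = B(C[256], C[512], 3, 2, "cnn5")
        self.res4 = _Residual(C[512], rng, "res4")
        self.cnn6 = B(C[512], C[1024], 3, 2, "cnn6")
        self.res5 = _Residual(C[1024], rng, "res5")

        self.cnn7 = B(C[1024], C[512], 1, 1, "cnn7")
        self.cnn8 = B(C[512], C[1024], 3, 1, "cnn8")
        self.spd1 = _DetectBlock(C[1024], rng, "spd1")

        self.cnn9 = B(C[512], C[256], 1, 1, "cnn9")
        self.ups1 = nn.Upsample3d(2)
        self.cnn10 = B(C[256] + C[512], C[256], 1, 1, "cnn10")
        self.cnn11 = B(C[256], C[512], 3, 1, "cnn11")
        self.spd2 = _DetectBlock(C[512], rng, "spd2")

        self.cnn12 = B(C[512], C[128], 1, 1, "cnn12")
        self.ups2 = nn.Upsample3d(2)
        self.cnn13 = B(C[128] + C[256], C[128], 1, 1, "cnn13")
        self.cnn14 = B(C[128], C[256], 3, 1, "cnn14")
        self.spd3 = _DetectBlock(C[256], rng, "spd3")

        self._c = C
        self.children = [
            self.cnn1, self.cnn2, self.res1, self.cnn3, self.res2, self.cnn4,
            self.res3, self.cnn5, self.res4, self.cnn6, self.res5, self.cnn7,
            self.cnn8, self.spd1, self.cnn9, self.cnn10, self.cnn11, self.spd2,
            self.cnn12, self.cnn13, self.cnn14, self.spd3,
        ]

    def parameters(self):
        return [p for m in self.children for p in m.parameters()]

    def forward(self, x):
        """x: (B, 1, S, S, S) -> list of three raw maps, coarse to fine."""
        if x.ndim != 5 or x.shape[2] != self.cfg.input_size:
            raise ValueError(
                f"expected (B,1,{self.cfg.input_size}^3) input, got {x.shape}"
            )
        t = self.cnn1(x)
        t = self.res1(self.cnn2(t))
        t = self.res2(self.cnn3(t))
        r3 = self.res3(self.cnn4(t))
        r4 = self.res4(self.cnn5(r3))
        r5 = self.res5(self.cnn6(r4))

        y7 = self.cnn7(r5)
        raw1 = self.spd1(self.cnn8(y7))

        u1 = self.ups1(self.cnn9(y7))
        cat1 = np.concatenate([u1, r4], axis=1)
        y11 = self.cnn11(self.cnn10(cat1))
        raw2 = self.spd2(y11)

        u2 = self.ups2(self.cnn12(y11))
        cat2 = np.concatenate([u2, r3], axis=1)
        raw3 = self.spd3(self.cnn14(self.cnn13(cat2)))

        self._split1 = u1.shape[1]
        self._split2 = u2.shape[1]
        return [raw1, raw2, raw3]

    def backward(self, d_raws):
        d1, d2, d3 = d_raws
        d_cat2 = self.cnn13.backward(self.cnn14.backward(self.spd3.backward(d3)))
        d_u2, d_r3b = d_cat2[:, : self._split2], d_cat2[:, self._split2 :]
        d_y11 = self.cnn12.backward(self.ups2.backward(d_u2))
        d_y11 = d_y11 + self.spd2.backward(d2)
        d_cat1 = self.cnn10.backward(self.cnn11.backward(d_y11))
        d_u1, d_r4b = d_cat1[:, : self._split1], d_cat1[:, self._split1 :]
        d_y7 = self.cnn9.backward(self.ups1.backward(d_u1))
        d_y7 = d_y7 + self.cnn8.backward(self.spd1.backward(d1))
        d_r5 = self.cnn7.backward(d_y7)
        d_r4 = self.cnn6.backward(self.res5.backward(d_r5)) + d_r4b
        d_r3 = self.cnn5.backward(self.res4.backward(d_r4)) + d_r3b
        d = self.cnn4.backward(self.res3.backward(d_r3))
        d = self.cnn3.backward(self.res2.backward(d))
        d = self.cnn2.backward(self.res1.backward(d))
        return self.cnn1.backward(d)


def build_yolo3d(cfg: YoloConfig, seed: int = 0) -> Yolo3DNet:
    """Instantiate the detector; raises if the shape contract cannot hold."""
    return Yolo3DNet(cfg, seed=seed)


def _size_iou(extents: np.ndarray, anchor: float) -> float:
    """IoU of two boxes sharing a center: one with ``extents``, one cubic."""
    inter = float(np.prod(np.minimum(extents, anchor)))
    union = float(np.prod(extents)) + anchor**3 - inter
    return inter / union


def assign_scale(extents: np.ndarray, anchors: AnchorSpec) -> int:
    """Index of the scale whose anchor best matches the box size."""
    ious = [_size_iou(np.asarray(extents, dtype=float), a) for a in anchors.as_array()]
    return int(np.argmax(ious))


def scale_preference(extents: np.ndarray, anchors: AnchorSpec) -> list[int]:
    """Scales ordered by descending anchor size-IoU (best first)."""
    ious = [_size_iou(np.asarray(extents, dtype=float), a) for a in anchors.as_array()]
    return sorted(range(3), key=lambda s: -ious[s])


def _empty_targets(cfg: YoloConfig) -> list[dict]:
    out = []
    for g in cfg.grid_sizes:
        out.append(
            {
                "obj": np.zeros((g, g, g), dtype=np.float32),
                "box": np.zeros((6, g, g, g), dtype=np.float32),
                "cls": np.zeros((g, g, g), dtype=np.int64),
                "planes": np.zeros((18, g, g, g), dtype=np.float32),
            }
        )
    return out


def encode_yolo_targets(
    annotations: list[VertebraAnnotation], cfg: YoloConfig, plane_dilation: int = 0
) -> list[dict]:
    """Grid targets per scale for boxes given in the normalized patch frame.

    Each vertebra claims the cell containing its center at the scale
    whose anchor maximizes size-IoU with its extents *and* at the finest
    scale (at most one responsible cell per vertebra per scale).  The
    size-matched scale carries the anchor prior; the finest grid
    separates closely stacked vertebrae whose centers share a coarse
    cell, so no ground truth is silently discarded, while the remaining
    scale stays background (a vertebra far from an anchor's size should
    not fire that head).  Duplicate per-scale predictions of one
    vertebra are merged by non-max suppression at inference.  When two
    vertebrae share a cell at some scale, the larger one keeps it there.

    ``plane_dilation`` > 0 additionally marks the Chebyshev neighborhood
    of each vertebra's finest-scale cell for spanning-vector supervision
    (``plane_mask``; ambiguous cells follow the nearest vertebra center).
    A training aid only — objectness, box and class targets are
    unaffected — and off by default.
    """
    targets = _empty_targets(cfg)
    anchors = cfg.anchor.as_array()
    occupancy: dict[tuple[int, tuple], float] = {}

    def write(s, cell, ann, c):
        g = cfg.grid_sizes[s]
        t = targets[s]
        t["obj"][cell] = 1.0
        off = c * g - np.array(cell)
        t["box"][(slice(0, 3),) + cell] = off
        t["box"][(slice(3, 6),) + cell] = np.log(ann.box.extents / anchors[s])
        t["cls"][cell] = ann.class_id
        t["planes"][(slice(None),) + cell] = ann.planes.to_params()

    for ann in annotations:
        if ann.box.frame != "normalized":
            raise ValueError("encode_yolo_targets expects normalized boxes")
        c = np.clip(ann.box.center, 0.0, 1.0 - 1e-9)
        for s in sorted({assign_scale(ann.box.extents, cfg.anchor), 2}):
            g = cfg.grid_sizes[s]
            cell = tuple(np.minimum((c * g).astype(int), g - 1))
            key = (s, cell)
            if key in occupancy:
                if ann.box.volume <= occupancy[key]:
                    logger.warning(
                        "cell collision at scale %d cell %s; keeping larger box", s, cell
                    )
                    continue
                logger.warning(
                    "cell collision at scale %d cell %s; replacing smaller box", s, cell
                )
            occupancy[key] = ann.box.volume
            write(s, cell, ann, c)

    for t in targets:
        t["plane_mask"] = t["obj"] > 0.5
    if plane_dilation > 0 and annotations:
        s = 2
        g = cfg.grid_sizes[s]
        t = targets[s]
        owner_dist = np.full((g, g, g), np.inf)
        owner_params = {}
        for ann in annotations:
            c = np.clip(ann.box.center, 0.0, 1.0 - 1e-9)
            cell = np.minimum((c * g).astype(int), g - 1)
            lo = np.maximum(cell - plane_dilation, 0)
            hi = np.minimum(cell + plane_dilation, g - 1)
            params = ann.planes.to_params()
            for i in range(lo[0], hi[0] + 1):
                for j in range(lo[1], hi[1] + 1):
                    for k in range(lo[2], hi[2] + 1):
                        d = np.linalg.norm((np.array([i, j, k]) + 0.5) / g - c)
                        if d < owner_dist[i, j, k]:
                            owner_dist[i, j, k] = d
                            owner_params[(i, j, k)] = params
        for (i, j, k), params in owner_params.items():
            t["plane_mask"][i, j, k] = True
            t["planes"][:, i, j, k] = params
    return targets


def raw_from_targets(targets: list[dict], cfg: YoloConfig, logit_mag: float = 12.0) -> list[np.ndarray]:
    """Raw activations that decode exactly back to the encoded targets.

    Used for round-trip checks and for driving the post-detection chain
    without a trained network.
    """
    raws = []
    for t in targets:
        g = t["obj"].shape[0]
        raw = np.zeros((1, N_CHANNELS, g, g, g), dtype=np.float32)
        eps = 1e-6
        off = np.clip(t["box"][0:3], eps, 1 - eps)
        raw[0, _XYZ] = np.log(off / (1 - off))
        raw[0, _WHD] = t["box"][3:6]
        raw[0, _OBJ] = np.where(t["obj"] > 0.5, logit_mag, -logit_mag)
        for k in range(3):
            raw[0, 7 + k] = np.where(t["cls"] == k + 1, logit_mag, 0.0)
        raw[0, _PLN] = t["planes"]
        raws.append(raw)
    return raws


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-np.clip(x, -60, 60)))


def decode_yolo_output(
    raws: list[np.ndarray], cfg: YoloConfig, batch_index: int = 0, min_objectness: float = 0.0
) -> list[Detection]:
    """Decode raw per-scale maps into candidate detections.

    center = (sigmoid(t_xyz) + cell) / G; extents = anchor * exp(t_whd);
    objectness and class probabilities through sigmoids; spanning vectors
    taken linearly and orthonormalized.  ``min_objectness`` can skip
    hopeless cells early (0 decodes every candidate).
    """
    if len(raws) != 3:
        raise ValueError("expected raw outputs for three scales")
    anchors = cfg.anchor.as_array()
    dets: list[Detection] = []
    for s, raw in enumerate(raws):
        g = cfg.grid_sizes[s]
        if raw.shape[1:] != (N_CHANNELS, g, g, g):
            raise ValueError(f"scale {s}: expected {(N_CHANNELS, g, g, g)}, got {raw.shape[1:]}")
        r = np.asarray(raw[batch_index], dtype=float)
        obj = _sigmoid(r[_OBJ])
        keep = np.argwhere(obj >= min_objectness)
        if keep.size == 0:
            continue
        idx = tuple(keep.T)
        off = _sigmoid(r[_XYZ][(slice(None),) + idx])  # (3, n)
        centers = (off + keep.T) / g
        extents = anchors[s] * np.exp(r[_WHD][(slice(None),) + idx])
        probs = _sigmoid(r[_CLS][(slice(None),) + idx])
        planes = r[_PLN][(slice(None),) + idx]
        for i in range(keep.shape[0]):
            c = np.clip(centers[:, i], 0.0, 1.0)
            e = np.clip(extents[:, i], 1e-6, 1.0)
            try:
                triplet = orthonormalize_triplet(planes[:, i])
            except ValueError:
                # degenerate regressed vectors (e.g. an untrained network):
                # fall back to the canonical patient frame
                triplet = PlaneTriplet.identity()
            dets.append(
                Detection(
                    box=Box3D(c, e, frame="normalized"),
                    objectness=float(obj[idx[0][i], idx[1][i], idx[2][i]]),
                    class_probs=probs[:, i].copy(),
                    planes=triplet,
                    scale=s,
                    cell=tuple(int(v) for v in keep[i]),
                )
            )
    return dets


def _bce(p, target):
    p = np.clip(p, 1e-12, 1 - 1e-12)
    return -(target * np.log(p) + (1 - target) * np.log(1 - p))


def stack_targets(per_sample: list[list[dict]]) -> list[dict]:
    """Stack per-volume grid targets into batched targets (leading B axis)."""
    out = []
    for s in range(3):
        out.append({k: np.stack([t[s][k] for t in per_sample]) for k in per_sample[0][s]})
    return out


def _batched(targets: list[dict], B: int) -> list[dict]:
    """Promote shared (unbatched) targets to a broadcast batched view."""
    if targets[0]["obj"].ndim == 4:
        return targets
    return [
        {k: np.broadcast_to(v, (B,) + v.shape) for k, v in t.items()} for t in targets
    ]


def yolo_loss_and_grad(
    raws: list[np.ndarray], targets: list[dict], w: LossWeights = LossWeights()
) -> tuple[LossBreakdown, list[np.ndarray]]:
    """Composite detection loss and its gradient w.r.t. the raw maps.

    Terms (each averaged over its supporting cells, across all scales
    and the batch): OL/NOL binary cross-entropy on objectness at object /
    background cells; BL mean squared error on the six box parameters;
    CL softmax cross-entropy over the three classes; APL/CPL/SPL mean
    squared error on each plane's six spanning components, normalized by
    all 18 plane components so the three terms sum to the overall plane
    MSE.  Empty supports contribute zero.

    ``targets`` may be per-scale grids shared by the whole batch, or
    batched per-sample grids (leading batch axis) from
    :func:`stack_targets`.
    """
    B = raws[0].shape[0]
    targets = _batched(targets, B)
    n_obj = sum(int((t["obj"] > 0.5).sum()) for t in targets)
    n_noobj = sum(int((t["obj"] <= 0.5).sum()) for t in targets)
    n_pl = sum(
        int(t.get("plane_mask", t["obj"] > 0.5).sum()) for t in targets
    )

    terms = dict(OL=0.0, NOL=0.0, BL=0.0, CL=0.0, APL=0.0, CPL=0.0, SPL=0.0)
    grads = [np.zeros_like(r) for r in raws]

    for s, (raw, t) in enumerate(zip(raws, targets)):
        obj_mask = t["obj"] > 0.5  # (B, g, g, g)
        p_obj = _sigmoid(raw[:, _OBJ])

        if n_obj:
            terms["OL"] += float(_bce(p_obj[obj_mask], 1.0).sum()) / n_obj
        if n_noobj:
            terms["NOL"] += float(_bce(p_obj[~obj_mask], 0.0).sum()) / n_noobj
        d_obj = np.zeros_like(p_obj)
        if n_obj:
            d_obj[obj_mask] = (p_obj[obj_mask] - 1.0) * (w.w_OL / n_obj)
        if n_noobj:
            d_obj[~obj_mask] = p_obj[~obj_mask] * (w.w_NOL / n_noobj)
        grads[s][:, _OBJ] = d_obj

        idx = np.argwhere(obj_mask)  # (n, 4): b, i, j, k
        if n_obj and idx.size:
            b, i, j, k = idx.T
            raw_at = raw[b, :, i, j, k]  # (n, 28)
            # box: sigmoid on offsets, identity on log-extent ratios
            p_off = _sigmoid(raw_at[:, 0:3])
            t_box = t["box"][b, :, i, j, k]  # (n, 6)
            t_off, t_whd = t_box[:, 0:3], t_box[:, 3:6]
            p_whd = raw_at[:, 3:6]
            terms["BL"] += float(((p_off - t_off) ** 2).sum() + ((p_whd - t_whd) ** 2).sum()) / (
                6 * n_obj
            )
            g_at = np.zeros_like(raw_at)
            g_at[:, 0:3] = 2.0 * (p_off - t_off) * p_off * (1 - p_off) * (w.w_BL / (6 * n_obj))
            g_at[:, 3:6] = 2.0 * (p_whd - t_whd) * (w.w_BL / (6 * n_obj))

            # class: softmax cross-entropy over the three region classes
            logits = raw_at[:, _CLS]
            logits = logits - logits.max(axis=1, keepdims=True)
            ez = np.exp(logits)
            sm = ez / ez.sum(axis=1, keepdims=True)
            onehot = np.zeros_like(sm)
            cls = t["cls"][b, i, j, k] - 1
            onehot[np.arange(cls.size), cls] = 1.0
            terms["CL"] += float(-(onehot * np.log(np.clip(sm, 1e-12, None))).sum()) / n_obj
            g_at[:, _CLS] = (sm - onehot) * (w.w_CL / n_obj)

            g_at[:, _OBJ] = grads[s][b, _OBJ, i, j, k]
            grads[s][b, :, i, j, k] = g_at

        # planes: MSE per plane, denominator 18 (all spanning components),
        # over the plane-supervision cells (= object cells by default)
        pl_mask = t.get("plane_mask", t["obj"] > 0.5)
        idx_pl = np.argwhere(pl_mask)
        if n_pl and idx_pl.size:
            b, i, j, k = idx_pl.T
            diff = raw[b, :, i, j, k][:, _PLN] - t["planes"][b, :, i, j, k]
            w_pln = (w.w_APL, w.w_CPL, w.w_SPL)
            g_pl = np.zeros((idx_pl.shape[0], 18), dtype=raw.dtype)
            for pi, key in enumerate(("APL", "CPL", "SPL")):
                sl = slice(6 * pi, 6 * pi + 6)
                terms[key] += float((diff[:, sl] ** 2).sum()) / (18 * n_pl)
                g_pl[:, sl] = 2.0 * diff[:, sl] * (w_pln[pi] / (18 * n_pl))
            cur = grads[s][b, :, i, j, k]
            cur[:, _PLN] = g_pl
            grads[s][b, :, i, j, k] = cur

    total = (
        w.w_OL * terms["OL"]
        + w.w_NOL * terms["NOL"]
        + w.w_BL * terms["BL"]
        + w.w_CL * terms["CL"]
        + w.w_APL * terms["APL"]
        + w.w_CPL * terms["CPL"]
        + w.w_SPL * terms["SPL"]
    )
    return LossBreakdown(**terms, total=total), grads


def yolo_loss(
    raws: list[np.ndarray], targets: list[dict], w: LossWeights = LossWeights()
) -> LossBreakdown:
    return yolo_loss_and_grad(raws, targets, w)[0]


def select_detections(
    dets: list[Detection],
    conf_thr: float = 0.10,
    iou_thr: float = 0.15,
    classprob_thr: float = 0.25,
) -> list[Detection]:
    """Confidence gate, per-class NMS, then class-probability gate.

    Defaults are the best threshold combination from the hyperparameter
    search (confidence 0.10, IoU 0.15, class probability 0.25).
    """
    above = [d for d in dets if d.objectness >= conf_thr]
    kept = nms3d(above, iou_thr)
    return [d for d in kept if float(np.max(d.class_probs)) >= classprob_thr]
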