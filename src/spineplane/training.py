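"""Training and inference pipelines tying the networks to the data.

The detector consumes whole volumes resampled to its input size with
intensities rescaled to [0, 1]; detections are mapped back to world mm
through the stored spacing/origin.  The segmentation network runs in a
sliding window with 50% overlap and averaged logits (a single window
when the patch covers the volume).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from skimage.transform import resize

from . import nn
from .augment import AugmentConfig, augment_sample
from .geometry import Box3D, PlaneTriplet, VertebraAnnotation
from .segplane import UNet3D, extract_annotations, seg_loss_and_grad
from .yolo3d import (
    Detection,
    LossWeights,
    Yolo3DNet,
    YoloConfig,
    decode_yolo_output,
    encode_yolo_targets,
    select_detections,
    stack_targets,
    yolo_loss_and_grad,
)

logger = logging.getLogger(__name__)

__all__ = [
    "normalize_annotations",
    "denormalize_detection",
    "prepare_volume",
    "train_yolo",
    "infer_yolo",
    "train_seg",
    "infer_seg",
    "save_model",
    "load_model",
]


def normalize_annotations(
    annotations: list[VertebraAnnotation], fov_mm: np.ndarray, origin=(0.0, 0.0, 0.0)
) -> list[VertebraAnnotation]:
    """World-mm annotations -> normalized patch frame ([0,1] per axis)."""
    fov = np.broadcast_to(np.asarray(fov_mm, dtype=float), (3,))
    origin = np.asarray(origin, dtype=float)
    out = []
    for a in annotations:
        out.append(
            VertebraAnnotation(
                box=Box3D((a.box.center - origin) / fov, a.box.extents / fov, frame="normalized"),
                planes=PlaneTriplet(a.planes.rot.copy()),
                class_id=a.class_id,
            )
        )
    return out


def denormalize_detection(
    det: Detection, fov_mm: np.ndarray, origin=(0.0, 0.0, 0.0)
) -> VertebraAnnotation:
    """Normalized detection -> world-mm annotation."""
    fov = np.broadcast_to(np.asarray(fov_mm, dtype=float), (3,))
    origin = np.asarray(origin, dtype=float)
    return VertebraAnnotation(
        box=Box3D(det.box.center * fov + origin, np.maximum(det.box.extents * fov, 1e-6)),
        planes=det.planes,
        class_id=det.class_id,
    )


def prepare_volume(volume: np.ndarray, input_size: int) -> np.ndarray:
    """Resample to the network input size and rescale intensities to [0,1]."""
    v = np.asarray(volume, dtype=np.float32)
    if v.shape != (input_size,) * 3:
        v = resize(v, (input_size,) * 3, order=1, anti_aliasing=False, preserve_range=True)
    lo, hi = float(v.min()), float(v.max())
    if hi > lo:
        v = (v - lo) / (hi - lo)
    return v.astype(np.float32)


@dataclass
class TrainLog:
    losses: list  # LossBreakdown (YOLO) or float (seg) per step


def train_yolo(
    samples,
    cfg: YoloConfig,
    epochs: int = 10,
    lr: float = 1e-5,
    weight_decay: float = 1e-4,
    weights: LossWeights = LossWeights(),
    seed: int = 0,
    augment_cfg: AugmentConfig | None = None,
    net: Yolo3DNet | None = None,
    max_steps: int | None = None,
    lr_milestones: dict[int, float] | None = None,
    batch_size: int = 1,
    plane_dilation: int = 0,
) -> tuple[Yolo3DNet, TrainLog]:
    """Train the detector on (volume, annotations, spacing) samples.

    ``samples``: sequence of ``(volume, annotations_world_mm, spacing)``;
    Adam with L2 decay; per-sample grid targets are stacked into small
    batches (normalization is per sample, so batching is purely
    computational).
    """
    rng = np.random.default_rng(seed)
    if net is None:
        net = Yolo3DNet(cfg, seed=seed)
    opt = nn.Adam(net.parameters(), lr=lr, weight_decay=weight_decay)
    net.train()
    log = TrainLog(losses=[])
    step = 0
    prepared = []
    for vol, anns, spacing in samples:
        fov = np.asarray(vol.shape) * spacing
        prepared.append((vol, anns, spacing, fov))
    for epoch in range(epochs):
        if lr_milestones and epoch in lr_milestones:
            opt.lr = lr_milestones[epoch]
            logger.info("epoch %d: learning rate -> %g", epoch, opt.lr)
        order = rng.permutation(len(prepared))
        ep_total = 0.0
        for start in range(0, len(order), batch_size):
            xs, ts = [], []
            for i in order[start : start + batch_size]:
                vol, anns, spacing, fov = prepared[i]
                if augment_cfg is not None:
                    vol, anns, _ = augment_sample(
                        vol, anns, None, augment_cfg, rng=rng, spacing=spacing
                    )
                xs.append(prepare_volume(vol, cfg.input_size)[None])
                ts.append(
                    encode_yolo_targets(
                        normalize_annotations(anns, fov), cfg, plane_dilation=plane_dilation
                    )
                )
            x = np.stack(xs)
            targets = stack_targets(ts)
            raws = net.forward(x)
            loss, grads = yolo_loss_and_grad(raws, targets, weights)
            opt.zero_grad()
            net.backward(grads)
            opt.step()
            log.losses.append(loss)
            ep_total += loss.total
            step += 1
            if max_steps is not None and step >= max_steps:
                return net, log
        n_batches = int(np.ceil(len(prepared) / batch_size))
        logger.info(
            "epoch %d: mean total loss %.5f (OL %.4f NOL %.4f BL %.4f CL %.4f)",
            epoch,
            ep_total / n_batches,
            np.mean([l.OL for l in log.losses[-n_batches:]]),
            np.mean([l.NOL for l in log.losses[-n_batches:]]),
            np.mean([l.BL for l in log.losses[-n_batches:]]),
            np.mean([l.CL for l in log.losses[-n_batches:]]),
        )
    return net, log


def infer_yolo(
    net: Yolo3DNet,
    volume: np.ndarray,
    spacing: float,
    origin=(0.0, 0.0, 0.0),
    conf_thr: float = 0.10,
    iou_thr: float = 0.15,
    classprob_thr: float = 0.25,
) -> list[VertebraAnnotation]:
    """Whole-volume detection: resample, forward, decode, select, map to mm."""
    cfg = net.cfg
    fov = np.asarray(volume.shape) * spacing
    x = prepare_volume(volume, cfg.input_size)[None, None]
    net.eval()
    raws = net.forward(x)
    dets = decode_yolo_output(raws, cfg, min_objectness=min(conf_thr, 1e-3))
    logger.info("decoded %d candidate detections (of %d cells)", len(dets), cfg.n_candidates)
    kept = select_detections(dets, conf_thr, iou_thr, classprob_thr)
    logger.info("%d detections survive thresholding + NMS", len(kept))
    return [denormalize_detection(d, fov, origin) for d in kept]


def train_seg(
    samples,
    net: UNet3D | None = None,
    epochs: int = 10,
    lr: float = 1e-2,
    momentum: float = 0.99,
    weight_decay: float = 3e-5,
    w_CE: float = 1.0,
    w_DC: float = 1.0,
    seed: int = 0,
    depth: int = 3,
    base_width: int = 16,
    max_steps: int | None = None,
) -> tuple[UNet3D, TrainLog]:
    """Train the plane-cylinder segmentation network.

    ``samples``: sequence of ``(volume, masks)`` with masks of shape
    (3, D, H, W) labeled in {0..3}.  Mini-batch gradient descent with
    momentum, one volume per step.
    """
    rng = np.random.default_rng(seed)
    if net is None:
        net = UNet3D(depth=depth, base_width=base_width, seed=seed)
    opt = nn.SGD(net.parameters(), lr=lr, momentum=momentum, weight_decay=weight_decay)
    net.train()
    log = TrainLog(losses=[])
    step = 0
    for epoch in range(epochs):
        order = rng.permutation(len(samples))
        for i in order:
            vol, masks = samples[i]
            x = prepare_volume(vol, vol.shape[0])[None, None]
            logits = net.forward(x)
            loss, grad = seg_loss_and_grad(logits, masks, w_CE, w_DC)
            opt.zero_grad()
            net.backward(grad)
            opt.step()
            log.losses.append(loss)
            step += 1
            if max_steps is not None and step >= max_steps:
                return net, log
        logger.info("seg epoch %d: mean loss %.5f", epoch, float(np.mean(log.losses[-len(samples):])))
    return net, log


def _sliding_windows(shape, patch, stride):
    starts = []
    for n in shape:
        s = list(range(0, max(n - patch, 0) + 1, stride))
        if s[-1] != n - patch and n > patch:
            s.append(n - patch)
        starts.append(s)
    for i in starts[0]:
        for j in starts[1]:
            for k in starts[2]:
                yield i, j, k


def infer_seg(
    net: UNet3D,
    volume: np.ndarray,
    spacing: float,
    origin=(0.0, 0.0, 0.0),
    patch: int | None = None,
    eps: float = 2.0,
    min_samples: int = 10,
) -> list[VertebraAnnotation]:
    """Sliding-window segmentation followed by the clustering chain."""
    net.eval()
    vol = np.asarray(volume, dtype=np.float32)
    lo, hi = float(vol.min()), float(vol.max())
    if hi > lo:
        vol = (vol - lo) / (hi - lo)
    if patch is None:
        patch = min(64, min(vol.shape))
    patch = min(patch, min(vol.shape))
    net.check_patch(patch)
    logits_sum = np.zeros((3, 4) + vol.shape, dtype=np.float32)
    counts = np.zeros(vol.shape, dtype=np.float32)
    for i, j, k in _sliding_windows(vol.shape, patch, max(patch // 2, 1)):
        window = vol[i : i + patch, j : j + patch, k : k + patch][None, None]
        out = net.forward(window)[0]
        logits_sum[:, :, i : i + patch, j : j + patch, k : k + patch] += out
        counts[i : i + patch, j : j + patch, k : k + patch] += 1.0
    logits = logits_sum / counts[None, None]
    labels = np.stack([np.argmax(logits[c], axis=0) for c in range(3)]).astype(np.uint8)
    logger.info("segmentation foreground voxels per channel: %s", [int((l > 0).sum()) for l in labels])
    return extract_annotations(
        labels, spacing=spacing, origin=origin, eps=eps, min_samples=min_samples
    )


def _iter_batchnorms(module):
    if isinstance(module, nn.BatchNorm3d):
        yield module
    for ch in getattr(module, "children", []):
        yield from _iter_batchnorms(ch)


def save_model(path, net, meta: dict | None = None):
    """Persist parameters + batch-norm statistics as an .npz archive."""
    arrays = {}
    for i, p in enumerate(net.parameters()):
        arrays[f"param_{i}"] = p.value
    for i, bn in enumerate(_iter_batchnorms(net)):
        arrays[f"bn_mean_{i}"] = bn.running_mean
        arrays[f"bn_var_{i}"] = bn.running_var
    import json

    arrays["meta"] = np.frombuffer(json.dumps(meta or {}).encode(), dtype=np.uint8)
    np.savez_compressed(path, **arrays)


def load_model(path, net):
    """Load parameters saved by :func:`save_model` into ``net`` (in place)."""
    data = np.load(path)
    for i, p in enumerate(net.parameters()):
        p.value = data[f"param_{i}"].astype(np.float32)
    for i, bn in enumerate(_iter_batchnorms(net)):
        bn.running_mean = data[f"bn_mean_{i}"].astype(np.float32)
        bn.running_var = data[f"bn_var_{i}"].astype(np.float32)
    import json

    meta = json.loads(bytes(data["meta"]).decode()) if "meta" in data else {}
    return net, meta
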