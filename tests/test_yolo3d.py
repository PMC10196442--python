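"""Detector architecture contract, target encoding, loss and selection."""

import numpy as np
import pytest

from spineplane.geometry import Box3D, PlaneTriplet, VertebraAnnotation, plane_angle_error
from spineplane.yolo3d import (
    AnchorSpec,
    Detection,
    LossWeights,
    YoloConfig,
    assign_scale,
    build_yolo3d,
    decode_yolo_output,
    encode_yolo_targets,
    raw_from_targets,
    select_detections,
    yolo_loss,
    yolo_loss_and_grad,
)

from conftest import random_triplet


@pytest.fixture(scope="module")
def small_cfg():
    return YoloConfig(input_size=64, width_multiplier=0.25)


@pytest.fixture(scope="module")
def small_net(small_cfg):
    return build_yolo3d(small_cfg, seed=0)


class TestArchitecture:
    def test_grid_sizes_160(self):
        cfg = YoloConfig(input_size=160)
        assert cfg.grid_sizes == (5, 10, 20)
        assert cfg.n_candidates == 5**3 + 10**3 + 20**3 == 9125

    def test_grid_sizes_64(self, small_cfg):
        assert small_cfg.grid_sizes == (2, 4, 8)

    def test_invalid_input_size(self):
        with pytest.raises(ValueError):
            YoloConfig(input_size=100)

    def test_forward_shape_contract(self, small_cfg, small_net):
        x = np.zeros((1, 1, 64, 64, 64), dtype=np.float32)
        small_net.eval()
        raws = small_net.forward(x)
        assert [r.shape for r in raws] == [
            (1, 28, 2, 2, 2),
            (1, 28, 4, 4, 4),
            (1, 28, 8, 8, 8),
        ]

    def test_forward_rejects_wrong_size(self, small_net):
        with pytest.raises(ValueError):
            small_net.forward(np.zeros((1, 1, 32, 32, 32), dtype=np.float32))

    def test_width_multiplier_scales_channels(self):
        net = build_yolo3d(YoloConfig(input_size=64, width_multiplier=0.25))
        # first conv: 32 channels at width 1.0 -> 8 at 0.25
        assert net.cnn1.children[0].cout == 8

    def test_anchor_ordering_validated(self):
        with pytest.raises(ValueError):
            AnchorSpec(scale1=0.07, scale2=0.11, scale3=0.15)


class TestEncoding:
    def test_anchor_matched_box_goes_to_scale1(self):
        cfg = YoloConfig(input_size=160)
        ann = VertebraAnnotation(
            Box3D((0.5, 0.5, 0.5), (0.15, 0.15, 0.15), frame="normalized"),
            PlaneTriplet.identity(),
            3,
        )
        t = encode_yolo_targets([ann], cfg)
        assert assign_scale(np.array([0.15] * 3), cfg.anchor) == 0
        assert t[0]["obj"][2, 2, 2] == 1.0
        # also represented on the finest grid; the middle scale stays empty
        assert t[1]["obj"].sum() == 0 and t[2]["obj"].sum() == 1

    def test_small_box_goes_to_scale3(self):
        cfg = YoloConfig(input_size=160)
        assert assign_scale(np.array([0.07] * 3), cfg.anchor) == 2
        ann = VertebraAnnotation(
            Box3D((0.5, 0.5, 0.5), (0.07,) * 3, frame="normalized"),
            PlaneTriplet.identity(),
            1,
        )
        t = encode_yolo_targets([ann], cfg)
        assert t[2]["obj"].sum() == 1.0

    def test_empty_annotations(self, small_cfg):
        t = encode_yolo_targets([], small_cfg)
        assert all(x["obj"].sum() == 0 for x in t)

    def test_coarse_collision_resolved_at_fine_scale(self, small_cfg):
        # two vertebrae sharing coarse cells stay separated on the fine grid
        mk = lambda z: VertebraAnnotation(
            Box3D((0.3, 0.3, z), (0.15,) * 3, frame="normalized"),
            PlaneTriplet.identity(),
            3,
        )
        t = encode_yolo_targets([mk(0.30), mk(0.45)], small_cfg)
        assert t[0]["obj"].sum() == 1  # shared 2-cell grid: larger box kept
        assert t[2]["obj"].sum() == 2  # 8-cell grid separates them

    def test_world_frame_rejected(self, small_cfg):
        ann = VertebraAnnotation(
            Box3D((10, 10, 10), (20, 20, 20), frame="world"), PlaneTriplet.identity(), 1
        )
        with pytest.raises(ValueError):
            encode_yolo_targets([ann], small_cfg)


class TestDecoding:
    def test_zero_activations_closed_form(self):
        cfg = YoloConfig(input_size=160)
        raws = [np.zeros((1, 28) + (g,) * 3, dtype=np.float32) for g in cfg.grid_sizes]
        dets = decode_yolo_output(raws, cfg)
        d0 = next(d for d in dets if d.scale == 0 and d.cell == (0, 0, 0))
        assert np.allclose(d0.box.center, 0.1)  # (sigmoid(0)+0)/5
        assert np.allclose(d0.box.extents, 0.15)  # anchor * exp(0)
        assert d0.objectness == pytest.approx(0.5)

    def test_candidate_count(self, small_cfg):
        raws = [np.zeros((1, 28) + (g,) * 3, dtype=np.float32) for g in small_cfg.grid_sizes]
        assert len(decode_yolo_output(raws, small_cfg)) == small_cfg.n_candidates

    def test_objectness_saturation(self, small_cfg):
        raws = [np.full((1, 28) + (g,) * 3, 0.0, dtype=np.float32) for g in small_cfg.grid_sizes]
        raws[0][0, 6] = -50.0
        dets = decode_yolo_output(raws, small_cfg)
        assert min(d.objectness for d in dets if d.scale == 0) < 1e-12

    def test_shape_mismatch_raises(self, small_cfg):
        raws = [np.zeros((1, 28, 3, 3, 3), dtype=np.float32)] * 3
        with pytest.raises(ValueError):
            decode_yolo_output(raws, small_cfg)

    def test_encode_decode_round_trip(self, small_cfg, rng):
        anns = []
        for z in (0.2, 0.5, 0.8):
            e = float(rng.uniform(0.05, 0.15))
            anns.append(
                VertebraAnnotation(
                    Box3D((rng.uniform(0.3, 0.7), rng.uniform(0.3, 0.7), z), (e,) * 3,
                          frame="normalized"),
                    random_triplet(rng),
                    int(rng.integers(1, 4)),
                )
            )
        targets = encode_yolo_targets(anns, small_cfg)
        dets = decode_yolo_output(raw_from_targets(targets, small_cfg), small_cfg,
                                  min_objectness=0.5)
        n_positives = sum(int(t["obj"].sum()) for t in targets)
        assert len(dets) == n_positives >= len(anns)
        for ann in anns:
            best = min(dets, key=lambda d: np.linalg.norm(d.box.center - ann.box.center))
            g = small_cfg.grid_sizes[best.scale]
            assert np.all(np.abs(best.box.center - ann.box.center) <= 0.5 / g + 1e-5)
            assert np.allclose(best.box.extents, ann.box.extents, atol=1e-5)
            assert best.class_id == ann.class_id
            for p in ("axial", "coronal", "sagittal"):
                assert plane_angle_error(
                    best.planes.normal(p), ann.planes.normal(p)
                ) < 0.1


def _one_object_setup(cfg, single_cell=False):
    ann = VertebraAnnotation(
        Box3D((0.5, 0.5, 0.5), (0.14,) * 3, frame="normalized"), PlaneTriplet.identity(), 2
    )
    targets = encode_yolo_targets([ann], cfg)
    if single_cell:  # keep only the best-scale cell as positive
        for s in (1, 2):
            targets[s]["obj"][...] = 0.0
            targets[s]["plane_mask"][...] = False
    raws = raw_from_targets(targets, cfg)
    return ann, targets, raws


class TestLoss:
    def test_perfect_prediction_zero_terms(self, small_cfg):
        _, targets, raws = _one_object_setup(small_cfg)
        loss = yolo_loss(raws, targets)
        assert loss.BL == pytest.approx(0.0, abs=1e-8)
        assert loss.CL == pytest.approx(0.0, abs=1e-4)
        assert loss.APL == pytest.approx(0.0, abs=1e-8)
        assert loss.CPL == pytest.approx(0.0, abs=1e-8)
        assert loss.SPL == pytest.approx(0.0, abs=1e-8)
        assert loss.OL < 1e-4 and loss.NOL < 1e-4

    def test_total_is_weighted_sum(self, small_cfg, rng):
        _, targets, _ = _one_object_setup(small_cfg)
        raws = [rng.normal(size=(1, 28) + (g,) * 3).astype(np.float32)
                for g in small_cfg.grid_sizes]
        w = LossWeights()
        loss = yolo_loss(raws, targets, w)
        expect = (
            w.w_OL * loss.OL + w.w_NOL * loss.NOL + w.w_BL * loss.BL + w.w_CL * loss.CL
            + w.w_APL * loss.APL + w.w_CPL * loss.CPL + w.w_SPL * loss.SPL
        )
        assert loss.total == pytest.approx(expect, rel=1e-12)

    def test_noobject_term_weighted_ten(self, small_cfg):
        """A change in the NOL term moves the total by 10x that change."""
        _, targets, raws = _one_object_setup(small_cfg)
        bumped = [r.copy() for r in raws]
        bumped[2][0, 6, 0, 0, 0] = 3.0  # background cell objectness logit
        l0, l1 = yolo_loss(raws, targets), yolo_loss(bumped, targets)
        assert l1.total - l0.total == pytest.approx(10.0 * (l1.NOL - l0.NOL), rel=1e-9)

    def test_plane_epsilon_convention(self, small_cfg):
        """One object cell, one perturbed spanning component: APL = eps^2/18."""
        _, targets, raws = _one_object_setup(small_cfg, single_cell=True)
        eps = 0.3
        s = next(i for i, t in enumerate(targets) if t["obj"].sum() > 0)
        cell = tuple(np.argwhere(targets[s]["obj"] > 0)[0])
        raws[s][(0, 10) + cell] += eps  # first axial spanning component
        loss = yolo_loss(raws, targets)
        assert loss.APL == pytest.approx(eps**2 / 18, rel=1e-5)
        assert loss.CPL == pytest.approx(0.0, abs=1e-8)

    def test_no_objects_defined_empty(self, small_cfg, rng):
        targets = encode_yolo_targets([], small_cfg)
        raws = [rng.normal(size=(1, 28) + (g,) * 3).astype(np.float32)
                for g in small_cfg.grid_sizes]
        loss = yolo_loss(raws, targets)
        assert loss.OL == 0.0 and loss.BL == 0.0 and loss.CL == 0.0
        assert loss.APL == loss.CPL == loss.SPL == 0.0
        assert loss.NOL > 0

    def test_gradient_matches_finite_difference_at_object_cell(self, small_cfg):
        ann, targets, _ = _one_object_setup(small_cfg)
        # moderate logits: saturated sigmoids are flat below float32 resolution
        raws = raw_from_targets(targets, small_cfg, logit_mag=2.0)
        rng = np.random.default_rng(0)
        raws = [r + rng.normal(0, 0.3, size=r.shape).astype(np.float32) for r in raws]
        _, grads = yolo_loss_and_grad(raws, targets)
        s = next(i for i, t in enumerate(targets) if t["obj"].sum() > 0)
        cell = tuple(np.argwhere(targets[s]["obj"] > 0)[0])
        eps = 1e-3
        for ch in (0, 4, 6, 8, 12, 25):  # offset, extent, obj, class, planes
            idx = (0, ch) + cell
            rp = [r.copy() for r in raws]
            rp[s][idx] += eps
            rm = [r.copy() for r in raws]
            rm[s][idx] -= eps
            num = (yolo_loss(rp, targets).total - yolo_loss(rm, targets).total) / (2 * eps)
            assert grads[s][idx] == pytest.approx(num, rel=1e-3, abs=1e-6)


class TestSelection:
    def _det(self, center, obj, probs, cls_scale=0):
        return Detection(
            box=Box3D(center, (0.1, 0.1, 0.1), frame="normalized"),
            objectness=obj,
            class_probs=np.asarray(probs, dtype=float),
            planes=PlaneTriplet.identity(),
            scale=cls_scale,
            cell=(0, 0, 0),
        )

    def test_all_below_confidence(self):
        dets = [self._det((0.5, 0.5, 0.5), 0.05, (0.9, 0.1, 0.1))]
        assert select_detections(dets) == []

    def test_duplicate_of_one_vertebra_suppressed(self):
        a = self._det((0.5, 0.5, 0.5), 0.9, (0.9, 0.1, 0.1))
        b = self._det((0.52, 0.5, 0.5), 0.6, (0.9, 0.1, 0.1))
        out = select_detections([a, b])
        assert out == [a]

    def test_classprob_gate(self):
        d = self._det((0.5, 0.5, 0.5), 0.9, (0.2, 0.2, 0.2))
        assert select_detections([d]) == []
        d2 = self._det((0.5, 0.5, 0.5), 0.9, (0.2, 0.3, 0.2))
        out = select_detections([d2])
        assert out and out[0].class_id == 2
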