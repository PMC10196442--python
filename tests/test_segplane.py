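"""Cylinder labels, segmentation loss and the clustering/PCA chain."""

import numpy as np
import pytest
from scipy import ndimage

from spineplane.geometry import Box3D, PlaneTriplet, VertebraAnnotation, plane_angle_error
from spineplane.phantom import PhantomSpec, sample_spine_geometry
from spineplane.segplane import (
    Cluster,
    CylinderSpec,
    UNet3D,
    choose_cylinder_size,
    cluster_masks,
    extract_annotations,
    filter_clusters,
    group_clusters,
    plane_normals_from_cluster,
    rasterize_plane_cylinders,
    seg_loss,
    seg_loss_and_grad,
    vertebra_center_from_clusters,
)


def _ann(center, extent, rot=None, cls=2):
    return VertebraAnnotation(
        box=Box3D(center, np.full(3, extent), frame="world"),
        planes=PlaneTriplet(rot if rot is not None else np.eye(3)),
        class_id=cls,
    )


class TestCylinderSpec:
    def test_ratio_enforced(self):
        with pytest.raises(ValueError):
            CylinderSpec(diameter=10.0, height=5.0)
        spec = CylinderSpec.from_diameter(10.0)
        assert spec.height == pytest.approx(2.5)

    def test_two_vertebrae_rule(self):
        anns = [_ann((0, 0, 0), 24.0), _ann((0, 0, 20.0), 24.0)]
        spec = choose_cylinder_size(anns)
        assert spec.diameter == pytest.approx(18.0)  # 0.9 * 20
        assert spec.height == pytest.approx(4.5)

    def test_single_vertebra_fallback(self):
        spec = choose_cylinder_size([_ann((0, 0, 0), 10.0)])
        assert spec.diameter == pytest.approx(15.0)
        assert spec.height == pytest.approx(3.75)

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            choose_cylinder_size([])


class TestRasterize:
    def test_axial_voxel_count_matches_analytic_volume(self):
        # large cylinder with a grid-offset center so half-voxel boundary
        # effects stay well below the 2% band
        spec = CylinderSpec.from_diameter(300.0)
        shape, spacing = (320, 320, 320), 1.0
        center = (160.3, 159.6, 160.2)
        masks = rasterize_plane_cylinders([_ann(center, 200.0)], spec, shape, spacing)
        count = int((masks[0] > 0).sum())
        analytic = np.pi * (spec.diameter / 2) ** 2 * spec.height / spacing**3
        assert count == pytest.approx(analytic, rel=0.02)

    def test_rotation_invariant_count(self):
        spec = CylinderSpec.from_diameter(120.0)
        shape, spacing = (160, 160, 160), 1.0
        center = (80.2, 79.9, 80.1)
        base = rasterize_plane_cylinders([_ann(center, 80.0)], spec, shape, spacing)
        a = np.radians(90)
        rot = np.array([[1, 0, 0], [0, np.cos(a), -np.sin(a)], [0, np.sin(a), np.cos(a)]])
        rotated = rasterize_plane_cylinders(
            [_ann(center, 80.0, rot=rot)], spec, shape, spacing
        )
        assert int((rotated[0] > 0).sum()) == pytest.approx(int((base[0] > 0).sum()), rel=0.02)

    def test_empty_annotations(self):
        masks = rasterize_plane_cylinders([], CylinderSpec.from_diameter(5), (16, 16, 16), 1.0)
        assert masks.shape == (3, 16, 16, 16) and masks.sum() == 0

    def test_distinct_vertebrae_disjoint(self):
        anns = sample_spine_geometry(PhantomSpec(grid_size=128, seed=5))
        spec = choose_cylinder_size(anns)
        spacing = PhantomSpec(grid_size=128, seed=5).spacing
        total = np.zeros((3, 128, 128, 128), dtype=int)
        for ann in anns:
            total += (
                rasterize_plane_cylinders([ann], spec, (128,) * 3, spacing) > 0
            ).astype(int)
        # no voxel belongs to two different vertebrae within one channel
        assert int(total.max()) <= 1

    def test_labels_carry_class_value(self):
        masks = rasterize_plane_cylinders(
            [_ann((24, 24, 24), 20.0, cls=3)], CylinderSpec.from_diameter(20.0), (96,) * 3, 0.5
        )
        assert set(np.unique(masks)) == {0, 3}


class TestSegLoss:
    def _perfect_logits(self, masks):
        logits = np.full((1, 3, 4) + masks.shape[1:], -20.0, dtype=np.float32)
        for c in range(3):
            for k in range(4):
                logits[0, c, k][masks[c] == k] = 20.0
        return logits

    def test_perfect_prediction_dice_zero(self):
        masks = np.zeros((3, 8, 8, 8), dtype=np.uint8)
        masks[:, 2:5, 2:5, 2:5] = 2
        logits = self._perfect_logits(masks)
        assert seg_loss(logits, masks, w_CE=0.0, w_DC=1.0) == pytest.approx(0.0, abs=1e-3)

    def test_uniform_logits_cross_entropy(self):
        """Uniform posteriors over 4 classes: CE = ln 4 per voxel per channel."""
        masks = np.zeros((3, 6, 6, 6), dtype=np.uint8)
        masks[:, :3] = 1
        logits = np.zeros((1, 3, 4, 6, 6, 6), dtype=np.float32)
        total = seg_loss(logits, masks, w_CE=1.0, w_DC=0.0)
        assert total == pytest.approx(3 * np.log(4.0), rel=1e-6)

    def test_channel_summation_rule(self, rng):
        """Identical channels: the total is 3x a single channel's loss."""
        masks1 = rng.integers(0, 4, size=(6, 6, 6)).astype(np.uint8)
        masks = np.stack([masks1] * 3)
        logits1 = rng.normal(size=(1, 1, 4, 6, 6, 6)).astype(np.float32)
        logits = np.concatenate([logits1] * 3, axis=1)
        total = seg_loss(logits, masks)
        # per-channel contribution measured by zeroing out the others and
        # subtracting their (identical) background contribution
        zero_lg = np.zeros_like(logits)
        zero_mk = np.zeros_like(masks)
        base = seg_loss(zero_lg, zero_mk) / 3.0  # one all-background channel
        lg = zero_lg.copy()
        lg[0, 0] = logits[0, 0]
        mk = zero_mk.copy()
        mk[0] = masks[0]
        single = seg_loss(lg, mk) - 2 * base
        assert total == pytest.approx(3 * single, rel=1e-4)

    def test_gradient_matches_finite_difference(self, rng):
        masks = rng.integers(0, 4, size=(3, 5, 5, 5)).astype(np.uint8)
        logits = rng.normal(size=(1, 3, 4, 5, 5, 5)).astype(np.float32)
        total, grad = seg_loss_and_grad(logits, masks)
        eps = 1e-3
        for _ in range(8):
            idx = tuple(rng.integers(0, s) for s in logits.shape)
            lp, lm = logits.copy(), logits.copy()
            lp[idx] += eps
            lm[idx] -= eps
            num = (seg_loss(lp, masks) - seg_loss(lm, masks)) / (2 * eps)
            assert grad[idx] == pytest.approx(num, abs=1e-4)


class TestUNet:
    def test_shape_contract(self):
        net = UNet3D(depth=2, base_width=4, seed=0)
        y = net.forward(np.zeros((1, 1, 16, 16, 16), dtype=np.float32))
        assert y.shape == (1, 3, 4, 16, 16, 16)

    def test_invalid_patch_size(self):
        net = UNet3D(depth=3, base_width=4)
        with pytest.raises(ValueError):
            net.forward(np.zeros((1, 1, 12, 12, 12), dtype=np.float32))

    def test_deterministic_eval(self):
        net = UNet3D(depth=2, base_width=4, seed=0)
        net.eval()
        x = np.random.default_rng(0).normal(size=(1, 1, 16, 16, 16)).astype(np.float32)
        assert np.array_equal(net.forward(x), net.forward(x))

    def test_backward_runs(self):
        net = UNet3D(depth=2, base_width=4, seed=0)
        x = np.random.default_rng(0).normal(size=(1, 1, 16, 16, 16)).astype(np.float32)
        y = net.forward(x)
        dx = net.backward(np.ones_like(y))
        assert dx.shape == x.shape


class TestClustering:
    def _blob_masks(self, positions, size=5, shape=(48, 48, 48)):
        m = np.zeros((3,) + shape, dtype=np.uint8)
        for p in positions:
            sl = tuple(slice(c, c + size) for c in p)
            m[0][sl] = 1
        return m

    def test_two_blobs_two_clusters(self):
        masks = self._blob_masks([(5, 5, 5), (30, 30, 30)])
        cl = cluster_masks(masks, eps=2, min_samples=5)
        assert len(cl) == 2

    def test_isolated_voxels_are_noise(self):
        m = np.zeros((3, 32, 32, 32), dtype=np.uint8)
        for p in [(5, 5, 5), (15, 15, 15), (25, 25, 25)]:
            m[0][p] = 1
        assert cluster_masks(m, eps=2, min_samples=5) == []

    def test_matches_connected_components_at_eps1(self, rng):
        """eps=1, min_samples=1 reduces DBSCAN to 6-connected labeling."""
        m = np.zeros((3, 40, 40, 40), dtype=np.uint8)
        for _ in range(6):
            p = rng.integers(2, 33, size=3)
            s = int(rng.integers(2, 5))
            m[0][p[0] : p[0] + s, p[1] : p[1] + s, p[2] : p[2] + s] = 1
        cl = cluster_masks(m, eps=1, min_samples=1)
        structure = ndimage.generate_binary_structure(3, 1)  # faces only
        _, n_cc = ndimage.label(m[0], structure=structure)
        assert len(cl) == n_cc
        sizes_dbscan = sorted(c.size for c in cl)
        lab, _ = ndimage.label(m[0], structure=structure)
        sizes_cc = sorted(np.bincount(lab.ravel())[1:].tolist())
        assert sizes_dbscan == sizes_cc

    def test_empty_channel(self):
        assert cluster_masks(np.zeros((3, 8, 8, 8), dtype=np.uint8)) == []


class TestFilterGroup:
    def _cluster(self, channel, n, centroid=(0, 0, 0)):
        vox = np.tile(np.asarray(centroid, dtype=int), (n, 1))
        vox += np.arange(n)[:, None] % 3
        return Cluster(channel=channel, voxels=vox, centroid=np.asarray(centroid, float),
                       class_id=1)

    def test_half_max_threshold(self):
        cl = [self._cluster("axial", n) for n in (1000, 600, 499)]
        kept = filter_clusters(cl)
        assert sorted(c.size for c in kept) == [600, 1000]

    def test_single_cluster_kept(self):
        assert len(filter_clusters([self._cluster("coronal", 7)])) == 1

    def test_equal_sizes_all_kept(self):
        cl = [self._cluster("sagittal", 50, (i * 10, 0, 0)) for i in range(4)]
        assert len(filter_clusters(cl)) == 4

    def test_largest_never_removed(self, rng):
        for _ in range(10):
            cl = [self._cluster("axial", int(rng.integers(1, 1000))) for _ in range(5)]
            kept = filter_clusters(cl)
            assert max(c.size for c in cl) in [c.size for c in kept]

    def test_grouping_drops_incomplete(self):
        ax = self._cluster("axial", 50, (10, 10, 10))
        co = self._cluster("coronal", 50, (11, 10, 10))
        triples = group_clusters([ax, co])  # sagittal missing
        assert triples == []

    def test_center_mean_of_centroids(self):
        t = (
            self._cluster("axial", 5, (1, 2, 3)),
            self._cluster("coronal", 5, (3, 2, 1)),
            self._cluster("sagittal", 5, (2, 2, 2)),
        )
        assert np.allclose(vertebra_center_from_clusters(t), (2, 2, 2))


class TestPCANormals:
    def _rasterized_cluster(self, rot):
        spec = CylinderSpec.from_diameter(20.0)
        masks = rasterize_plane_cylinders(
            [_ann((24, 24, 24), 20.0, rot=rot)], spec, (96,) * 3, 0.5
        )
        vox = np.argwhere(masks[0] > 0)
        return Cluster("axial", vox, vox.mean(axis=0) * 0.5, class_id=2)

    def test_axis_aligned_normal(self):
        n = plane_normals_from_cluster(self._rasterized_cluster(np.eye(3)))
        assert plane_angle_error(n, (0, 0, 1)) < 1.0

    def test_rotated_30_deg(self):
        a = np.radians(30)
        rot = np.array([[1, 0, 0], [0, np.cos(a), -np.sin(a)], [0, np.sin(a), np.cos(a)]])
        n = plane_normals_from_cluster(self._rasterized_cluster(rot))
        assert plane_angle_error(n, (0, -np.sin(a), np.cos(a))) < 1.0

    def test_flat_cylinder_variances(self):
        """Empirical variances match h^2/12 axially and d^2/16 radially."""
        spacing = 0.25
        spec = CylinderSpec.from_diameter(40.0)
        masks = rasterize_plane_cylinders(
            [_ann((25.1, 24.9, 25.05), 30.0)], spec, (200,) * 3, spacing
        )
        vox = np.argwhere(masks[0] > 0)
        x = (vox - vox.mean(axis=0)) * spacing
        var_axial = float(np.var(x[:, 2]))
        var_radial = float(np.var(x[:, 0]))
        d, h = spec.diameter, spec.height
        assert var_axial == pytest.approx(h**2 / 12, rel=0.1)
        assert var_radial == pytest.approx((d / 2) ** 2 / 4, rel=0.1)
        assert var_axial < var_radial

    def test_too_small_cluster_raises(self):
        c = Cluster("axial", np.zeros((2, 3), dtype=int), np.zeros(3), 1)
        with pytest.raises(ValueError):
            plane_normals_from_cluster(c)


class TestEndToEndRecovery:
    def test_noise_free_masks_recover_ground_truth(self):
        """The chain is exact up to discretization on clean cylinder masks."""
        spacing = 0.5
        rot = PlaneTriplet.identity().rot
        a = np.radians(10)
        rot_b = np.array([[1, 0, 0], [0, np.cos(a), -np.sin(a)], [0, np.sin(a), np.cos(a)]])
        anns = [
            _ann((32, 30, 20), 22.0, cls=3),
            _ann((32, 34, 47), 22.0, rot=rot_b, cls=3),
        ]
        spec = choose_cylinder_size(anns)
        masks = rasterize_plane_cylinders(anns, spec, (128,) * 3, spacing)
        rec = extract_annotations(masks, spacing=spacing)
        assert len(rec) == 2
        for ann in anns:
            best = min(rec, key=lambda r: np.linalg.norm(r.box.center - ann.box.center))
            assert np.linalg.norm(best.box.center - ann.box.center) <= spacing
            assert best.class_id == ann.class_id
            for p in ("axial", "coronal", "sagittal"):
                assert plane_angle_error(best.planes.normal(p), ann.planes.normal(p)) <= 1.5
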