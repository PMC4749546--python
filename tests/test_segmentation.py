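"""Rendering fidelity and the mask → skeleton → puncta → density chain."""

import numpy as np
import pytest
from scipy import ndimage

from dendromito.images import VolumeStack
from dendromito.segmentation import (DendriteMask, detect_mitochondria,
                                     detect_synapses, make_dendrite_mask,
                                     mito_density, skeletonize_mask,
                                     synapse_density)
from dendromito.synthetic import (ArborParams, GroundTruth, PlacementParams,
                                  RenderParams, generate_arbor,
                                  place_organelles, render_volume)

CLEAN = dict(background=0.0, gaussian_read_noise_sd=0.0, photon_scale=10_000.0)


def puncta_scene(positions_um, seed=0, **render_kw):
    """Render impulses at given world xyz on a straight dummy skeleton."""
    from dendromito.skeleton import ArborSkeleton, SkeletonPoints
    n = 21
    pos = np.zeros((n, 3))
    pos[:, 0] = np.arange(n, dtype=float)
    pos[:, 1] = 5.0
    pos[:, 2] = 2.0
    sk = ArborSkeleton(positions=pos, parent=np.arange(-1, n - 1))
    pts, _ = sk.project(np.asarray(positions_um))
    truth = GroundTruth(skeleton=sk, synapses=pts, mitochondria=pts)
    scene = render_volume(truth, RenderParams(seed=seed, **render_kw))
    return sk, pts, scene


class TestRender:
    def test_centroid_within_half_voxel(self):
        target = np.array([[7.3, 5.1, 2.0]])
        sk, pts, scene = puncta_scene(target, **CLEAN)
        img = scene.channels["synapses"].intensities
        com_vox = ndimage.center_of_mass(img)
        com_um = np.array(com_vox)[::-1] * scene.voxel_size[::-1] + scene.origin_um
        want = sk.point_xyz(pts)[0]
        assert np.all(np.abs(com_um - want) <= 0.5 * scene.voxel_size[::-1])

    def test_empty_truth_is_pure_background(self):
        scene = render_volume(GroundTruth(), RenderParams(seed=1))
        for ch in scene.channels.values():
            # Poisson(background) + read noise: mean near background, no blobs
            assert ch.intensities.mean() == pytest.approx(5.0, abs=1.0)

    def test_same_seed_bit_identical(self):
        sk = generate_arbor(ArborParams(n_branch_events=3, seed=2))
        truth = place_organelles(sk, PlacementParams(seed=3))
        a = render_volume(truth, RenderParams(seed=4))
        b = render_volume(truth, RenderParams(seed=4))
        for name in a.channels:
            np.testing.assert_array_equal(a.channels[name].intensities,
                                          b.channels[name].intensities)

    def test_organelle_count_conserved(self):
        # well-separated organelles: rendered component count equals truth
        xs = np.array([[3.0, 5.0, 2.0], [9.0, 5.0, 2.0], [15.0, 5.0, 2.0]])
        _, _, scene = puncta_scene(xs, **CLEAN)
        img = scene.channels["mito"].intensities
        lab, n = ndimage.label(img > 0.5 * img.max())
        assert n == 3


class TestDendriteMask:
    def test_dice_against_truth_tube(self):
        sk = generate_arbor(ArborParams(n_branch_events=5, seed=5))
        truth = place_organelles(sk, PlacementParams(seed=6))
        scene = render_volume(truth, RenderParams(seed=7, **CLEAN))
        mask = make_dendrite_mask(scene.channels["cytosol"], method="fraction",
                                  quantile=0.5, closing_radius=0.0)
        inter = (mask.mask & scene.tube_mask).sum()
        dice = 2 * inter / (mask.mask.sum() + scene.tube_mask.sum())
        assert dice >= 0.9

    def test_all_zero_stack_rejected(self):
        with pytest.raises(ValueError, match="empty channel"):
            make_dendrite_mask(VolumeStack(np.zeros((4, 8, 8)), [0.4, 0.2, 0.2]))

    def test_constant_stack_error_or_empty_by_flag(self):
        stack = VolumeStack(np.full((4, 8, 8), 3.0), [0.4, 0.2, 0.2])
        with pytest.raises(ValueError):
            make_dendrite_mask(stack)
        mask = make_dendrite_mask(stack, on_degenerate="empty")
        assert mask.n_voxels == 0

    def test_provenance_round_trip(self, tmp_path):
        from dendromito import io
        stack = VolumeStack(np.random.default_rng(0).poisson(
            5, (4, 16, 16)).astype(float), [0.4, 0.2, 0.2])
        stack.intensities[2, 8, 8] = 500.0
        mask = make_dendrite_mask(stack, method="quantile", quantile=0.99)
        io.save_mask(mask, tmp_path / "m.tif")
        back = io.load_mask(tmp_path / "m.tif")
        np.testing.assert_array_equal(back.mask, mask.mask)
        assert back.provenance == pytest.approx(mask.provenance)


class TestSkeletonize:
    def _tube_mask(self, shape, line, voxel_size):
        m = np.zeros(shape, bool)
        m[line] = True
        dist = ndimage.distance_transform_edt(~m, sampling=voxel_size)
        return DendriteMask(dist <= 0.6, np.asarray(voxel_size))

    def test_straight_tube_segment_count(self):
        # 20 µm straight tube at 0.2 µm voxels -> ~20 one-µm links, no branches
        vs = (0.4, 0.2, 0.2)
        mask = self._tube_mask((8, 20, 110), (4, 10, slice(5, 105)), vs)
        sk = skeletonize_mask(mask, target_segment_length=1.0)
        assert len(sk.branch_points) == 0
        assert sk.total_length == pytest.approx(20.0, abs=1.5)
        assert abs(sk.n_segments - 20) <= 2
        assert sk.validate_segment_length(1.0)

    def test_y_mask_single_branch_point(self):
        m = np.zeros((60, 80), bool)
        m[30, 5:40] = True
        for k in range(35):
            y0 = 30 - k // 2
            y1 = 30 + k // 2
            if 0 <= y0 < 60:
                m[y0, 40 + k // 2] = True
            if 0 <= y1 < 60:
                m[y1, 40 + k // 2] = True
        dist = ndimage.distance_transform_edt(~m, sampling=(0.2, 0.2))
        mask = DendriteMask(dist <= 0.5, np.array([0.2, 0.2]))
        sk = skeletonize_mask(mask, target_segment_length=1.0, prune_length=2.0)
        assert len(sk.branch_points) == 1

    def test_length_recovery_on_rendered_arbor(self):
        arbor = generate_arbor(ArborParams(n_branch_events=5, seed=8))
        truth = place_organelles(arbor, PlacementParams(seed=9))
        scene = render_volume(truth, RenderParams(seed=10, **CLEAN))
        mask = make_dendrite_mask(scene.channels["cytosol"], method="fraction",
                                  quantile=0.5, closing_radius=0.0)
        sk = skeletonize_mask(mask)
        assert abs(sk.total_length - arbor.total_length) / arbor.total_length < 0.05

    def test_multiple_components_keeps_largest(self):
        m = np.zeros((40, 60), bool)
        m[20, 5:50] = True   # 9 µm tube
        m[5, 5:10] = True    # 1 µm speck
        dist = ndimage.distance_transform_edt(~m, sampling=(0.2, 0.2))
        mask = DendriteMask(dist <= 0.5, np.array([0.2, 0.2]))
        sk = skeletonize_mask(mask)
        assert sk.total_length == pytest.approx(9.0, abs=1.0)


class TestPuncta:
    def test_two_separated_puncta_centroids(self):
        targets = np.array([[6.0, 5.0, 2.0], [9.0, 5.0, 2.0]])
        sk, pts, scene = puncta_scene(targets, **CLEAN)
        mask = DendriteMask(np.ones(scene.channels["synapses"].shape, bool),
                            scene.voxel_size)
        out = detect_synapses(scene.channels["synapses"], mask)
        assert out.n_puncta == 2
        got = np.sort(out.centroids_um[:, 0]) + scene.origin_um[0]
        want = np.sort(sk.point_xyz(pts)[:, 0])
        np.testing.assert_allclose(got, want, atol=0.5 * scene.voxel_size[-1] * 2)

    def test_zero_signal_no_puncta(self):
        stack = VolumeStack(np.zeros((6, 20, 20)), [0.4, 0.2, 0.2])
        mask = DendriteMask(np.ones((6, 20, 20), bool), stack.voxel_size)
        out = detect_synapses(stack, mask)
        assert out.n_puncta == 0

    def test_close_pair_freeze_prevents_merge(self):
        # 1.2 µm apart with overlapping blur, intensity ratio 2
        from dendromito.synthetic.render import _splat, _peak_normalize
        shape = (8, 40, 60)
        vs = np.array([0.4, 0.2, 0.2])
        coords = np.array([[4.0, 20.0, 20.0], [4.0, 20.0, 26.0]])
        img = _splat(shape, coords, weights=np.array([2.0, 1.0]))
        psf_vox = np.array([0.6, 0.25, 0.25]) / vs
        img = _peak_normalize(ndimage.gaussian_filter(img, psf_vox), psf_vox)
        stack = VolumeStack(img * 1000, vs)
        mask = DendriteMask(np.ones(shape, bool), vs)
        out = detect_synapses(stack, mask)
        assert out.n_puncta == 2

    def test_empty_mask_error(self):
        stack = VolumeStack(np.ones((4, 8, 8)), [0.4, 0.2, 0.2])
        with pytest.raises(ValueError, match="mask"):
            detect_synapses(stack, DendriteMask(np.zeros((4, 8, 8), bool),
                                                stack.voxel_size))


class TestMitochondria:
    def test_count_recovery_and_containment(self):
        arbor = generate_arbor(ArborParams(n_branch_events=5, seed=11))
        truth = place_organelles(arbor, PlacementParams(
            mito_volume_fraction=0.05, seed=12))
        scene = render_volume(truth, RenderParams(seed=13, **CLEAN))
        mask = make_dendrite_mask(scene.channels["cytosol"], method="fraction",
                                  quantile=0.3)
        out = detect_mitochondria(scene.channels["mito"], mask)
        assert out.n_components == pytest.approx(len(truth.mitochondria), rel=0.15)
        assert np.all(mask.mask[out.mask])

    def test_signal_free_channel_empty(self):
        stack = VolumeStack(np.zeros((4, 10, 10)), [0.4, 0.2, 0.2])
        mask = DendriteMask(np.ones((4, 10, 10), bool), stack.voxel_size)
        out = detect_mitochondria(stack, mask)
        assert out.n_voxels == 0


class TestDensities:
    def test_volumetric_fraction_ratio(self):
        mask = DendriteMask(np.zeros((10, 10), bool), np.array([0.2, 0.2]))
        mask.mask[:5] = True  # 50 voxels... make 1000-voxel example explicit
        mask = DendriteMask(np.ones((10, 100), bool), np.array([0.2, 0.2]))
        m = np.zeros((10, 100), bool)
        m.ravel()[:100] = True
        om = detect_mitochondria(
            VolumeStack(np.zeros((10, 100)), [0.2, 0.2]), mask)
        om.mask = m
        assert mito_density(om, mask) == pytest.approx(0.1)

    def test_saturation_and_empty(self):
        mask = DendriteMask(np.ones((5, 5), bool), np.array([0.2, 0.2]))
        om = detect_mitochondria(VolumeStack(np.zeros((5, 5)), [0.2, 0.2]), mask)
        assert mito_density(om, mask) == 0.0
        om.mask = mask.mask.copy()
        assert mito_density(om, mask) == 1.0

    def test_synapse_density_per_um(self, straight_path):
        class P:  # minimal puncta stand-in
            n_puncta = 5
        assert synapse_density(P(), straight_path) == pytest.approx(0.5)
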