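"""Isocontour segmentation, boxing and mask resampling."""

import numpy as np
import pytest
from scipy import ndimage

from oracles import blurred_sphere_crossing_radius
from thyropet import phantom, segment, suv
from thyropet.volumes import ImageVolume, VoiMask


def _full_box(vol):
    return np.zeros(3, int), np.asarray(vol.shape) - 1


class TestSegmentNodule:
    def test_plateau_threshold_and_support(self, plateau_phantom):
        spec, pet, _, truth = plateau_phantom
        voi = segment.segment_nodule(pet, _full_box(pet), background_suv=2.0)
        assert voi.provenance["threshold"] == pytest.approx(6.0)  # 2 + 0.5*(10-2)
        assert np.array_equal(voi.data, truth.data)

    def test_zero_background_pure_isocontour(self, plateau_phantom):
        _, pet, _, truth = plateau_phantom
        voi = segment.segment_nodule(pet, _full_box(pet), background_suv=0.0)
        assert voi.provenance["threshold"] == pytest.approx(5.0)

    def test_additive_variant_threshold(self, plateau_phantom):
        _, pet, _, _ = plateau_phantom
        voi = segment.segment_nodule(pet, _full_box(pet), background_suv=2.0, mode="additive")
        assert voi.provenance["threshold"] == pytest.approx(0.5 * 10.0 + 2.0)

    def test_blurred_sphere_boundary_matches_analytic_radius(self):
        # sphere R=15mm, peak 10 over bg 2, PSF 7mm; boundary where the
        # blurred profile crosses T should match the closed-form crossing
        spacing = 2.0
        spec = phantom.NoduleSpec(
            centre_mm=[49.0, 49.0, 49.0],
            diameters_mm=[30.0, 30.0, 30.0],
            peak_suv=10.0,
            background_suv=2.0,
            psf_fwhm_mm=7.0,
            noise_sd_fraction=0.0,
        )
        pet, _, _ = phantom.generate_phantom(spec, spacing, (50, 50, 50), seed=0)
        voi = segment.segment_nodule(pet, _full_box(pet), background_suv=2.0)
        threshold = voi.provenance["threshold"]
        sigma = 7.0 / (2 * np.sqrt(2 * np.log(2)))
        level = (threshold - 2.0) / (10.0 - 2.0)  # on the unit blurred profile
        analytic_r = blurred_sphere_crossing_radius(15.0, sigma, level)
        # measured boundary radius: furthest in-mask voxel centre from centre
        idx = np.argwhere(voi.data) * spacing
        measured_r = np.linalg.norm(idx - 49.0, axis=1).max()
        assert abs(measured_r - analytic_r) <= spacing * np.sqrt(3)

    def test_not_above_background_rejected(self):
        vol = ImageVolume(np.full((10, 10, 10), 2.0), 3.0)
        with pytest.raises(ValueError, match="not above background"):
            segment.segment_nodule(vol, _full_box(vol), background_suv=5.0)

    def test_mask_single_component_containing_suvmax(self, plateau_phantom):
        _, pet, _, _ = plateau_phantom
        voi = segment.segment_nodule(pet, _full_box(pet), background_suv=2.0)
        labels, n = ndimage.label(voi.data, structure=np.ones((3, 3, 3)))
        assert n == 1
        seed = np.unravel_index(np.argmax(pet.data), pet.shape)
        assert voi.data[seed]

    def test_raising_background_never_enlarges_mask(self, plateau_phantom):
        _, pet, _, _ = plateau_phantom
        sizes = []
        for bg in (0.0, 1.0, 2.0, 3.0):
            voi = segment.segment_nodule(pet, _full_box(pet), background_suv=bg)
            sizes.append(voi.voxel_count)
        assert all(a >= b for a, b in zip(sizes, sizes[1:]))

    def test_scale_equivariance(self, plateau_phantom):
        _, pet, _, _ = plateau_phantom
        voi1 = segment.segment_nodule(pet, _full_box(pet), background_suv=2.0)
        scaled = ImageVolume(pet.data * 4.0, pet.spacing)
        voi2 = segment.segment_nodule(scaled, _full_box(pet), background_suv=8.0)
        assert voi2.provenance["threshold"] == pytest.approx(4.0 * voi1.provenance["threshold"])
        assert np.array_equal(voi1.data, voi2.data)


class TestBoxing:
    def test_zero_margin_box_equals_extent(self):
        vol = ImageVolume(np.zeros((20, 20, 20)), 2.0)
        lo, hi = segment.apply_boxing(vol, centre_mm=[20, 20, 20], extent_mm=8.0, margin_factor=1.0)
        assert np.all(hi - lo >= 8.0 / 2.0)  # covers the stated extent
        assert np.all(lo <= 10) and np.all(hi >= 10)

    def test_second_nodule_excluded_by_boxing(self):
        data = np.full((30, 12, 12), 1.0)
        data[6:9, 5:8, 5:8] = 10.0  # index nodule
        data[20:23, 5:8, 5:8] = 12.0  # hotter neighbour
        vol = ImageVolume(data, 2.0)
        box = segment.apply_boxing(vol, centre_mm=[14, 12, 12], extent_mm=10.0)
        voi = segment.segment_nodule(vol, box, background_suv=1.0)
        assert voi.data[7, 6, 6]
        assert not voi.data[21, 6, 6]

    def test_box_always_contains_locator_centre(self):
        rng = np.random.default_rng(0)
        vol = ImageVolume(np.zeros((24, 24, 24)), 2.5)
        for _ in range(50):
            centre = rng.uniform(5, 50, size=3)
            lo, hi = segment.apply_boxing(vol, centre, extent_mm=rng.uniform(4, 20))
            idx = vol.index_of(centre)
            assert np.all(lo <= idx) and np.all(idx <= hi)

    def test_fully_outside_locator_rejected(self):
        vol = ImageVolume(np.zeros((10, 10, 10)), 2.0)
        with pytest.raises(ValueError, match="outside"):
            segment.apply_boxing(vol, centre_mm=[100, 100, 100], extent_mm=5.0)


class TestResampleMask:
    def test_identity_on_same_grid(self, plateau_phantom):
        _, _, _, truth = plateau_phantom
        out = segment.resample_mask(truth, truth.spacing, truth.shape, truth.origin)
        assert np.array_equal(out.data, truth.data)

    def test_volume_preserved_downsampling(self):
        mask = np.zeros((24, 24, 24), bool)
        mask[6:18, 6:18, 6:18] = True
        src = VoiMask(mask, 4.0)
        out = segment.resample_mask(src, 2.0)
        src_voxel_ml = 4.0**3 / 1000.0
        assert abs(out.volume_ml - src.volume_ml) <= src_voxel_ml

    def test_down_up_round_trip_dice(self):
        # sphere of radius >= 3 voxels: Dice after down/up resampling >= 0.8
        shape = (32, 32, 32)
        idx = np.indices(shape)
        r2 = sum((idx[a] - 15.5) ** 2 for a in range(3))
        sphere = VoiMask(r2 <= 8.0**2, 2.0)
        down = segment.resample_mask(sphere, 4.0)
        up = segment.resample_mask(down, 2.0, target_shape=shape)
        inter = np.logical_and(sphere.data, up.data).sum()
        dice = 2 * inter / (sphere.data.sum() + up.data.sum())
        assert dice >= 0.8

    def test_disjoint_fov_rejected(self):
        mask = VoiMask(np.ones((4, 4, 4), bool), 2.0)
        with pytest.raises(ValueError, match="overlap"):
            segment.resample_mask(mask, 2.0, target_shape=(4, 4, 4), target_origin=[500, 0, 0])


class TestMinVoxels:
    @pytest.mark.parametrize("n,expected", [(64, True), (63, False)])
    def test_boundary_inclusive(self, n, expected):
        data = np.zeros((5, 5, 5), bool)
        data.flat[:n] = True
        assert segment.check_min_voxels(VoiMask(data, 4.0)) is expected

    def test_cohort_flagging_matches_recount(self):
        rng = np.random.default_rng(1)
        masks = []
        for _ in range(20):
            m = np.zeros((6, 6, 6), bool)
            m.flat[rng.choice(216, size=rng.integers(30, 120), replace=False)] = True
            masks.append(VoiMask(m, 4.0))
        flagged = sum(not segment.check_min_voxels(m) for m in masks)
        recount = sum(int(m.data.sum()) < 64 for m in masks)
        assert flagged == recount
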