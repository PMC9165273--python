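"""Radiomic feature extraction: manifest contract, matrix oracles, limits."""

import numpy as np
import pytest

from oracles import enumerate_glcm, enumerate_runs
from thyropet import radiomics
from thyropet.radiomics import texture
from thyropet.radiomics.preprocess import discretise, interpolate_volume
from thyropet.volumes import ImageVolume, VoiMask

EXPECTED_FAMILY_COUNTS = {
    "shape": 14,
    "firstorder": 18,
    "glcm": 24,
    "glrlm": 16,
    "glszm": 16,
    "gldm": 14,
    "ngtdm": 5,
}


class TestManifest:
    def test_family_counts_and_total(self):
        counts = {fam: len(names) for fam, names in radiomics.FEATURE_MANIFEST.items()}
        assert counts == EXPECTED_FAMILY_COUNTS
        assert radiomics.N_FEATURES_PER_MODALITY == 107

    def test_names_unique_and_frozen(self):
        assert len(set(radiomics.ALL_FEATURE_NAMES)) == 107
        # golden spot-checks against the standard catalogue
        assert "glcm_Autocorrelation" in radiomics.ALL_FEATURE_NAMES
        assert "shape_Sphericity" in radiomics.ALL_FEATURE_NAMES
        assert "ngtdm_Coarseness" in radiomics.ALL_FEATURE_NAMES
        assert "firstorder_RobustMeanAbsoluteDeviation" in radiomics.ALL_FEATURE_NAMES

    def test_extraction_emits_exactly_the_manifest(self):
        rng = np.random.default_rng(0)
        vol = ImageVolume(rng.uniform(1, 9, (8, 8, 8)), 4.0)
        m = np.zeros((8, 8, 8), bool)
        m[2:6, 2:6, 2:6] = True
        fv = radiomics.extract_features(vol, VoiMask(m, 4.0))
        assert tuple(fv.values) == radiomics.ALL_FEATURE_NAMES


class TestInterpolation:
    def test_same_spacing_identity(self):
        vol = ImageVolume(np.random.default_rng(1).random((6, 6, 6)), 4.0)
        out = interpolate_volume(vol, 4.0)
        assert np.array_equal(out.data, vol.data)

    def test_constant_volume(self):
        vol = ImageVolume(np.full((10, 10, 10), 3.3), 3.18)
        out = interpolate_volume(vol, 4.0)
        assert np.allclose(out.data, 3.3)

    def test_linear_ramp_reproduced_exactly(self):
        idx = np.indices((12, 12, 12)).astype(float)
        ramp = 2.0 * idx[0] + 0.5 * idx[1] - 1.25 * idx[2] + 7.0
        vol = ImageVolume(ramp, 2.0)
        out = interpolate_volume(vol, 3.0)
        gi = np.indices(out.shape).astype(float) * 3.0 / 2.0
        expected = 2.0 * gi[0] + 0.5 * gi[1] - 1.25 * gi[2] + 7.0
        interior = (slice(0, 7),) * 3  # clamped-edge region excluded
        assert np.allclose(out.data[interior], expected[interior], atol=1e-10)

    def test_non_finite_rejected(self):
        data = np.ones((4, 4, 4))
        data[0, 0, 0] = np.nan
        with pytest.raises(ValueError, match="non-finite"):
            interpolate_volume(ImageVolume(data, 4.0), 2.0)


class TestDiscretise:
    def test_forced_levels_by_floor_rule(self):
        data = np.zeros((3, 1, 1))
        data[:, 0, 0] = [0.2, 0.7, 1.2]
        vol = ImageVolume(data, 4.0)
        mask = VoiMask(np.ones((3, 1, 1), bool), 4.0)
        levels, edges = discretise(vol, mask, 0.5)
        assert levels[:, 0, 0].tolist() == [1, 2, 3]
        assert edges[0] == pytest.approx(0.2)

    def test_constant_region_single_level_warns(self):
        vol = ImageVolume(np.full((3, 3, 3), 5.0), 4.0)
        mask = VoiMask(np.ones((3, 3, 3), bool), 4.0)
        with pytest.warns(UserWarning, match="single grey level"):
            levels, _ = discretise(vol, mask, 0.5)
        assert levels.max() == 1

    def test_histogram_matches_brute_force(self):
        rng = np.random.default_rng(2)
        vol = ImageVolume(rng.uniform(0, 10, (6, 6, 6)), 4.0)
        mask = VoiMask(rng.random((6, 6, 6)) > 0.3, 4.0)
        levels, _ = discretise(vol, mask, 0.5)
        vals = vol.data[mask.data]
        expected = np.floor((vals - vals.min()) / 0.5).astype(int) + 1
        assert np.array_equal(np.sort(levels[mask.data]), np.sort(expected))


class TestTextureMatrices:
    """Worked 4x4x1 grid: matrices equal brute-force enumeration."""

    @pytest.fixture
    def worked_levels(self):
        grid = np.array(
            [[1, 2, 2, 3], [1, 1, 3, 3], [4, 2, 2, 1], [4, 4, 1, 1]], dtype=np.int64
        )
        return grid[:, :, None]  # 4x4x1

    def test_glcm_matches_enumeration(self, worked_levels):
        for d in texture.DIRECTIONS_13:
            got = texture.glcm_matrix(worked_levels, d, 4)
            want = enumerate_glcm(worked_levels, d, 4)
            assert np.array_equal(got, want), f"direction {d}"

    def test_glcm_on_random_grids_matches_enumeration(self):
        rng = np.random.default_rng(3)
        for _ in range(25):
            levels = rng.integers(0, 5, size=(4, 5, 3))
            for d in texture.DIRECTIONS_13[::4]:
                got = texture.glcm_matrix(levels, d, 4)
                want = enumerate_glcm(levels, d, 4)
                assert np.array_equal(got, want)

    def test_glrlm_matches_enumeration(self, worked_levels):
        for d in texture.DIRECTIONS_13:
            got = texture.glrlm_matrix(worked_levels, d, 4)
            want = enumerate_runs(worked_levels, d, 4)
            assert np.array_equal(got[:, : want.shape[1]], want), f"direction {d}"

    def test_glrlm_on_random_grids_matches_enumeration(self):
        rng = np.random.default_rng(4)
        for _ in range(10):
            levels = rng.integers(0, 4, size=(5, 4, 3))
            for d in texture.DIRECTIONS_13:
                got = texture.glrlm_matrix(levels, d, 3)
                want = enumerate_runs(levels, d, 3)
                n = min(got.shape[1], want.shape[1])
                assert np.array_equal(got[:, :n], want[:, :n])

    def test_glrlm_run_totals_cover_all_voxels(self, worked_levels):
        # along any direction, run lengths weighted by counts sum to N voxels
        for d in texture.DIRECTIONS_13:
            mat = texture.glrlm_matrix(worked_levels, d, 4)
            lengths = np.arange(1, mat.shape[1] + 1)
            assert (mat * lengths).sum() == 16

    def test_glszm_zones_on_worked_grid(self, worked_levels):
        mat = texture.glszm_matrix(worked_levels, 4)
        # hand enumeration (26-connectivity in-plane = 8-connectivity):
        # level 1: zones {(0,0),(1,0),(1,1)}, {(2,3),(3,2),(3,3)} -> two of size 3
        # level 2: {(0,1),(0,2)}, {(2,1),(2,2)} -> two of size 2
        # level 3: {(0,3),(1,2),(1,3)} -> one of size 3
        # level 4: {(2,0),(3,0),(3,1)} -> one of size 3
        assert mat[0, 2] == 2 and mat[1, 1] == 2 and mat[2, 2] == 1 and mat[3, 2] == 1
        assert mat.sum() == 6

    def test_gldm_dependence_counts_on_uniform_block(self):
        levels = np.zeros((4, 4, 4), np.int64)
        levels[1:3, 1:3, 1:3] = 1  # 2x2x2 uniform block
        mat = texture.gldm_matrix(levels, alpha=0, n_levels=1)
        # every voxel of the block has the 7 other block voxels as dependants
        assert mat[0, 7] == 8 and mat.sum() == 8

    def test_ngtdm_two_level_plane(self):
        levels = np.ones((3, 3, 1), np.int64)
        levels[1, 1, 0] = 2
        n_i, p_i, s_i = texture.ngtdm_table(levels, 2)
        assert n_i.tolist() == [8.0, 1.0]
        # centre voxel: all 8 neighbours are level 1 -> |2 - 1| = 1
        assert s_i[1] == pytest.approx(1.0)
        # corner/edge voxels: neighbour averages include the centre 2
        assert s_i[0] > 0


class TestDegenerateLimits:
    def test_constant_intensity_mask(self):
        vol = ImageVolume(np.full((6, 6, 6), 4.0), 4.0)
        m = np.zeros((6, 6, 6), bool)
        m[1:5, 1:5, 1:5] = True
        with pytest.warns(UserWarning):
            fv = radiomics.extract_features(vol, VoiMask(m, 4.0))
        assert fv.values["firstorder_Variance"] == 0.0
        assert fv.values["glcm_Contrast"] == 0.0
        assert fv.values["glcm_Correlation"] == 1.0
        assert fv.values["ngtdm_Coarseness"] == 1e6  # degenerate convention
        assert fv.values["ngtdm_Contrast"] == 0.0

    def test_single_voxel_mask_texture_undefined_not_zero(self):
        vol = ImageVolume(np.random.default_rng(0).random((5, 5, 5)) + 1, 4.0)
        m = np.zeros((5, 5, 5), bool)
        m[2, 2, 2] = True
        fv = radiomics.extract_features(vol, VoiMask(m, 4.0))
        assert np.isfinite(fv.values["shape_MeshVolume"])
        assert np.isnan(fv.values["glcm_Contrast"])
        assert np.isfinite(fv.values["firstorder_Mean"])


class TestShape:
    def test_sphere_sphericity_approaches_one(self):
        values = {}
        for spacing, shape in ((2.0, 32), (1.0, 64)):
            idx = np.indices((shape,) * 3).astype(float)
            centre = (shape - 1) / 2.0
            r2 = sum((idx[a] - centre) ** 2 for a in range(3))
            mask = VoiMask(r2 <= (20.0 / spacing) ** 2, spacing)
            from thyropet.radiomics.shape import shape_features

            values[spacing] = shape_features(mask)
        assert values[1.0]["Sphericity"] == pytest.approx(1.0, abs=0.02)
        assert abs(values[1.0]["Sphericity"] - 1) <= abs(values[2.0]["Sphericity"] - 1) + 0.005
        # mesh volume close to the analytic sphere volume at 1 mm
        assert values[1.0]["MeshVolume"] == pytest.approx(4 / 3 * np.pi * 20.0**3, rel=0.02)

    def test_axis_lengths_of_anisotropic_box(self):
        mask = np.zeros((40, 40, 40), bool)
        mask[5:35, 10:30, 15:25] = True  # 30 x 20 x 10 voxels
        from thyropet.radiomics.shape import shape_features

        feats = shape_features(VoiMask(mask, 1.0))
        assert feats["MajorAxisLength"] > feats["MinorAxisLength"] > feats["LeastAxisLength"]
        assert feats["Elongation"] == pytest.approx(20 / 30, rel=0.02)
        assert feats["Flatness"] == pytest.approx(10 / 30, rel=0.02)
        assert feats["VoxelVolume"] == 30 * 20 * 10


class TestInvariances:
    def test_rotation_and_flip_leave_averaged_textures_unchanged(self):
        rng = np.random.default_rng(5)
        vol_data = rng.uniform(1, 8, (7, 7, 7))
        m = np.zeros((7, 7, 7), bool)
        m[1:6, 1:6, 1:6] = rng.random((5, 5, 5)) > 0.25
        base = radiomics.extract_features(
            ImageVolume(vol_data, 4.0), VoiMask(m, 4.0), families=("glcm", "glrlm", "ngtdm")
        )
        for transform in (
            lambda a: np.rot90(a, k=1, axes=(0, 1)),
            lambda a: np.flip(a, axis=2),
            lambda a: np.rot90(a, k=2, axes=(1, 2)),
        ):
            fv = radiomics.extract_features(
                ImageVolume(transform(vol_data).copy(), 4.0),
                VoiMask(transform(m).copy(), 4.0),
                families=("glcm", "glrlm", "ngtdm"),
            )
            for name, val in base.values.items():
                assert fv.values[name] == pytest.approx(val, rel=1e-9), name


class TestTlg:
    def test_uniform_worked_value(self):
        # 5 g/mL over 2 mL -> TLG 10 g
        vol = ImageVolume(np.full((10, 10, 10), 5.0), 4.0)
        m = np.zeros((10, 10, 10), bool)
        m.flat[: int(round(2000.0 / 64.0))] = True  # 2 mL at 64 mm^3/voxel
        m = VoiMask(m, 4.0)
        assert radiomics.compute_tlg(vol, m) == pytest.approx(5.0 * m.volume_ml)

    def test_linearity_and_sum_identity(self):
        rng = np.random.default_rng(6)
        vol = ImageVolume(rng.uniform(0.5, 9, (6, 6, 6)), 4.0)
        m = VoiMask(rng.random((6, 6, 6)) > 0.5, 4.0)
        tlg = radiomics.compute_tlg(vol, m)
        assert radiomics.compute_tlg(ImageVolume(vol.data * 2, 4.0), m) == pytest.approx(2 * tlg)
        assert tlg == pytest.approx(vol.data[m.data].sum() * 64.0 / 1000.0)
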