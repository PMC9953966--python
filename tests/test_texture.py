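import numpy as np
import pytest

import oracles as bf
from conftest import random_quantized
from tauradiomics import (Volume, extract_features, glcm_features, glcm_matrix,
                          glrlm_features, glrlm_matrix, glszm_features,
                          glszm_matrix, histogram_features, lloyd_max_quantize,
                          ngtdm_features, ngtdm_table, quantize_roi,
                          roi_feature_vector)
from tauradiomics.roi import ROI, ROISet
from tauradiomics.image import Mask
from tauradiomics.texture import (FEATURE_NAMES, GLCM_NAMES, GLRLM_NAMES,
                                  GLSZM_NAMES, NGTDM_NAMES, QuantizedROI)

EYE = np.eye(4)


def _q(grid, ng):
    grid = np.asarray(grid, dtype=np.int32)
    return QuantizedROI(grid, grid[grid > 0], ng, np.arange(1, ng) + 0.5,
                        np.arange(1, ng + 1, dtype=float))


class TestLloydMax:
    def test_uniform_density_analytic_solution(self, rng):
        x = rng.uniform(0, 1, 100_000)
        _, bounds, cents, degen = lloyd_max_quantize(x, 4)
        assert not degen
        np.testing.assert_allclose(bounds, [0.25, 0.5, 0.75], atol=0.01)
        np.testing.assert_allclose(cents, [0.125, 0.375, 0.625, 0.875], atol=0.01)

    def test_discrete_support_zero_distortion(self, rng):
        masses = np.array([0.0, 1.0, 5.0, 9.0])
        x = rng.choice(masses, size=2000)
        levels, _, cents, degen = lloyd_max_quantize(x, 4)
        assert not degen
        np.testing.assert_allclose(np.sort(cents), masses, atol=1e-12)
        # zero quantization error: every value reconstructed exactly
        np.testing.assert_allclose(cents[levels - 1], x, atol=1e-12)

    def test_constant_input_degenerate_flagged(self):
        levels, _, cents, degen = lloyd_max_quantize(np.full(50, 3.3), 8)
        assert degen
        assert set(levels) == {1}

    def test_assignments_cover_1_to_ng(self, rng):
        levels, *_ = lloyd_max_quantize(rng.normal(size=5000), 16)
        assert levels.min() >= 1 and levels.max() <= 16


class TestHistogramFeatures:
    def test_single_level_degenerate(self):
        f = histogram_features(_q(np.full((3, 3, 1), 2), 4))
        assert f == {"global_variance": 0.0, "global_skewness": 0.0,
                     "global_kurtosis": 0.0}

    def test_two_point_moments(self):
        grid = np.array([[[1, 2, 1, 2]]])
        f = histogram_features(_q(grid, 2))
        assert f["global_variance"] == pytest.approx(0.25)
        assert f["global_skewness"] == pytest.approx(0.0, abs=1e-12)
        assert f["global_kurtosis"] == pytest.approx(1.0)

    def test_symmetric_histogram_zero_skewness(self):
        grid = np.array([[[1, 2, 2, 3, 3, 3, 4, 4, 5]]])  # symmetric around 3
        assert histogram_features(_q(grid, 5))["global_skewness"] == \
            pytest.approx(0.0, abs=1e-12)


class TestGLCM:
    def test_constant_roi(self):
        f = glcm_features(glcm_matrix(_q(np.full((3, 3, 3), 2), 4)))
        assert f["glcm_energy"] == pytest.approx(1.0)
        assert f["glcm_contrast"] == 0.0
        assert f["glcm_entropy"] == pytest.approx(0.0)
        assert f["glcm_homogeneity"] == pytest.approx(1.0)

    def test_2x2_grid_matches_bruteforce(self):
        grid = np.array([[[1], [2]], [[3], [4]]])
        q = _q(grid, 4)
        mine = glcm_features(glcm_matrix(q))
        theirs = bf.bf_glcm_features(bf.bf_glcm(q.grid, 4))
        for short, val in theirs.items():
            assert mine[f"glcm_{short}"] == pytest.approx(val, rel=1e-12)

    def test_alternating_line_perfect_anticorrelation(self):
        # 1D alternating levels: every counted pair is (1,2)/(2,1)
        grid = np.array([[[1, 2, 1, 2, 1, 2, 1, 2]]])
        f = glcm_features(glcm_matrix(_q(grid, 2)))
        assert f["glcm_correlation"] == pytest.approx(-1.0, abs=1e-9)
        # contrast is maximal for two adjacent levels: every pair differs by 1
        assert f["glcm_contrast"] == pytest.approx(1.0)

    def test_single_voxel_degenerate(self):
        f = glcm_features(glcm_matrix(_q(np.array([[[3]]]), 4)))
        assert f["glcm_energy"] == 1.0
        assert f["glcm_contrast"] == 0.0


class TestGLRLM:
    def test_constant_line_single_direction_hand_count(self):
        q = _q(np.ones((4, 1, 1)), 1)
        mat = glrlm_matrix(q, directions=[(1, 0, 0)])
        np.testing.assert_array_equal(mat, [[0, 0, 0, 1]])
        f = glrlm_features(mat, n_voxels=4, n_directions=1)
        assert f["glrlm_lre"] == pytest.approx(16.0)
        assert f["glrlm_sre"] == pytest.approx(1 / 16)
        assert f["glrlm_rp"] == pytest.approx(0.25)

    def test_all_distinct_levels_all_runs_length_one(self):
        grid = np.arange(1, 28).reshape(3, 3, 3)
        f = glrlm_features(glrlm_matrix(_q(grid, 27)), n_voxels=27)
        assert f["glrlm_rp"] == pytest.approx(1.0)
        assert f["glrlm_sre"] == pytest.approx(1.0)
        assert f["glrlm_lre"] == pytest.approx(1.0)

    def test_random_3x3x3_matches_bruteforce(self, rng):
        for _ in range(20):
            q = random_quantized(rng, shape=(3, 3, 3), ng=3)
            mat = glrlm_matrix(q)
            want = bf.bf_glrlm(q.grid, 3)
            np.testing.assert_array_equal(mat, want)
            mine = glrlm_features(mat, q.n_voxels)
            theirs = bf.bf_rlm_features(want, q.n_voxels * 13)
            for short, val in theirs.items():
                assert mine[f"glrlm_{short}"] == pytest.approx(val, rel=1e-12)


class TestGLSZM:
    def test_constant_roi_single_zone(self):
        grid = np.full((3, 3, 2), 2)
        mat = glszm_matrix(_q(grid, 4))
        assert mat.sum() == 1
        f = glszm_features(mat, n_voxels=18)
        assert f["glszm_zp"] == pytest.approx(1 / 18)
        assert f["glszm_lze"] == pytest.approx(18 ** 2)

    def test_all_distinct_levels_every_voxel_its_own_zone(self):
        grid = np.arange(1, 28).reshape(3, 3, 3)
        f = glszm_features(glszm_matrix(_q(grid, 27)), n_voxels=27)
        assert f["glszm_zp"] == pytest.approx(1.0)
        assert f["glszm_sze"] == pytest.approx(1.0)

    def test_zone_partition_conserves_voxel_count(self, rng):
        for _ in range(20):
            q = random_quantized(rng, shape=(5, 4, 3), ng=3)
            mat = glszm_matrix(q)
            sizes = np.arange(1, mat.shape[1] + 1)
            assert (mat * sizes).sum() == q.n_voxels


class TestNGTDM:
    def test_constant_roi_guarded_coarseness(self):
        n, s = ngtdm_table(_q(np.full((3, 3, 3), 1), 2))
        f = ngtdm_features(n, s)
        assert f["ngtdm_contrast"] == 0.0
        assert f["ngtdm_busyness"] == 0.0
        assert f["ngtdm_coarseness"] == pytest.approx(1e6, rel=1e-6)

    def test_single_bright_interior_voxel(self):
        grid = np.ones((3, 3, 3), dtype=np.int32)
        grid[1, 1, 1] = 2
        n, s = ngtdm_table(_q(grid, 2))
        want_n, want_s = bf.bf_ngtdm(grid, 2)
        np.testing.assert_allclose(n, want_n)
        np.testing.assert_allclose(s, want_s)
        assert s[1] == pytest.approx(1.0)  # |2 - mean(26 ones)|

    def test_translation_invariance(self):
        core = np.array([[[1, 2], [2, 1]], [[2, 1], [1, 2]]], dtype=np.int32)
        a = np.zeros((6, 6, 6), dtype=np.int32)
        b = np.zeros((6, 6, 6), dtype=np.int32)
        a[0:2, 0:2, 0:2] = core
        b[3:5, 3:5, 3:5] = core
        fa = ngtdm_features(*ngtdm_table(_q(a, 2)))
        fb = ngtdm_features(*ngtdm_table(_q(b, 2)))
        assert fa == fb


class TestOracleEquivalence:
    """Every family equals the brute-force enumerators on random 4x4x4 ROIs."""

    @pytest.mark.parametrize("ng", [2, 4, 6])
    def test_all_families_match_bruteforce(self, rng, ng):
        for _ in range(12):
            q = random_quantized(rng, shape=(4, 4, 4), ng=ng)
            # GLCM
            mine = glcm_features(glcm_matrix(q))
            theirs = bf.bf_glcm_features(bf.bf_glcm(q.grid, ng))
            for k, v in theirs.items():
                assert mine[f"glcm_{k}"] == pytest.approx(v, rel=1e-10, abs=1e-10)
            # GLRLM
            m = glrlm_matrix(q)
            np.testing.assert_array_equal(m, bf.bf_glrlm(q.grid, ng))
            mine = glrlm_features(m, q.n_voxels)
            theirs = bf.bf_rlm_features(bf.bf_glrlm(q.grid, ng), q.n_voxels * 13)
            for k, v in theirs.items():
                assert mine[f"glrlm_{k}"] == pytest.approx(v, rel=1e-10, abs=1e-10)
            # GLSZM
            m = glszm_matrix(q)
            np.testing.assert_array_equal(m, bf.bf_glszm(q.grid, ng))
            mine = glszm_features(m, q.n_voxels)
            theirs = bf.bf_rlm_features(bf.bf_glszm(q.grid, ng), q.n_voxels)
            for (mk, v) in zip(GLSZM_NAMES,
                               [theirs[k] for k in ["sre", "lre", "gln", "rln",
                                                    "rp", "lgre", "hgre",
                                                    "srlge", "srhge", "lrlge",
                                                    "lrhge", "glv", "rlv"]]):
                assert mine[mk] == pytest.approx(v, rel=1e-10, abs=1e-10)
            # NGTDM
            n, s = ngtdm_table(q)
            wn, ws = bf.bf_ngtdm(q.grid, ng)
            np.testing.assert_allclose(n, wn, rtol=1e-10)
            np.testing.assert_allclose(s, ws, rtol=1e-10, atol=1e-10)
            mine = ngtdm_features(n, s)
            theirs = bf.bf_ngtdm_features(wn, ws)
            for k, v in theirs.items():
                assert mine[f"ngtdm_{k}"] == pytest.approx(v, rel=1e-10, abs=1e-10)
            # histogram
            mine = histogram_features(q)
            theirs = bf.bf_histogram_features(q.levels)
            for k, v in theirs.items():
                assert mine[f"global_{k}"] == pytest.approx(v, rel=1e-10, abs=1e-10)


class TestFeatureVectorInvariants:
    def _roi_setup(self, rng, shape=(14, 14, 14)):
        vol = Volume(rng.normal(size=shape), np.eye(4))
        mask = np.zeros(shape, bool)
        mask[2:9, 3:10, 2:8] = True
        return vol, mask

    def test_exactly_43_features(self, rng):
        vol, mask = self._roi_setup(rng)
        feats = roi_feature_vector(vol, mask, ng=8)
        assert len(feats) == 43
        assert list(feats) == FEATURE_NAMES
        fams = {"global": 3, "glcm": 9, "glrlm": 13, "glszm": 13, "ngtdm": 5}
        for fam, n in fams.items():
            assert sum(k.startswith(fam) for k in feats) == n
        assert all(np.isfinite(v) for v in feats.values())

    def test_invariant_to_roi_translation(self, rng):
        vol, mask = self._roi_setup(rng)
        f1 = roi_feature_vector(vol, mask, ng=8)
        shifted_data = np.roll(vol.data, (3, 2, 4), axis=(0, 1, 2))
        shifted_mask = np.roll(mask, (3, 2, 4), axis=(0, 1, 2))
        f2 = roi_feature_vector(Volume(shifted_data, np.eye(4)),
                                shifted_mask, ng=8)
        for k in f1:
            assert f1[k] == pytest.approx(f2[k], rel=1e-12), k

    def test_invariant_to_affine_intensity_rescale(self, rng):
        vol, mask = self._roi_setup(rng)
        f1 = roi_feature_vector(vol, mask, ng=8)
        f2 = roi_feature_vector(vol.copy_with(3.7 * vol.data + 11.0), mask, ng=8)
        for k in f1:
            assert f1[k] == pytest.approx(f2[k], rel=1e-9), k

    def test_glcm_symmetric_and_matrices_normalizable(self, rng):
        vol, mask = self._roi_setup(rng)
        q = quantize_roi(vol, mask, ng=8)
        mat = glcm_matrix(q)
        np.testing.assert_array_equal(mat, mat.T)
        p = mat / mat.sum()
        assert p.sum() == pytest.approx(1.0, abs=1e-12)


class TestExtractFeatures:
    def _roiset(self, shape, boxes, names):
        rois = []
        for rid, (name, box) in enumerate(zip(names, boxes), start=1):
            m = np.zeros(shape, bool)
            m[box] = True
            rois.append(ROI(rid, name, Mask(m, EYE.copy())))
        return ROISet(rois)

    def test_sixty_rois_give_2580_columns(self, rng):
        shape = (20, 20, 20)
        vol = Volume(rng.normal(size=shape), EYE.copy())
        boxes = []
        for k in range(60):
            i, j, l = k % 5, (k // 5) % 5, k // 25
            boxes.append((slice(4 * i, 4 * i + 4), slice(4 * j, 4 * j + 4),
                          slice(6 * l, 6 * l + 6)))
        rs = self._roiset(shape, boxes, [f"r{k}" for k in range(60)])
        row = extract_features(vol, rs, ng=8)
        assert len(row) == 2580

    def test_single_roi_gives_43_columns(self, rng):
        shape = (8, 8, 8)
        vol = Volume(rng.normal(size=shape), EYE.copy())
        rs = self._roiset(shape, [(slice(1, 7),) * 3], ["only"])
        row = extract_features(vol, rs, ng=8)
        assert len(row) == 43
        assert all(k.startswith("only__") for k in row)

    def test_identical_subjects_identical_rows(self, rng):
        shape = (10, 10, 10)
        vol = Volume(rng.normal(size=shape), EYE.copy())
        rs = self._roiset(shape, [(slice(1, 8),) * 3], ["r"])
        assert extract_features(vol, rs, ng=8) == extract_features(vol, rs, ng=8)

    def test_undersized_roi_yields_missing_with_warning(self, rng):
        shape = (6, 6, 6)
        vol = Volume(rng.normal(size=shape), EYE.copy())
        rs = self._roiset(shape, [(slice(0, 1), slice(0, 1), slice(0, 1))], ["t"])
        with pytest.warns(UserWarning, match="below minimum"):
            row = extract_features(vol, rs, ng=8)
        assert all(np.isnan(v) for v in row.values())
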