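import numpy as np
import pytest

from oracles import bf_bh_cutoff
from tauradiomics import (CohortSpec, LabelMap, Mask, Volume, cluster_filter,
                          define_rois, fdr_threshold, generate_atlas,
                          generate_subject_volume, map_to_atlas,
                          voxelwise_ttest)
from tauradiomics.cohort import SubjectRecord
from tauradiomics.image import GeometryError

EYE = np.eye(4)


def _vols(arrays):
    return [Volume(np.asarray(a, dtype=float), EYE.copy()) for a in arrays]


def _full_mask(shape=(1, 1, 1)):
    return Mask(np.ones(shape, bool), EYE.copy())


class TestVoxelwiseTTest:
    def test_identical_groups_give_t0_p1(self, rng):
        vols = _vols([rng.normal(size=(4, 4, 4)) for _ in range(3)])
        sm = voxelwise_ttest(vols, [v.copy_with(v.data) for v in vols],
                             Mask(np.ones((4, 4, 4), bool), EYE.copy()))
        np.testing.assert_allclose(sm.t, 0.0, atol=1e-12)
        np.testing.assert_allclose(sm.p, 1.0)
        assert sm.df == 4

    def test_hand_computed_single_voxel(self):
        a = _vols([[[[1.0]]], [[[2.0]]], [[[3.0]]]])
        b = _vols([[[[4.0]]], [[[5.0]]], [[[6.0]]]])
        sm = voxelwise_ttest(a, b, _full_mask())
        assert sm.t[0, 0, 0] == pytest.approx(-3.674, abs=1e-3)
        assert sm.p[0, 0, 0] == pytest.approx(0.0214, abs=1e-4)
        assert sm.df == 4

    def test_group_swap_negates_t_keeps_p(self, rng):
        a = _vols([rng.normal(size=(3, 3, 3)) for _ in range(4)])
        b = _vols([rng.normal(1.0, size=(3, 3, 3)) for _ in range(4)])
        m = Mask(np.ones((3, 3, 3), bool), EYE.copy())
        s1 = voxelwise_ttest(a, b, m)
        s2 = voxelwise_ttest(b, a, m)
        np.testing.assert_allclose(s1.t, -s2.t, atol=1e-12)
        np.testing.assert_allclose(s1.p, s2.p, atol=1e-12)

    def test_small_group_rejected(self, rng):
        a = _vols([rng.normal(size=(2, 2, 2))])
        with pytest.raises(ValueError):
            voxelwise_ttest(a, a * 2, _full_mask((2, 2, 2)))


class TestFdrThreshold:
    def test_textbook_example_all_rejected(self):
        assert fdr_threshold([0.001, 0.008, 0.039, 0.041], q=0.05) == \
            pytest.approx(0.041)

    def test_all_ones_nothing_rejected(self):
        assert fdr_threshold(np.ones(10), q=0.05) is None

    def test_single_small_p_rejected(self):
        assert fdr_threshold([0.025], q=0.05) == pytest.approx(0.025)

    def test_agrees_with_bruteforce_on_random_vectors(self, rng):
        for _ in range(1000):
            m = int(rng.integers(1, 1000))
            p = rng.random(m) ** float(rng.uniform(0.5, 3.0))
            q = float(rng.uniform(0.005, 0.2))
            got = fdr_threshold(p, q)
            want = bf_bh_cutoff(list(p), q)
            if want is None:
                assert got is None
            else:
                assert got == pytest.approx(want, abs=0)


class TestClusterFilter:
    def _mask_with_components(self):
        data = np.zeros((30, 30, 10), bool)
        data[1:11, 1:11, 1:7] = True    # 600 voxels
        data[15:25, 15:25, 1:5] = True  # 400 voxels
        return Mask(data, EYE.copy())

    def test_size_600_survives_400_removed(self):
        out = cluster_filter(self._mask_with_components(), min_voxels=500)
        assert out.count() == 600

    def test_empty_in_empty_out(self):
        out = cluster_filter(Mask(np.zeros((5, 5, 5), bool), EYE.copy()), 500)
        assert out.count() == 0

    def test_exactly_min_voxels_removed_strict(self):
        data = np.zeros((20, 20, 10), bool)
        data[0:10, 0:10, 0:5] = True  # exactly 500
        assert cluster_filter(Mask(data, EYE.copy()), 500).count() == 0

    def test_18_connectivity_joins_edge_neighbors(self):
        # two voxels sharing only an edge: one component under 18, two under 6
        data = np.zeros((4, 4, 4), bool)
        data[1, 1, 1] = data[2, 2, 1] = True
        m = Mask(data, EYE.copy())
        assert cluster_filter(m, min_voxels=1, connectivity=18).count() == 2
        assert cluster_filter(m, min_voxels=1, connectivity=6).count() == 0


class TestMapToAtlas:
    def _atlas(self):
        labels = np.zeros((12, 12, 12), dtype=np.int32)
        labels[:6] = 1
        labels[6:] = 2
        return LabelMap(labels, EYE.copy(), {1: "r1", 2: "r2"})

    def test_full_brain_survival_returns_whole_regions(self):
        lm = self._atlas()
        surv = Mask(lm.labels > 0, EYE.copy())
        rs = map_to_atlas(surv, lm, min_overlap=10)
        assert rs.ids() == (1, 2)
        assert {r.n_voxels for r in rs} == {6 * 12 * 12}

    def test_disjoint_survival_gives_empty_set(self):
        lm = self._atlas()
        surv = Mask(np.zeros((12, 12, 12), bool), EYE.copy())
        assert len(map_to_atlas(surv, lm)) == 0

    def test_roi_is_intersection_not_whole_label(self):
        lm = self._atlas()
        surv = np.zeros((12, 12, 12), bool)
        surv[0:2] = True  # 288 voxels inside region 1 only
        rs = map_to_atlas(Mask(surv, EYE.copy()), lm, min_overlap=64)
        assert rs.ids() == (1,)
        assert rs.rois[0].n_voxels == 288

    def test_min_overlap_gate(self):
        lm = self._atlas()
        surv = np.zeros((12, 12, 12), bool)
        surv[0, 0, :5] = True  # 5-voxel overlap
        assert len(map_to_atlas(Mask(surv, EYE.copy()), lm, min_overlap=64)) == 0


class TestEndToEndRecovery:
    def test_injected_regions_recovered_with_few_false_positives(self):
        """d=2, n=40/group: the ROI chain should find the affected regions
        and almost nothing else (median over 5 seeds)."""
        n_extra = []
        n_missed = []
        for seed in range(5):
            spec = CohortSpec(n_per_group=40, shape=(32, 32, 32), n_regions=13,
                              n_affected=4, mean_shift=2.0, texture_effect=0.0,
                              seed=100 + seed)
            atlas = generate_atlas(spec)
            vols = {g: [] for g in spec.groups}
            idx = 0
            for g in spec.groups:
                for k in range(spec.n_per_group):
                    rec = SubjectRecord(id=f"s{idx}", group=g,
                                        cohort="discovery", age=70, sex="M",
                                        mmse=27, tau_status="NA",
                                        apoe_status="NA", index=idx)
                    vols[g].append(generate_subject_volume(spec, rec, atlas))
                    idx += 1
            rs = define_rois(vols[spec.groups[0]], vols[spec.groups[1]],
                             atlas, q=0.01, min_cluster=100, min_overlap=32)
            found = set(rs.ids())
            injected = set(spec.affected_ids())
            n_missed.append(len(injected - found))
            n_extra.append(len(found - injected))
        assert np.median(n_missed) == 0
        assert np.median(n_extra) <= 2

    def test_global_null_yields_almost_no_rois(self):
        """No injected effect, 20v20: expected surviving ROI count <= 1
        across repetitions."""
        counts = []
        for seed in range(10):
            spec = CohortSpec(n_per_group=20, shape=(32, 32, 32), n_regions=10,
                              n_affected=4, mean_shift=0.0, texture_effect=0.0,
                              seed=300 + seed)
            atlas = generate_atlas(spec)
            vols = {g: [] for g in spec.groups}
            idx = 0
            for g in spec.groups:
                for k in range(spec.n_per_group):
                    rec = SubjectRecord(id=f"s{idx}", group=g,
                                        cohort="discovery", age=70, sex="M",
                                        mmse=27, tau_status="NA",
                                        apoe_status="NA", index=idx)
                    vols[g].append(generate_subject_volume(spec, rec, atlas))
                    idx += 1
            rs = define_rois(vols[spec.groups[0]], vols[spec.groups[1]],
                             atlas, q=0.01, min_cluster=100, min_overlap=32)
            counts.append(len(rs))
        assert np.mean(counts) <= 1.0

    def test_invariant_to_subject_order_within_groups(self, rng):
        spec = CohortSpec(n_per_group=10, shape=(32, 32, 32), n_regions=10,
                          n_affected=4, mean_shift=1.5, seed=44)
        atlas = generate_atlas(spec)
        vols = []
        for idx in range(10):
            rec = SubjectRecord(id=f"s{idx}", group="AD", cohort="discovery",
                                age=70, sex="M", mmse=25, tau_status="NA",
                                apoe_status="NA", index=idx)
            vols.append(generate_subject_volume(spec, rec, atlas))
        ga, gb = vols[:5], vols[5:]
        rs1 = define_rois(ga, gb, atlas, min_cluster=50, min_overlap=16)
        perm = [ga[i] for i in rng.permutation(5)]
        rs2 = define_rois(perm, gb, atlas, min_cluster=50, min_overlap=16)
        assert rs1.ids() == rs2.ids()
        for r1, r2 in zip(rs1, rs2):
            np.testing.assert_array_equal(r1.mask.data, r2.mask.data)
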