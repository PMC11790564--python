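"""Lesion labeling, cross-session matching, categories and per-lesion ROIs."""

import numpy as np
import pytest

from wmhperf import geometry, tracking
from wmhperf.volumes import LabelVolume

from .oracles import brute_force_distance, flood_fill_components

VS = (1.0, 1.0, 2.0)  # voxel volume 2 mm^3


def vol(mask, vs=VS):
    return LabelVolume(np.asarray(mask), vs)


def blob(shape, slices):
    m = np.zeros(shape, dtype=bool)
    m[slices] = True
    return m


class TestLabelClusters:
    def test_empty_mask_gives_empty_list(self):
        assert tracking.label_clusters(vol(np.zeros((5, 5, 5), dtype=bool))) == []

    @pytest.mark.parametrize("n_voxels,kept", [(4, False), (5, True), (6, True)])
    def test_ten_mm3_floor_is_strict(self, n_voxels, kept):
        # at 2 mm^3/voxel: 4 voxels = 8 mm^3 dropped, 5 voxels = 10 mm^3 kept
        mask = np.zeros((10, 10, 5), dtype=bool)
        mask[2, 2, :1] = True
        mask[3, 2:2 + n_voxels - 1, 0] = True
        clusters = tracking.label_clusters(vol(mask))
        assert (len(clusters) == 1) == kept
        if kept:
            assert clusters[0].volume_mm3 == n_voxels * 2.0

    @pytest.mark.parametrize("connectivity,expected", [(26, 1), (18, 1), (6, 2)])
    def test_diagonal_touch_depends_on_connectivity(self, connectivity, expected):
        mask = np.zeros((12, 12, 6), dtype=bool)
        mask[2:4, 2:4, 1:3] = True      # blob A
        mask[4:6, 4:6, 1:3] = True      # blob B, touching A only at a corner
        clusters = tracking.label_clusters(vol(mask), connectivity=connectivity, min_volume_mm3=0)
        assert len(clusters) == expected
        assert len(flood_fill_components(mask, connectivity)) == expected

    def test_components_match_flood_fill_on_random_mask(self):
        rng = np.random.default_rng(4)
        mask = rng.random((10, 10, 6)) < 0.2
        for conn in (6, 18, 26):
            clusters = tracking.label_clusters(vol(mask), connectivity=conn, min_volume_mm3=0)
            oracle = flood_fill_components(mask, conn)
            assert len(clusters) == len(oracle)
            got = sorted(frozenset(map(tuple, np.argwhere(c.voxels))) for c in clusters)
            assert got == sorted(frozenset(c) for c in oracle)


class TestAssignBand:
    def make_dist(self, shape=(30, 30, 10)):
        vent = np.zeros(shape, dtype=bool)
        vent[0, :, :] = True
        return geometry.ventricular_distance(vol(vent))

    def test_centroid_distance_2mm_is_jv(self):
        dist = self.make_dist()
        mask = blob((30, 30, 10), (slice(1, 4), slice(10, 13), slice(3, 5)))
        cl = tracking.label_clusters(vol(mask))[0]
        band = tracking.assign_band(cl, dist)
        assert band == "JV"
        assert cl.centroid_ventricular_distance_mm == pytest.approx(2.0)

    def test_rules_agree_when_lesion_in_one_band(self):
        dist = self.make_dist()
        mask = blob((30, 30, 10), (slice(14, 17), slice(10, 13), slice(3, 5)))  # d in 14..16
        cl = tracking.label_clusters(vol(mask))[0]
        assert tracking.assign_band(cl, dist, rule="centroid") == "D"
        assert tracking.assign_band(cl, dist, rule="majority") == "D"
        assert not cl.band_rules_disagree

    def test_elongated_lesion_spanning_boundary_flags_disagreement(self):
        dist = self.make_dist()
        # rows 1..11 -> distances 1..11 mm: centroid at 6 mm (PV) but most
        # voxels below 10 mm; widen the tail so the majority band is JV
        mask = np.zeros((30, 30, 10), dtype=bool)
        mask[1:12, 10, 3] = True
        mask[1:3, 8:13, 3] = True  # extra JV-side bulk
        cl = tracking.label_clusters(vol(mask))[0]
        tracking.assign_band(cl, dist, rule="centroid")
        bf = brute_force_distance(np.asarray(dist.values == 0), VS)
        majority_oracle = np.unique(
            [geometry.band_of_distance(d) for d in bf[cl.voxels]], return_counts=True
        )
        oracle_band = majority_oracle[0][np.argmax(majority_oracle[1])]
        assert cl.majority_band == oracle_band
        assert cl.band_rules_disagree == (cl.band != cl.majority_band)


class TestMatchAndCategorize:
    def test_identical_masks_all_stagnant_zero_change(self):
        mask = blob((12, 12, 6), (slice(2, 6), slice(2, 6), slice(1, 4)))
        bl = tracking.label_clusters(vol(mask), "baseline")
        fu = tracking.label_clusters(vol(mask), "followup")
        trajs = tracking.match_clusters(bl, fu)
        assert len(trajs) == 1
        assert trajs[0].category == "stagnant"
        assert trajs[0].volume_change_fraction == 0.0

    def test_unmatched_followup_is_new(self):
        bl_mask = blob((14, 14, 6), (slice(1, 4), slice(1, 4), slice(1, 3)))
        fu_mask = bl_mask | blob((14, 14, 6), (slice(9, 12), slice(9, 12), slice(3, 5)))
        bl = tracking.label_clusters(vol(bl_mask), "baseline")
        fu = tracking.label_clusters(vol(fu_mask), "followup")
        trajs = tracking.match_clusters(bl, fu)
        assert sorted(t.category for t in trajs) == ["new", "stagnant"]

    def test_unmatched_baseline_is_vanished(self):
        bl_mask = blob((10, 10, 5), (slice(2, 6), slice(2, 6), slice(1, 3)))
        bl = tracking.label_clusters(vol(bl_mask), "baseline")
        trajs = tracking.match_clusters(bl, [])
        assert [t.category for t in trajs] == ["vanished"]

    def test_merge_assigned_to_larger_overlap_parent(self):
        shape = (20, 20, 6)
        a = blob(shape, (slice(2, 6), slice(2, 8), slice(1, 4)))    # bigger
        b = blob(shape, (slice(8, 10), slice(2, 5), slice(1, 4)))   # smaller
        fu_mask = blob(shape, (slice(2, 10), slice(2, 8), slice(1, 4)))  # covers both
        bl = tracking.label_clusters(vol(a | b), "baseline")
        fu = tracking.label_clusters(vol(fu_mask), "followup")
        trajs = tracking.match_clusters(bl, fu)
        merged = [t for t in trajs if t.merged_parents]
        assert len(merged) == 1
        # exhaustive overlap table: parent must be the max-overlap baseline id
        overlaps = {c.id: int(np.count_nonzero(c.voxels & fu[0].voxels)) for c in bl}
        assert merged[0].baseline_id == max(overlaps, key=overlaps.get)
        assert set(merged[0].merged_parents) == set(overlaps)

    @pytest.mark.parametrize(
        "v_bl,v_fu,expected",
        [
            (50, 56, "growing"),    # +12%
            (50, 54, "stagnant"),   # +8%
            (50, 50, "stagnant"),
            (50, 55, "stagnant"),   # exactly +10%: strict rule
            (50, 44, "shrinking"),  # -12%
            (50, 45, "shrinking"),  # exactly -10%
        ],
    )
    def test_categorize_rule_table(self, v_bl, v_fu, expected):
        assert tracking.categorize((v_fu - v_bl) / v_bl) == expected

    def test_every_cluster_in_exactly_one_trajectory(self):
        rng = np.random.default_rng(7)
        bl_mask = rng.random((16, 16, 8)) < 0.12
        fu_mask = rng.random((16, 16, 8)) < 0.12
        bl = tracking.label_clusters(vol(bl_mask), "baseline", min_volume_mm3=0)
        fu = tracking.label_clusters(vol(fu_mask), "followup", min_volume_mm3=0)
        trajs = tracking.match_clusters(bl, fu)
        fu_ids = [t.followup_id for t in trajs if t.followup_id is not None]
        assert sorted(fu_ids) == sorted(c.id for c in fu)
        bl_ids = [t.baseline_id for t in trajs if t.baseline_id is not None]
        assert len(bl_ids) == len(set(bl_ids))


class TestLesionRois:
    def test_adjacent_lesions_excluded_from_each_others_shells(self):
        shape = (24, 24, 8)
        a = blob(shape, (slice(4, 7), slice(4, 7), slice(2, 5)))
        b = blob(shape, (slice(9, 12), slice(4, 7), slice(2, 5)))  # 2-3 mm away
        wm = vol(np.ones(shape, dtype=bool))
        all_wmh = vol(a | b)
        cl_a = tracking.label_clusters(vol(a))[0]
        _, shells = tracking.lesion_rois(cl_a, wm, all_wmh)
        assert not (shells.p4 & b).any()
        assert not (shells.p8 & b).any()

    def test_shell_counts_match_brute_force(self):
        shape = (19, 19, 9)
        lesion = blob(shape, (slice(9, 10), slice(9, 10), slice(4, 5)))
        wm = vol(np.ones(shape, dtype=bool))
        cl = tracking.label_clusters(vol(lesion), min_volume_mm3=0)[0]
        _, shells = tracking.lesion_rois(cl, wm, vol(lesion))
        bf = brute_force_distance(lesion, VS)
        assert shells.p4.sum() == np.count_nonzero((bf > 0) & (bf <= 4))
        assert shells.p8.sum() == np.count_nonzero((bf > 0) & (bf <= 8))


class TestBackprojection:
    def test_constant_region_recovers_painted_value(self):
        shape = (10, 10, 5)
        rcbf = LabelVolume(np.full(shape, 0.77), VS)
        brain = vol(np.ones(shape, dtype=bool))
        roi = blob(shape, (slice(2, 5), slice(2, 5), slice(1, 3)))
        mean, n_excl = tracking.backproject_roi_mean(roi, rcbf, brain)
        assert mean == pytest.approx(0.77)
        assert n_excl == 0

    def test_voxels_outside_brain_are_excluded_and_counted(self):
        shape = (10, 10, 5)
        rcbf = LabelVolume(np.ones(shape), VS)
        brain_mask = np.ones(shape, dtype=bool)
        brain_mask[0:2] = False
        roi = blob(shape, (slice(0, 4), slice(0, 4), slice(0, 2)))
        mean, n_excl = tracking.backproject_roi_mean(roi, rcbf, vol(brain_mask))
        assert mean == pytest.approx(1.0)
        assert n_excl == int(np.count_nonzero(roi & ~brain_mask))

    def test_empty_footprint_yields_missing_not_crash(self):
        shape = (6, 6, 3)
        rcbf = LabelVolume(np.ones(shape), VS)
        brain = vol(np.zeros(shape, dtype=bool))
        roi = np.ones(shape, dtype=bool)
        mean, n_excl = tracking.backproject_roi_mean(roi, rcbf, brain)
        assert mean is None
        assert n_excl == roi.sum()
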