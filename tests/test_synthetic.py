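"""Generator correctness: determinism, planted truth, calibration, fidelity."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from wmhperf import geometry, pipeline, synthetic, tracking
from wmhperf.volumes import LabelVolume

from .conftest import masks_from_subject
from .oracles import brute_force_distance


def zero_noise_spec(**kw):
    defaults = dict(n_subjects=1, n_longitudinal=1, voxel_noise_cv=0.0, seed=42)
    defaults.update(kw)
    return synthetic.CohortSpec(**defaults)


class TestSpecValidation:
    def test_category_fractions_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sum to 1"):
            synthetic.CohortSpec(category_fractions={"stagnant": 0.5, "growing": 0.4, "new": 0.2})

    def test_factors_must_be_positive(self):
        with pytest.raises(ValueError, match="positive"):
            synthetic.CohortSpec(tissue_rcbf_factors={"GM": -1.0, "NAWM": 1.0, "WMH": 1.0, "P4": 1.0, "P8": 1.0})

    def test_negative_noise_rejected(self):
        with pytest.raises(ValueError, match="voxel_noise_cv"):
            synthetic.CohortSpec(voxel_noise_cv=-0.1)


class TestAnatomy:
    def test_labels_disjoint_and_tile_brain(self, small_cohort):
        a = small_cohort[0]["anatomy"]
        parts = [a.ventricle, a.csf, a.wm, a.gm]
        total = np.zeros(a.brain.shape, dtype=int)
        for p in parts:
            total += p.astype(int)
        assert total.max() == 1  # mutually disjoint
        assert np.array_equal(total > 0, a.brain)  # tiling
        assert not (a.brain & ~a.brain).any()

    def test_seeded_determinism_bit_identical(self):
        spec = zero_noise_spec(seed=7)
        a1 = synthetic.generate_anatomy(spec, 0)
        a2 = synthetic.generate_anatomy(spec, 0)
        for name in ("ventricle", "csf", "wm", "gm", "brain"):
            assert np.array_equal(getattr(a1, name), getattr(a2, name))

    def test_ventricle_is_connected(self, small_cohort):
        from scipy import ndimage

        a = small_cohort[0]["anatomy"]
        _, n = ndimage.label(a.ventricle)
        assert n == 1

    def test_deep_band_nonempty_verified_by_brute_force(self):
        # default 96x96x48 grid at 1x1x2 mm must hold WM beyond 10 mm of the
        # ventricle; verify the farthest WM voxel with an all-source physical
        # distance scan rather than trusting the EDT
        spec = zero_noise_spec()
        a = synthetic.generate_anatomy(spec, 0)
        from scipy import ndimage

        d = ndimage.distance_transform_edt(~a.ventricle, sampling=a.voxel_size_mm)
        far_idx = np.unravel_index(np.argmax(np.where(a.wm, d, -1)), d.shape)
        src = np.argwhere(a.ventricle) * np.asarray(a.voxel_size_mm)
        p = np.asarray(far_idx) * np.asarray(a.voxel_size_mm)
        brute = np.sqrt(((src - p) ** 2).sum(axis=1)).min()
        assert brute > 10.0
        assert brute == pytest.approx(d[far_idx], abs=1e-9)

    def test_too_small_grid_raises_sizing_error(self):
        spec = zero_noise_spec(grid_shape=(40, 40, 20))
        with pytest.raises(ValueError, match="grid too small along"):
            synthetic.generate_anatomy(spec, 0)


class TestPlantedLesions:
    def test_stagnant_masks_identical_growing_ratio_on_target(self, small_cohort):
        for data in small_cohort.values():
            les = data["lesions"]
            for _, row in les.truth.iterrows():
                bl = les.baseline_labels == row["lesion"]
                fu = les.followup_labels == row["lesion"]
                if row["category"] == "stagnant":
                    assert np.array_equal(bl, fu)
                elif row["category"] == "growing":
                    ratio = fu.sum() / bl.sum()
                    assert ratio > 1.10
                    assert abs(ratio - row["growth_factor_target"]) <= 0.02 * row["growth_factor_target"]
                elif row["category"] == "new":
                    assert bl.sum() == 0 and fu.sum() > 0

    def test_all_lesions_at_least_ten_mm3(self, small_cohort):
        for data in small_cohort.values():
            truth = data["lesions"].truth
            present = truth[truth["category"] != "new"]
            assert (present["baseline_volume_mm3"] >= 10).all()
            assert (truth["followup_volume_mm3"] >= 10).all()

    def test_lesions_only_in_wm(self, small_cohort):
        for data in small_cohort.values():
            wm = data["anatomy"].wm
            for labels in (data["lesions"].baseline_labels, data["lesions"].followup_labels):
                assert np.all(wm[labels > 0])

    def test_growth_ratio_arithmetic(self):
        # a planted factor f on an n-voxel baseline gives round(n*f) voxels
        spec = zero_noise_spec(
            category_fractions={"stagnant": 0.0, "growing": 1.0, "new": 0.0, "shrinking": 0.0},
            seed=13,
        )
        les = synthetic.plant_lesions(synthetic.generate_anatomy(spec, 0), spec, 0)
        grow = les.truth[les.truth["category"] == "growing"]
        assert len(grow) > 0
        for _, row in grow.iterrows():
            expected = round(row["baseline_voxels"] * row["growth_factor_target"])
            assert abs(row["followup_voxels"] - expected) <= 1

    def test_category_fractions_within_binomial_bounds(self):
        fractions = {"stagnant": 0.5, "growing": 0.3, "new": 0.2, "shrinking": 0.0}
        spec = zero_noise_spec(
            n_subjects=20, n_longitudinal=20,
            category_fractions=fractions,
            lesion_count_dist={"kind": "poisson", "mean": 10.0, "min": 8},
            seed=17,
        )
        counts = []
        for s in range(20):
            les = synthetic.plant_lesions(synthetic.generate_anatomy(spec, s), spec, s)
            counts.append(les.truth["category"])
        cats = pd.concat(counts)
        n = len(cats)
        assert n >= 150
        for cat, frac in fractions.items():
            if frac == 0:
                assert (cats == cat).sum() == 0
                continue
            lo, hi = stats.binom.interval(0.99, n, frac)
            assert lo <= (cats == cat).sum() <= hi


class TestPaintCbf:
    def test_zero_noise_brain_mean_equals_nominal(self, ):
        spec = zero_noise_spec()
        data = synthetic.generate_subject(spec, 0)
        for sess in data["sessions"].values():
            mean = sess["cbf"].data[data["anatomy"].brain].mean()
            assert mean == pytest.approx(spec.nominal_brain_cbf, rel=1e-12)

    def test_painted_gm_ratio_matches_factor(self):
        spec = zero_noise_spec()
        data = synthetic.generate_subject(spec, 0)
        a = data["anatomy"]
        cbf = data["sessions"]["baseline"]["cbf"].data
        gm_mean = cbf[a.gm].mean()
        brain_mean = cbf[a.brain].mean()
        assert gm_mean / brain_mean == pytest.approx(1.315, abs=1e-9)

    def test_csf_calibration_matches_hand_solved_weighted_mean(self):
        spec = zero_noise_spec()
        data = synthetic.generate_subject(spec, 0)
        a = data["anatomy"]
        painted = data["sessions"]["baseline"]["painted"]
        csf_mask = (a.ventricle | a.csf) & a.brain
        parenchyma_sum = painted.factor_map[a.brain & ~csf_mask].sum()
        solved = (a.brain.sum() - parenchyma_sum) / csf_mask.sum()
        assert painted.csf_value_factor == pytest.approx(solved, rel=1e-12)
        assert painted.csf_value_factor > 0

    def test_cumulative_p8_mean_hits_target_factor(self):
        spec = zero_noise_spec()
        data = synthetic.generate_subject(spec, 0)
        painted = data["sessions"]["baseline"]["painted"]
        a = data["anatomy"]
        cbf = data["sessions"]["baseline"]["cbf"].data
        p8_cum = painted.p4 | painted.p8_annulus
        brain_mean = cbf[a.brain].mean()
        assert cbf[p8_cum].mean() / brain_mean == pytest.approx(0.880, abs=1e-9)

    def test_inconsistent_factors_raise_calibration_error(self):
        factors = {"GM": 3.0, "NAWM": 3.0, "WMH": 3.0, "P4": 3.0, "P8": 3.0}
        spec = zero_noise_spec(tissue_rcbf_factors=factors)
        a = synthetic.generate_anatomy(spec, 0)
        les = synthetic.plant_lesions(a, spec, 0)
        with pytest.raises(ValueError, match="calibration"):
            synthetic.paint_cbf(a, les, spec, "baseline")


class TestGeneratorPipelineFidelity:
    """Anti-circularity: the pipeline, given only raw masks, must reproduce
    the labels the generator painted with."""

    def test_bands_and_shells_agree_voxelwise(self, small_cohort):
        data = small_cohort[0]
        masks = masks_from_subject(data, "baseline")
        painted = data["sessions"]["baseline"]["painted"]
        regions = pipeline.derive_regions(masks)
        assert np.array_equal(regions.bands.labels, painted.band_labels)
        assert np.array_equal(regions.shells.p4, painted.p4)
        assert np.array_equal(regions.shells.p8, painted.p4 | painted.p8_annulus)
        assert np.array_equal(regions.nawm.astype_mask(), painted.nawm)

    def test_zero_noise_roi_means_equal_painted_factors(self):
        spec = zero_noise_spec(n_subjects=1, n_longitudinal=0)
        roi, _ = pipeline.cohort_tables(spec)
        factors = {"GM": 1.315, "NAWM": 1.067, "WMH": 0.814, "P4": 0.845, "P8": 0.880}
        for tissue, f in factors.items():
            got = roi.loc[(roi.tissue == tissue) & (roi.region == "whole"), "mean_rcbf"].iloc[0]
            assert got == pytest.approx(f, abs=1e-9), tissue

    def test_recovered_categories_match_planted(self, small_cohort, small_cohort_spec):
        # lesions planted >=2% from the 10% boundary must all be recovered
        n_checked = 0
        for s, data in small_cohort.items():
            if "followup" not in data["sessions"]:
                continue
            masks_bl = masks_from_subject(data, "baseline")
            masks_fu = masks_from_subject(data, "followup")
            bl = tracking.label_clusters(masks_bl.wmh, "baseline")
            fu = tracking.label_clusters(masks_fu.wmh, "followup")
            trajs = tracking.match_clusters(bl, fu)
            truth = data["lesions"].truth
            fu_labels = data["lesions"].followup_labels
            by_id_fu = {c.id: c for c in fu}
            for traj in trajs:
                if traj.followup_id is None:
                    continue
                cl = by_id_fu[traj.followup_id]
                planted_ids = np.unique(fu_labels[cl.voxels])
                planted_ids = planted_ids[planted_ids > 0]
                assert len(planted_ids) == 1  # well-separated lesions
                planted = truth[truth["lesion"] == planted_ids[0]].iloc[0]
                ratio = planted["growth_factor_actual"]
                if planted["category"] in ("stagnant", "growing") and abs(ratio - 1.10) < 0.02:
                    continue  # too close to the boundary to demand recovery
                assert traj.category == planted["category"]
                n_checked += 1
        assert n_checked >= 10


class TestEmitCohort:
    def test_counts_manifest_and_replay(self, tmp_path):
        spec = zero_noise_spec(n_subjects=3, n_longitudinal=2, grid_shape=(96, 96, 48), seed=5)
        out = synthetic.emit_cohort(spec, tmp_path / "cohort")
        assert len(list(out.glob("sub-*/ses-baseline/cbf.nii.gz"))) == 3
        assert len(list(out.glob("sub-*/ses-followup/cbf.nii.gz"))) == 2
        truth1 = pd.read_csv(out / "lesion_truth.csv")
        spec2 = synthetic.load_manifest_spec(out)
        out2 = synthetic.emit_cohort(spec2, tmp_path / "cohort2")
        truth2 = pd.read_csv(out2 / "lesion_truth.csv")
        pd.testing.assert_frame_equal(truth1, truth2)

    def test_saved_volume_round_trip(self, tmp_path):
        spec = zero_noise_spec()
        a = synthetic.generate_anatomy(spec, 0)
        v = a.as_volume("wm")
        path = v.save(tmp_path / "wm.nii.gz")
        back = LabelVolume.load(path, as_bool=True)
        assert np.array_equal(back.data, v.data.astype(bool))
        assert back.voxel_size_mm == pytest.approx(v.voxel_size_mm)

    def test_demographics_match_cohort_parameters(self):
        spec = zero_noise_spec(n_subjects=300, n_longitudinal=90)
        demo = synthetic.demographics_table(spec)
        assert len(demo) == 300
        se = 7.9 / np.sqrt(300)
        assert abs(demo["age_years"].mean() - 77) < 3 * se
        assert demo["inter_scan_years"].notna().sum() == 90
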