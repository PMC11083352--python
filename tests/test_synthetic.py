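"""Synthetic en-face OCTA generator: exact planted truth, geometry,
determinism and cohort effects."""

import numpy as np
import pytest

from ccfd.synthetic import (
    CohortEffectSpec,
    SynthParams,
    generate_lesion_geometry,
    generate_paired_cohort,
    generate_scan,
    sample_cohort_fractions,
)


class TestGenerateScan:
    def test_zero_fraction_plants_nothing(self):
        scan, gt = generate_scan(SynthParams(image_size_px=128, deficit_fraction=0.0, seed=1))
        assert not gt.deficit_mask.any()
        assert all(v == 0.0 for v in gt.deficit_fraction_per_region.values())

    def test_planted_fraction_matches_target(self):
        p = SynthParams(image_size_px=256, deficit_fraction=0.5, seed=7)
        scan, gt = generate_scan(p)
        outside = ~(gt.mnv_mask | gt.halo_mask)
        frac = (gt.deficit_mask & outside).sum() / outside.sum()
        assert abs(frac - 0.5) < 0.02

    def test_recorded_fractions_equal_recounted(self, small_scan):
        scan, gt = small_scan
        for rid, name in [(0, "background")] + [(k, f"R{k}") for k in range(1, 6)]:
            m = gt.region_labels == rid
            recount = (gt.deficit_mask & m).sum() / m.sum()
            assert gt.deficit_fraction_per_region[name] == recount

    def test_no_deficits_inside_lesion(self, small_scan):
        scan, gt = small_scan
        assert not (gt.deficit_mask & (gt.mnv_mask | gt.halo_mask)).any()

    def test_seed_determinism(self):
        p = SynthParams(image_size_px=128, seed=42)
        s1, g1 = generate_scan(p)
        s2, g2 = generate_scan(p)
        assert np.array_equal(s1.flow, s2.flow)
        assert np.array_equal(s1.structure, s2.structure)
        assert np.array_equal(g1.deficit_mask, g2.deficit_mask)
        assert g1.deficit_fraction_per_region == g2.deficit_fraction_per_region

    @pytest.mark.parametrize("bad", [-0.1, 1.2])
    def test_rejects_invalid_fraction(self, bad):
        with pytest.raises(ValueError):
            SynthParams(deficit_fraction=bad)

    def test_monotone_in_fraction(self):
        fractions = []
        for f in (0.2, 0.35, 0.5):
            _, gt = generate_scan(SynthParams(image_size_px=128, deficit_fraction=f, seed=5))
            outside = ~(gt.mnv_mask | gt.halo_mask)
            fractions.append((gt.deficit_mask & outside).mean())
        assert fractions[0] < fractions[1] < fractions[2]

    def test_stationary_texture_in_subwindows(self):
        """Planted fraction in any 1 mm² window stays within 0.1 of the
        global fraction for deficit scales <= 100 µm."""
        p = SynthParams(image_size_px=250, deficit_fraction=0.45,
                        deficit_scale_um=100.0, seed=11)
        scan, gt = generate_scan(p)
        w = int(round(1000.0 / p.pixel_scale_um))  # 1 mm in px
        outside = ~(gt.mnv_mask | gt.halo_mask)
        for i in range(0, p.image_size_px - w, w // 2):
            for j in range(0, p.image_size_px - w, w // 2):
                win = outside[i : i + w, j : j + w]
                if win.mean() < 0.5:  # window dominated by the lesion
                    continue
                frac = gt.deficit_mask[i : i + w, j : j + w][win].mean()
                assert abs(frac - 0.45) < 0.1

    def test_shadow_field_shared_by_flow_and_structure(self, small_scan):
        """The flow image is the shadow-free flow times the recorded
        attenuation field (up to the final clip)."""
        scan, gt = small_scan
        expected = np.clip(gt.flow_ideal * gt.attenuation, 0.0, 1.0)
        assert np.allclose(scan.flow, expected)


class TestLesionGeometry:
    def test_mnv_pixel_count_matches_area(self):
        # 0.23 mm² at 12 µm/px → 0.23e6/144 ≈ 1597 px
        p = SynthParams(image_size_px=500, mnv_area_mm2=0.23, seed=2)
        roi = generate_lesion_geometry(p)
        assert abs(int(roi.mnv_mask.sum()) - 1597) <= 5

    def test_halo_disjoint_and_touching(self, small_roi):
        assert not (small_roi.mnv_mask & small_roi.halo_mask).any()
        # halo must touch the MNV boundary: dilating the MNV by one pixel
        # must hit halo pixels
        from scipy.ndimage import binary_dilation

        grown = binary_dilation(small_roi.mnv_mask) & ~small_roi.mnv_mask
        assert (grown & small_roi.halo_mask).any()

    def test_mnv_connected(self, small_roi):
        from skimage.measure import label

        assert label(small_roi.mnv_mask, connectivity=2).max() == 1

    def test_margin_violation_raises(self):
        p = SynthParams(image_size_px=500, seed=2)
        # centre 0.5 mm (~42 px) from the border
        with pytest.raises(ValueError, match="margin"):
            generate_lesion_geometry(p, center_px=(42.0, 250.0))

    def test_infeasible_area_rejected(self):
        with pytest.raises(ValueError):
            SynthParams(mnv_area_mm2=20.0)


class TestCohort:
    def test_null_effect_mean_difference_near_zero(self):
        spec = CohortEffectSpec(n_eyes=50, delta_r1_t2=0.0, seed=9)
        recs = sample_cohort_fractions(spec)
        r1 = {(r["eye_id"], r["timepoint"]): r["fd_percent"] for r in recs if r["ring"] == 1}
        diffs = [r1[(f"eye{e:02d}", "T2")] - r1[(f"eye{e:02d}", "T0")] for e in range(50)]
        se = np.std(diffs, ddof=1) / np.sqrt(len(diffs))
        assert abs(np.mean(diffs)) < 2 * se + 1e-9

    def test_planted_effect_recovered(self):
        """Mean planted R1 change at T2 matches the configured effect over
        a moderate cohort (Monte-Carlo over planted fractions)."""
        diffs_all = []
        for seed in range(8):
            spec = CohortEffectSpec(n_eyes=25, delta_r1_t2=-4.1, seed=seed)
            recs = sample_cohort_fractions(spec)
            r1 = {(r["eye_id"], r["timepoint"]): r["fd_percent"] for r in recs if r["ring"] == 1}
            diffs_all += [r1[(f"eye{e:02d}", "T2")] - r1[(f"eye{e:02d}", "T0")] for e in range(25)]
        se = np.std(diffs_all, ddof=1) / np.sqrt(len(diffs_all))
        assert abs(np.mean(diffs_all) - (-4.1)) < 2 * se

    def test_other_rings_have_no_planted_change(self):
        spec = CohortEffectSpec(n_eyes=200, delta_r1_t2=-4.1, seed=4)
        recs = sample_cohort_fractions(spec)
        for ring in (2, 3, 4, 5):
            vals = {(r["eye_id"], r["timepoint"]): r["fd_percent"] for r in recs if r["ring"] == ring}
            diffs = [vals[(f"eye{e:02d}", "T2")] - vals[(f"eye{e:02d}", "T0")] for e in range(200)]
            se = np.std(diffs, ddof=1) / np.sqrt(len(diffs))
            assert abs(np.mean(diffs)) < 3 * se + 1e-9

    def test_within_eye_correlation(self):
        spec = CohortEffectSpec(n_eyes=2000, delta_r1_t2=0.0,
                                within_eye_correlation=0.8, seed=13)
        recs = sample_cohort_fractions(spec)
        t0 = np.array([r["fd_percent"] for r in recs if r["ring"] == 2 and r["timepoint"] == "T0"])
        t2 = np.array([r["fd_percent"] for r in recs if r["ring"] == 2 and r["timepoint"] == "T2"])
        assert abs(np.corrcoef(t0, t2)[0, 1] - 0.8) < 0.05

    def test_cohort_determinism_and_shared_geometry(self):
        spec = CohortEffectSpec(n_eyes=2, seed=1)
        params = SynthParams(image_size_px=128, seed=1)
        c1 = generate_paired_cohort(spec, params)
        c2 = generate_paired_cohort(spec, params)
        assert len(c1) == 6
        for a, b in zip(c1, c2):
            assert np.array_equal(a.scan.flow, b.scan.flow)
        # one lesion geometry per eye, shared across visits
        eye0 = [c for c in c1 if c.eye_id == "eye00"]
        assert all(np.array_equal(eye0[0].roi.mnv_mask, c.roi.mnv_mask) for c in eye0)

    def test_rejects_single_eye(self):
        with pytest.raises(ValueError):
            CohortEffectSpec(n_eyes=1)

    def test_cohort_plants_requested_ring_fractions(self):
        spec = CohortEffectSpec(n_eyes=2, seed=6)
        params = SynthParams(image_size_px=160, seed=6)
        recs = sample_cohort_fractions(spec)
        cohort = generate_paired_cohort(spec, params)
        want = {(r["eye_id"], r["timepoint"], r["ring"]): r["fd_percent"] for r in recs}
        for cs in cohort:
            for k in range(1, 6):
                planted = 100 * cs.truth.deficit_fraction_per_region[f"R{k}"]
                # exact up to the rounding of the per-region pixel count
                npx = (cs.truth.region_labels == k).sum()
                assert abs(planted - want[(cs.eye_id, cs.timepoint, k)]) <= 100 * 0.5 / npx + 1e-9
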