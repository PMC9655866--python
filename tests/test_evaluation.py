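import numpy as np
import pytest

from dosegan.grid import DoseDistribution, StructureSet, VolumeGrid
from dosegan.evaluation import (
    conformity_index,
    cumulative_dvh,
    difference_histogram,
    dvh_query,
    evaluate_case,
    gamma_passing_rate,
    homogeneity_index,
    isodose_dsc,
    mae_percent,
    paired_ttest,
)


def dose_dist(values, rx=5400.0, spacing=(3.5, 3.5, 3.5)):
    return DoseDistribution(VolumeGrid(np.asarray(values, dtype=float), spacing), rx)


class TestMAE:
    def test_identical_is_zero(self, rng):
        d = dose_dist(rng.random((4, 4, 4)) * 5000)
        assert mae_percent(d, d, np.ones((4, 4, 4))) == 0.0

    def test_constant_offset(self, rng):
        gt = rng.random((4, 4, 4)) * 5000
        pred = gt + 54.0
        assert mae_percent(dose_dist(gt), dose_dist(pred), np.ones((4, 4, 4))) == (
            pytest.approx(1.0)
        )

    def test_three_voxel_hand_case(self):
        gt = np.zeros((1, 1, 3))
        pred = np.array([[[0.0, 54.0, 108.0]]])
        got = mae_percent(dose_dist(gt), dose_dist(pred), np.ones((1, 1, 3)))
        assert got == pytest.approx(1.0)  # mean of 0%, 1%, 2%

    def test_empty_mask_rejected(self, rng):
        d = dose_dist(rng.random((2, 2, 2)))
        with pytest.raises(ValueError):
            mae_percent(d, d, np.zeros((2, 2, 2)))


class TestDVH:
    def test_uniform_dose_is_step(self):
        dose = np.full((3, 3, 3), 5400.0)
        curve = cumulative_dvh(dose, np.ones_like(dose), bin_width=100.0)
        assert curve.volume_percent[0] == 100.0
        assert np.all(curve.volume_percent[curve.bin_edges <= 5400.0] == 100.0)
        assert np.all(curve.volume_percent[curve.bin_edges > 5400.0] == 0.0)

    def test_half_and_half_plateau(self):
        dose = np.concatenate([np.zeros(8), np.full(8, 5400.0)]).reshape(2, 2, 4)
        curve = cumulative_dvh(dose, np.ones_like(dose), bin_width=100.0)
        mid = (curve.bin_edges > 0) & (curve.bin_edges <= 5400.0)
        assert np.all(curve.volume_percent[mid] == 50.0)

    def test_monotone_nonincreasing_on_random_fields(self, rng):
        for _ in range(10):
            dose = rng.random((4, 4, 4)) * 6000
            curve = cumulative_dvh(dose, np.ones_like(dose))
            assert np.all(np.diff(curve.volume_percent) <= 0)


class TestDVHQuery:
    def test_uniform_dose(self):
        dose = np.full((2, 2, 2), 5400.0)
        mask = np.ones_like(dose)
        for p in (2, 50, 95, 99):
            assert dvh_query(dose, mask, "D", p) == 5400.0
        assert dvh_query(dose, mask, "V", 4000.0) == 100.0

    def test_ten_voxel_sort_oracle(self):
        dose = (np.arange(10.0) + 1) * 100.0  # 100 .. 1000
        mask = np.ones(10)
        dose = dose.reshape(1, 2, 5)
        mask = mask.reshape(1, 2, 5)
        assert dvh_query(dose, mask, "D", 95) == 100.0
        assert dvh_query(dose, mask, "D", 50) == 600.0
        assert dvh_query(dose, mask, "V", 550.0) == 50.0

    def test_dp_vd_duality_on_random_fields(self, rng):
        for _ in range(100):
            dose = rng.random((3, 3, 3)) * 6000
            mask = np.ones_like(dose)
            p = float(rng.uniform(1, 100))
            dp = dvh_query(dose, mask, "D", p)
            assert dvh_query(dose, mask, "V", dp) >= p
            d = float(rng.uniform(0, 6000))
            if dvh_query(dose, mask, "V", d) >= p:
                assert d <= dp
            else:
                assert d > dp


class TestIndices:
    def test_hi_uniform_zero_and_hand_case(self):
        assert homogeneity_index(5400.0, 5400.0, 5400.0) == 0.0
        assert homogeneity_index(5960.0, 5420.0, 5700.0) == pytest.approx(0.0947, abs=5e-5)

    def test_hi_scale_invariance(self, rng):
        d2, d98, d50 = 5960.0, 5420.0, 5700.0
        for s in (0.5, 2.0, 7.3):
            assert homogeneity_index(d2 * s, d98 * s, d50 * s) == pytest.approx(
                homogeneity_index(d2, d98, d50)
            )

    def test_ci_perfect_conformity(self):
        ptv = np.zeros((4, 4, 4), dtype=bool)
        ptv[1:3, 1:3, 1:3] = True
        dose = np.where(ptv, 5400.0, 1000.0)
        assert conformity_index(ptv, dose, 5400.0) == pytest.approx(1.0)

    def test_ci_disjoint_is_zero(self):
        ptv = np.zeros((4, 4, 4), dtype=bool)
        ptv[0, 0, 0] = True
        dose = np.zeros((4, 4, 4))
        dose[3, 3, 3] = 6000.0
        assert conformity_index(ptv, dose, 5400.0) == 0.0

    def test_ci_count_oracle(self):
        # V_T = 100, V_P = 120, V_TP = 90 -> 90^2 / (100 * 120)
        ptv = np.zeros(1000, dtype=bool)
        ptv[:100] = True
        dose = np.zeros(1000)
        dose[10:130] = 5400.0  # 120 voxels at Rx; 90 overlap the PTV
        got = conformity_index(ptv.reshape(10, 10, 10), dose.reshape(10, 10, 10), 5400.0)
        assert got == pytest.approx(0.675)


class TestDSC:
    def test_identical_is_one_at_every_level(self, rng):
        dose = rng.random((5, 5, 5)) * 6000
        for lvl in range(10, 101, 10):
            assert isodose_dsc(dose, dose, lvl, 5400.0) == 1.0

    def test_disjoint_is_zero(self):
        a = np.zeros((3, 3, 3)); a[0] = 6000.0
        b = np.zeros((3, 3, 3)); b[2] = 6000.0
        assert isodose_dsc(a, b, 90, 5400.0) == 0.0

    def test_set_count_oracle(self):
        # |A| = 80, |B| = 60, |A intersect B| = 50 -> 100/140
        a = np.zeros(200); a[:80] = 6000.0
        b = np.zeros(200); b[30:90] = 6000.0
        got = isodose_dsc(a.reshape(2, 10, 10), b.reshape(2, 10, 10), 100, 5400.0)
        assert got == pytest.approx(100.0 / 140.0)

    def test_both_empty_is_one_with_warning(self):
        z = np.zeros((2, 2, 2))
        with pytest.warns(UserWarning):
            assert isodose_dsc(z, z, 50, 5400.0) == 1.0


class TestGamma:
    def test_identical_fields_pass_fully(self, small_case):
        _, _, dose = small_case
        res = gamma_passing_rate(dose, dose)
        assert res.passing_rate == 100.0
        assert np.nanmax(res.gamma) == 0.0

    def test_flat_field_two_percent_offset(self):
        ref = dose_dist(np.full((6, 6, 6), 5400.0))
        ev = dose_dist(np.full((6, 6, 6), 5400.0 * 1.02))
        res = gamma_passing_rate(ref, ev)
        # pure dose difference: gamma = 2/3 everywhere
        np.testing.assert_allclose(res.gamma, 2.0 / 3.0, rtol=1e-10)
        assert res.passing_rate == 100.0

    def test_flat_field_six_percent_offset(self):
        ref = dose_dist(np.full((6, 6, 6), 5400.0))
        ev = dose_dist(np.full((6, 6, 6), 5400.0 * 1.06))
        res = gamma_passing_rate(ref, ev)
        np.testing.assert_allclose(res.gamma, 2.0, rtol=1e-10)
        assert res.passing_rate == 0.0

    def test_flat_field_symmetry_under_swap(self):
        a = dose_dist(np.full((5, 5, 5), 5400.0))
        b = dose_dist(np.full((5, 5, 5), 5400.0 * 1.02))
        r1 = gamma_passing_rate(a, b)
        r2 = gamma_passing_rate(b, a)
        np.testing.assert_allclose(r1.gamma, r2.gamma, rtol=1e-6)

    def test_low_dose_voxels_excluded(self):
        vals = np.full((4, 4, 4), 100.0)  # below 10% of 5400
        vals[0, 0, 0] = 5400.0
        ref = dose_dist(vals)
        res = gamma_passing_rate(ref, ref)
        assert np.isnan(res.gamma[1, 1, 1]) and res.gamma[0, 0, 0] == 0.0

    def test_loosening_criteria_never_hurts(self, rng):
        base = 5400.0 * (0.5 + 0.5 * rng.random((6, 6, 6)))
        ref = dose_dist(base)
        ev = dose_dist(base * (1 + 0.04 * rng.standard_normal((6, 6, 6))))
        tight = gamma_passing_rate(ref, ev, dd_pct=3, dta_mm=3)
        loose_dd = gamma_passing_rate(ref, ev, dd_pct=6, dta_mm=3)
        # same offset lattice for the looser DTA so search points are a superset
        loose_dta = gamma_passing_rate(ref, ev, dd_pct=3, dta_mm=6, step_divisor=20)
        assert np.all(loose_dd.gamma[~np.isnan(tight.gamma)] <=
                      tight.gamma[~np.isnan(tight.gamma)] + 1e-9)
        assert loose_dd.passing_rate >= tight.passing_rate
        assert loose_dta.passing_rate >= tight.passing_rate

    def test_dta_rescues_spatial_shift(self):
        # a one-voxel (3.5 mm) shift of a gradient field fails on dose
        # difference alone but lies within 2x DTA spatially
        grad = np.tile(np.linspace(1000, 6000, 8), (8, 8, 1))
        ref = dose_dist(grad)
        ev = dose_dist(np.roll(grad, 1, axis=2))
        res = gamma_passing_rate(ref, ev, dta_mm=3.5)
        interior = res.gamma[:, :, 2:-2]
        assert np.nanmax(interior) <= 1.0 + 1e-6


class TestHistogram:
    def test_identical_spike_at_zero(self, rng):
        d = dose_dist(rng.random((3, 3, 3)) * 5000)
        h = difference_histogram(d, d, np.ones((3, 3, 3)))
        assert h["bias_cgy"] == 0.0 and h["sd_cgy"] == 0.0

    def test_constant_offset_bias(self, rng):
        gt = rng.random((3, 3, 3)) * 5000
        h = difference_histogram(
            dose_dist(gt), dose_dist(gt + 100.0), np.ones((3, 3, 3))
        )
        assert h["bias_cgy"] == pytest.approx(100.0)

    def test_counts_conserved(self, rng):
        gt = rng.random((4, 4, 4)) * 5000
        mask = rng.random((4, 4, 4)) > 0.4
        h = difference_histogram(dose_dist(gt), dose_dist(gt * 1.01), mask)
        assert h["counts"].sum() == mask.sum()


class TestPairedTTest:
    def test_constant_shift_with_tiny_noise(self, rng):
        a = rng.normal(size=10)
        b = a + 1.0 + rng.normal(0, 1e-6, size=10)
        t, p = paired_ttest(a, b)
        assert p < 1e-6

    def test_alternating_differences_mean_zero(self):
        a = np.zeros(10)
        b = np.tile([1.0, -1.0], 5)
        t, p = paired_ttest(a, b)
        assert t == pytest.approx(0.0) and p == pytest.approx(1.0)

    def test_textbook_three_pair_case(self):
        a = np.array([1.0, 2.0, 3.0])
        t, p = paired_ttest(a + a, a)  # differences (1, 2, 3)
        assert t == pytest.approx(2 * np.sqrt(3), rel=1e-6)
        from scipy import stats

        assert p == pytest.approx(2 * stats.t.sf(2 * np.sqrt(3), df=2), rel=1e-6)

    def test_zero_variance_flagged(self):
        with pytest.raises(ValueError, match="degenerate"):
            paired_ttest(np.arange(5.0), np.arange(5.0) + 2.0)


class TestEvaluateCase:
    def test_perfect_prediction_hits_ideal_values(self, small_case):
        ct, structures, dose = small_case
        report = evaluate_case(dose, dose, structures)
        for role, entry in report["structures"].items():
            assert entry["mae_percent"] == 0.0
            for k, v in entry["indices_gt"].items():
                assert entry["indices_pred"][k] == pytest.approx(v)
        assert all(v == 1.0 for v in report["dsc"].values())
        assert report["gamma"]["global_gpr"] == 100.0
        assert report["difference_histogram"]["bias_cgy"] == 0.0

    def test_report_schema_complete(self, small_case):
        ct, structures, dose = small_case
        report = evaluate_case(dose, dose, structures)
        ptv = report["structures"]["ptv"]["indices_gt"]
        for key in ("d99", "d98", "d95", "d50", "d2", "hi", "ci", "dmax", "dmean"):
            assert key in ptv
        for oar in ("bladder", "rectum", "femur_head_l", "femur_head_r"):
            idx = report["structures"][oar]["indices_gt"]
            assert "dmax" in idx and "dmean" in idx
        assert "v40" in report["structures"]["bladder"]["indices_gt"]
        assert "v40" in report["structures"]["rectum"]["indices_gt"]
        assert set(report["gamma"]["per_structure"]) >= {"ptv", "body"}

    def test_index_ordering_chain(self, small_case):
        _, structures, dose = small_case
        from dosegan.evaluation import dose_indices

        idx = dose_indices(dose.values, structures["ptv"], 5400.0, "ptv")
        assert idx.d99 <= idx.d98 <= idx.d95 <= idx.d50 <= idx.d2 <= idx.dmax
        assert idx.hi >= 0.0

    def test_indices_match_independent_recomputation(self, small_case):
        _, structures, dose = small_case
        from dosegan.evaluation import dose_indices

        idx = dose_indices(dose.values, structures["ptv"], 5400.0, "ptv")
        vals = np.sort(dose.values[structures["ptv"].astype(bool)])[::-1]
        m = vals.size
        assert idx.d95 == vals[int(np.ceil(95 * m / 100)) - 1]
        assert idx.dmean == pytest.approx(vals.mean())
        assert idx.dmax == vals[0]
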