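"""Tests for calibration building, hydration inversion, breakpoint and
hysteresis analysis."""

import numpy as np
import pytest

from hydrasense import (
    CalibrationCurve,
    CalibrationPoint,
    build_calibration,
    detect_breakpoint,
    hysteresis_metric,
    rh_to_waters,
    sense,
)
from hydrasense.frap_sim import phase_separated_d_of_rh
from hydrasense.hydration import read_calibration_csv, write_calibration_csv


def curve_from_table(table, branch="dehydration", n_rep=1, jitter=0.0, seed=0):
    rng = np.random.default_rng(seed)
    pts = []
    for rh, d in table:
        reps = tuple(
            max(d + jitter * d * rng.standard_normal(), 1e-6) for _ in range(n_rep)
        )
        pts.append(CalibrationPoint(rh, reps, branch))
    return build_calibration(pts)


class TestBuildCalibration:
    def test_knot_means_hit_exactly(self, single_component_curve):
        assert float(single_component_curve.d_at(85.0)) == pytest.approx(4.75)
        assert float(single_component_curve.d_at(100.0)) == pytest.approx(5.35)
        assert float(single_component_curve.d_at(0.0)) == pytest.approx(0.25)

    def test_identical_replicates_zero_band(self):
        pts = [
            CalibrationPoint(rh, (d, d), "dehydration")
            for rh, d in [(0, 0.25), (50, 1.0), (100, 5.35)]
        ]
        curve = build_calibration(pts)
        np.testing.assert_allclose(curve.d_sds, 0.0)

    def test_large_non_monotone_dip_rejected(self):
        pts = [
            CalibrationPoint(rh, (d,), "dehydration")
            for rh, d in [(0, 0.25), (40, 3.0), (70, 1.0), (100, 5.35)]
        ]
        with pytest.raises(ValueError, match="non-monotone"):
            build_calibration(pts)

    def test_small_dip_within_sd_is_monotonized(self):
        pts = [
            CalibrationPoint(0, (0.25, 0.3), "dehydration"),
            CalibrationPoint(40, (1.05, 0.95), "dehydration"),
            CalibrationPoint(60, (1.0, 0.9), "dehydration"),  # dip 0.05 < SD
            CalibrationPoint(100, (5.0, 5.2), "dehydration"),
        ]
        curve = build_calibration(pts)
        assert curve.monotonized
        assert np.all(np.diff(curve.d_means) >= 0)

    def test_requires_three_levels(self):
        pts = [CalibrationPoint(rh, (1.0,), "dehydration") for rh in (0, 100)]
        with pytest.raises(ValueError, match="3 distinct RH"):
            build_calibration(pts)

    def test_branches_never_pooled(self):
        pts = [
            CalibrationPoint(0, (0.2,), "dehydration"),
            CalibrationPoint(50, (1.0,), "dehydration"),
            CalibrationPoint(100, (5.0,), "dehydration"),
            CalibrationPoint(50, (0.8,), "rehydration"),
        ]
        curve = build_calibration(pts, branch="dehydration")
        assert float(curve.d_at(50.0)) == pytest.approx(1.0)

    def test_csv_roundtrip(self, tmp_path):
        pts = [
            CalibrationPoint(0, (0.2, 0.3), "dehydration"),
            CalibrationPoint(50, (1.0, 1.1), "dehydration"),
            CalibrationPoint(100, (5.0, 5.1), "dehydration"),
        ]
        path = tmp_path / "cal.csv"
        write_calibration_csv(pts, path)
        back = read_calibration_csv(path)
        assert len(back) == 3
        assert back[1].d_values == (1.0, 1.1)

    def test_curve_json_roundtrip(self, tmp_path, single_component_curve):
        path = tmp_path / "curve.json"
        single_component_curve.to_json(path)
        back = CalibrationCurve.from_json(path)
        np.testing.assert_allclose(back.rh_knots, single_component_curve.rh_knots)
        np.testing.assert_allclose(back.d_means, single_component_curve.d_means)
        assert back.branch == single_component_curve.branch


class TestRhToWaters:
    @pytest.mark.parametrize("rh,waters", [(25, 2.4), (50, 3.6), (75, 6.3), (95, 10.5)])
    def test_anchors_reproduced_exactly(self, rh, waters):
        assert rh_to_waters(rh).waters == waters

    def test_floor_below_25(self):
        for rh in (0.0, 10.0, 24.9):
            est = rh_to_waters(rh)
            assert est.floor_applied
            assert est.waters == 4.0  # "not more than four"
            assert (est.low, est.high) == (3.0, 4.0)

    def test_above_95_is_lower_bound(self):
        est = rh_to_waters(99.0)
        assert est.extrapolated
        assert est.waters == 10.5
        assert est.high == np.inf

    def test_monotone_on_anchor_range(self):
        grid = np.linspace(25, 95, 500)
        vals = [rh_to_waters(r).waters for r in grid]
        assert np.all(np.diff(vals) >= 0)

    def test_domain_error(self):
        with pytest.raises(ValueError):
            rh_to_waters(101.0)


class TestSense:
    def test_knot_roundtrip_exact(self, single_component_curve):
        for rh, d in zip(
            single_component_curve.rh_knots, single_component_curve.d_means
        ):
            est = sense(float(d), single_component_curve)
            assert est.rh_estimate == pytest.approx(float(rh), abs=1e-3)

    def test_matches_grid_scan_oracle(self, single_component_curve):
        d_query = 1.2
        grid = np.linspace(0, 100, 10_001)
        vals = np.asarray(single_component_curve.d_at(grid))
        rh_oracle = grid[np.argmin(np.abs(vals - d_query))]
        est = sense(d_query, single_component_curve)
        assert est.rh_estimate == pytest.approx(rh_oracle, abs=0.1)

    def test_monotone_in_d(self, single_component_curve):
        ds = np.linspace(0.26, 5.3, 50)
        rhs = [sense(float(d), single_component_curve).rh_estimate for d in ds]
        assert np.all(np.diff(rhs) >= 0)

    def test_dried_phase_separated_membrane(self):
        curve = curve_from_table(phase_separated_d_of_rh())
        est = sense(0.04, curve)
        assert est.rh_estimate == pytest.approx(0.0, abs=1.0)
        assert est.waters_per_lipid <= 4.0
        assert est.floor_applied

    def test_out_of_range_clamped_and_flagged(self, single_component_curve):
        high = sense(50.0, single_component_curve)
        assert high.extrapolated and high.rh_estimate == 100.0
        low = sense(0.01, single_component_curve)
        assert low.extrapolated and low.rh_estimate == 0.0

    def test_ci_propagates_through_inverse(self, single_component_curve):
        est = sense(1.2, single_component_curve, d_ci=(1.0, 1.5))
        assert est.rh_low < est.rh_estimate < est.rh_high
        assert est.waters_low <= est.waters_per_lipid <= est.waters_high


class TestDetectBreakpoint:
    def test_perfect_hinge_recovered(self):
        rh = np.array([0, 20, 35, 50, 70, 85, 100], dtype=float)
        d = np.where(rh <= 50, 0.3 + 0.002 * rh, 0.4 + 0.09 * (rh - 50))
        curve = curve_from_table(list(zip(rh, d)))
        fit = detect_breakpoint(curve)
        assert fit.rh_breakpoint == 50.0
        assert fit.significant

    def test_straight_line_flagged_no_breakpoint(self):
        rh = np.array([0, 30, 60, 100], dtype=float)
        curve = curve_from_table(list(zip(rh, 0.1 + 0.04 * rh)))
        fit = detect_breakpoint(curve)
        assert not fit.significant

    def test_single_component_profile_breaks_near_50(self, single_component_curve):
        fit = detect_breakpoint(single_component_curve)
        assert 45.0 <= fit.rh_breakpoint <= 55.0
        assert fit.significant

    def test_requires_four_knots(self):
        curve = curve_from_table([(0, 0.2), (50, 1.0), (100, 5.0)])
        with pytest.raises(ValueError):
            detect_breakpoint(curve)


class TestHysteresis:
    def test_identical_curves_fully_reversible(self, single_component_curve):
        summary = hysteresis_metric(single_component_curve, single_component_curve)
        np.testing.assert_allclose(summary.delta_d, 0.0, atol=1e-12)
        assert summary.verdict == "fully reversible"

    def test_scaled_rehydration_branch(self):
        table = [(0, 0.25), (45, 0.42), (65, 1.8), (85, 4.75), (100, 5.35)]
        dehyd = curve_from_table(table)
        rehyd = curve_from_table(
            [(rh, 0.9 * d) for rh, d in table], branch="rehydration"
        )
        summary = hysteresis_metric(dehyd, rehyd)
        assert np.all(summary.delta_d > 0)
        ratio = np.asarray(rehyd.d_at(summary.rh_grid)) / np.asarray(
            dehyd.d_at(summary.rh_grid)
        )
        assert np.mean(ratio) == pytest.approx(0.9, abs=0.01)

    def test_lower_rehydration_with_matching_bulk_is_hysteresis(self):
        dehyd_pts = [
            CalibrationPoint(rh, (d * 0.98, d * 1.02), "dehydration")
            for rh, d in [(0, 0.25), (45, 0.42), (65, 1.8), (85, 4.75), (100, 5.35)]
        ]
        rehyd_pts = [
            CalibrationPoint(rh, (d * 0.98, d * 1.02), "rehydration")
            for rh, d in [(0, 0.25), (45, 0.35), (65, 1.4), (85, 4.1), (100, 5.30)]
        ]
        summary = hysteresis_metric(
            build_calibration(dehyd_pts), build_calibration(rehyd_pts)
        )
        assert summary.bulk_reversible
        assert summary.mean_delta > 0
        assert summary.verdict == "reversible with hysteresis"

    def test_disjoint_domains_rejected(self):
        low = curve_from_table([(0, 0.2), (10, 0.3), (20, 0.4)])
        high = curve_from_table([(60, 1.0), (80, 2.0), (100, 5.0)])
        with pytest.raises(ValueError):
            hysteresis_metric(low, high)
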