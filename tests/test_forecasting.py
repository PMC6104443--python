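"""Forecast grids, milestones, stalling, leapfrogging and calibration."""

import numpy as np
import pytest

from ehrcast import (
    BassParams,
    Generation,
    GenerationsModel,
    InfeasibleAnchorsError,
    StageYearPanel,
    calibrate_launch_offsets,
    detect_leapfrogging,
    forecast,
    generations_curves,
    mid_anchors,
    mid_time,
    milestones,
    stall_counts,
)


def _model(ms, ps, qs, taus, base=2000, horizon=2050):
    gens = tuple(
        Generation(i, ms[i], taus[i], BassParams(ps[i], qs[i])) for i in range(len(ms))
    )
    return GenerationsModel(base, horizon, gens)


class TestForecastGrid:
    def test_horizon_equal_base_gives_single_column(self):
        m = _model([10.0], [0.2], [0.1], [0.0], base=2010, horizon=2010)
        c = forecast(m)
        assert c.years.shape == (1,)
        assert c.S.shape == (1, 1)

    def test_annual_grid_spans_base_to_horizon(self, table2_model, table2_curves):
        years = table2_curves.years.astype(int)
        assert years[0] == table2_model.base_year
        assert years[-1] == table2_model.horizon_year
        assert np.all(np.diff(years) == 1)

    def test_last_stage_occupancy_strictly_increases(self, table2_curves):
        """The top stage has no successor, so its occupancy equals its
        cumulative curve: never decreasing, and strictly rising once
        the generation has launched."""
        S7 = table2_curves.occupancy(7)
        assert np.all(np.diff(S7) >= 0)
        live = S7 > 0
        assert np.all(np.diff(S7[live]) > 0)


class TestMilestones:
    def test_single_generation_mid_year_matches_closed_form(self):
        params = BassParams(0.05, 0.4)
        m = _model([500.0], [0.05], [0.4], [0.0], base=2000, horizon=2080)
        table = milestones(forecast(m))
        row = table.row(0)
        # by the horizon the curve is saturated, so the horizon-relative
        # mid-year is the ceiling of the closed-form t50
        assert row.mid_year == 2000 + int(np.ceil(mid_time(params)))
        # no successor: never peaks before the horizon
        assert row.peaked is False
        assert row.max_year == 2080

    def test_two_generation_peak_matches_fine_grid(self):
        """Annual argmax agrees with a 0.01-year grid search on the
        first generation's occupancy."""
        m = _model([300.0, 200.0], [0.08, 0.06], [0.3, 0.4], [0.0, 6.0])
        table = milestones(forecast(m))
        fine = np.arange(2000.0, 2050.0, 0.01)
        c = generations_curves(m, fine)
        t_star = fine[np.argmax(c.S[0])]
        assert abs(table.row(0).max_year - t_star) <= 1.0
        assert table.row(0).peaked is True

    def test_all_zero_stage_reported_missing(self):
        m = _model([100.0, 0.0], [0.1, 0.1], [0.0, 0.0], [0.0, 50.0])
        table = milestones(forecast(m))
        assert table.row(1).mid_year is None
        assert table.row(1).stall_count is None

    def test_peak_milestones_invariant_to_grid_extension(self):
        """Extending the horizon does not move the peak of a stage that
        has already peaked."""
        m1 = _model([300.0, 200.0], [0.08, 0.06], [0.3, 0.4], [0.0, 6.0], horizon=2040)
        m2 = _model([300.0, 200.0], [0.08, 0.06], [0.3, 0.4], [0.0, 6.0], horizon=2050)
        r1 = milestones(forecast(m1)).row(0)
        r2 = milestones(forecast(m2)).row(0)
        assert r1.peaked and r2.peaked
        assert r1.max_year == r2.max_year


class TestStallCounts:
    def test_sums_to_conservation_total(self, table2_model, table2_curves):
        counts = stall_counts(table2_curves, 2035)
        assert sum(counts.values()) == pytest.approx(
            float(table2_curves.S.sum(axis=0)[-1]), abs=1e-9
        )

    def test_base_year_mass_in_early_stages(self):
        m = _model([100.0, 50.0], [0.3, 0.2], [0.0, 0.0], [-10.0, 20.0])
        c = forecast(m)
        at_base = stall_counts(c, 2000)
        assert at_base[0] > 0
        assert at_base[1] == 0  # successor not yet launched

    def test_off_grid_year_rejected(self, table2_curves):
        with pytest.raises(ValueError, match="not on the evaluated grid"):
            stall_counts(table2_curves, 2060)


class TestLeapfrogging:
    def test_sequential_saturating_cascade_raises_no_flags(self):
        """Equal markets, separated launches, full pass-through, observed
        over the active filling phase: every stage fills higher than its
        predecessor and no cumulative curve stalls while its successor
        grows.  (In the deep saturated tail the relative-growth
        heuristic necessarily trips on any multi-generation system, so
        the invariant is a statement about the filling phase.)"""
        m = _model(
            [100.0, 100.0, 100.0], [0.35, 0.35, 0.35], [0.0, 0.0, 0.0], [0.0, 6.0, 12.0]
        )
        c = generations_curves(m, np.arange(2000.0, 2019.0))
        report = detect_leapfrogging(c)
        assert report.flagged() == []

    def test_skipped_stage_gets_occupancy_flag(self, insample_model):
        """A cohort in which units leapfrog the thin Stage 1 (its
        occupancy never exceeds Stage 0's) must flag it; verified by
        directly counting multi-stage jumps in the trajectories."""
        from ehrcast import CohortSpec, simulate_panel

        spec = CohortSpec(model=insample_model, n_units=3000, mode="stochastic", seed=5)
        traj, panel = simulate_panel(spec)
        report = detect_leapfrogging(panel)
        assert report.never_exceeds_predecessor[1] is True
        piv = traj.pivot(index="unit_id", columns="year", values="stage").to_numpy()
        first = piv[:, :-1]
        skipped_1 = ((first < 1) & (piv[:, 1:] > 1)).any(axis=1).mean()
        assert skipped_1 > 0.3  # stage 1 is predominantly skipped

    def test_flat_cumulative_with_growing_successor_flagged(self):
        """The published leapfrogging signature: stage-4 cumulative flat
        over >= 3 years while stage-5 cumulative keeps growing."""
        years = np.arange(2008, 2015)
        S5 = np.array([0.0, 10, 30, 60, 100, 150, 210])
        A4 = np.full(years.size, 400.0)  # plateaued
        S4 = A4 - S5
        panel = StageYearPanel(years, [4, 5], np.vstack([S4, S5]))
        report = detect_leapfrogging(panel)
        interval = report.cumulative_flat_while_successor_grows[4]
        assert interval is not None
        lo, hi = interval
        assert hi - lo >= 3

    def test_single_year_input_rejected(self):
        panel = StageYearPanel(np.array([2006]), [0, 1], np.array([[1.0], [2.0]]))
        with pytest.raises(ValueError, match="2 years"):
            detect_leapfrogging(panel)


class TestCalibration:
    def test_single_generation_anchor_recovers_launch(self):
        m = _model([500.0], [0.05], [0.4], [0.0], base=2000, horizon=2080)
        t50 = mid_time(BassParams(0.05, 0.4))
        anchor = 2012.0
        cal = calibrate_launch_offsets(m, {0: anchor})
        # single generation saturates by 2080, so the horizon-relative mid
        # equals the own-curve mid: tau = anchor - t50 exactly
        assert cal.tau[0] + 2000 == pytest.approx(anchor - t50, abs=1e-3)
        assert cal.fallback_stages == []
        assert abs(cal.residual_years[0]) <= 1.0

    def test_packaged_anchors_hit_within_one_year(self, table2_model):
        """Recalibrating the packaged model against its anchors lands
        every reachable stage's mid-year within a year; the two early
        stages are swamped by later generations' direct entrants and
        fall back to own-curve anchoring."""
        anchors = mid_anchors()
        cal = calibrate_launch_offsets(table2_model, anchors)
        assert cal.fallback_stages == [0, 1]
        for stage in range(2, 8):
            assert abs(cal.residual_years[stage]) <= 1.0
        assert np.allclose(cal.tau, table2_model.tau, atol=1e-6)

    def test_strict_mode_names_offending_stages(self, table2_model):
        with pytest.raises(InfeasibleAnchorsError) as err:
            calibrate_launch_offsets(table2_model, mid_anchors(), strict=True)
        assert err.value.stages == [0, 1]

    def test_anchor_perturbation_is_local(self, table2_model):
        """Moving one stage's anchor a year later moves (mostly) only
        that stage's launch, by about a year."""
        anchors = mid_anchors()
        base = calibrate_launch_offsets(table2_model, anchors)
        shifted = dict(anchors)
        shifted[4] = anchors[4] + 1
        moved = calibrate_launch_offsets(table2_model, shifted)
        delta = moved.tau - base.tau
        assert delta[4] == pytest.approx(1.0, abs=0.35)
        others = np.delete(delta, 4)
        assert np.max(np.abs(others)) < 0.35

    def test_missing_anchor_rejected(self, table2_model):
        with pytest.raises(ValueError, match="missing"):
            calibrate_launch_offsets(table2_model, {0: 2008.0})
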