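"""Respirometry estimators against hand computations and closed forms."""

import math

import numpy as np
import pandas as pd
import pytest

from thermoperf.config import AnalysisParams, CycleSchedule, RespirometerSpec
from thermoperf.respirometry import (
    MO2Sample,
    O2Trace,
    RespirometryError,
    SlopeRecord,
    align_cohort_timepoints,
    compute_epoc,
    compute_mo2,
    correct_background,
    estimate_smr,
    find_mmr,
    find_recovery_time,
    fit_slope,
    oxygen_solubility,
    segment_cycles,
    summarize_fish,
)
from thermoperf.synthetic import RespirometrySimParams, simulate_o2_trace

from conftest import linear_decline_trace, make_trace


def rec(slope, start=0.0, end=60.0, source="whole_cycle"):
    return SlopeRecord(
        window_start=start, window_end=end, slope=slope, source=source
    )


class TestComputeMO2:
    def test_hand_arithmetic_example(self, spec):
        # 10 %sat/h * (0.160-0.010) L * 0.08 mg/L/%sat / 0.050 kg
        sample = compute_mo2(rec(10.0), spec)
        assert sample.mo2 == pytest.approx(2.4, abs=1e-12)

    def test_zero_slope(self, spec):
        assert compute_mo2(rec(0.0), spec).mo2 == 0.0

    def test_linearity_in_mass_and_volume(self, spec):
        base = compute_mo2(rec(10.0), spec).mo2
        heavy = RespirometerSpec(
            spec.loop_volume, spec.fish_volume, spec.alpha, 2 * spec.mass
        )
        assert compute_mo2(rec(10.0), heavy).mo2 == pytest.approx(base / 2)
        bigger = RespirometerSpec(
            2 * spec.loop_volume - spec.fish_volume,
            spec.fish_volume,
            spec.alpha,
            spec.mass,
        )
        assert compute_mo2(rec(10.0), bigger).mo2 == pytest.approx(2 * base)


class TestBackgroundCorrection:
    def test_mean_subtraction(self):
        out = correct_background(
            [rec(10.0)], [rec(1.0, source="background")] * 3
        )
        assert out[0].slope == pytest.approx(9.0)

    def test_zero_background_is_identity(self):
        out = correct_background(
            [rec(10.0)], [rec(0.0, source="background")]
        )
        assert out[0].slope == 10.0 and not out[0].clamped

    def test_overcorrection_clamped_and_flagged(self):
        out = correct_background(
            [rec(1.0)], [rec(2.0, source="background")]
        )
        assert out[0].slope == 0.0 and out[0].clamped

    def test_no_background_cycles_is_error(self):
        with pytest.raises(RespirometryError):
            correct_background([rec(1.0)], [])


class TestSegmentCycles:
    def test_noiseless_constant_rate_recovered_exactly(self, schedule):
        trace = linear_decline_trace(schedule, 10.0, n_cycles=3)
        recs = segment_cycles(trace, schedule)
        assert len(recs) == 3
        for r in recs:
            assert r.slope == pytest.approx(10.0, rel=1e-9)

    def test_cycle_shorter_than_trims_skipped(self, schedule):
        t = np.arange(0.0, 100.0, 5.0)  # one truncated closed phase
        trace = make_trace(t, 100.0 - 0.001 * t, np.full(t.size, "closed"))
        assert segment_cycles(trace, schedule) == []

    def test_least_squares_matches_normal_equations(self, schedule):
        rng = np.random.default_rng(5)
        t = np.arange(0.0, 720.0, 5.0)
        o2 = 100.0 - 0.002 * t + rng.normal(0, 0.05, t.size)
        phases = np.where(t < 540.0, "closed", "flush").astype(object)
        trace = make_trace(t, o2, phases)
        (record,) = segment_cycles(trace, schedule)
        sel = (t >= 120.0) & (t <= 480.0)
        tc, yc = t[sel], o2[sel]
        beta = ((tc - tc.mean()) * (yc - yc.mean())).sum() / (
            (tc - tc.mean()) ** 2
        ).sum()
        assert record.slope == pytest.approx(-beta * 3600.0, rel=1e-9)


class TestFindMMR:
    @staticmethod
    def _two_rate_trace():
        # decline at 20 %sat/h for the first 90 s of closed time, then 10;
        # O2 resets to 100% at every flush
        sched = CycleSchedule(60.0, 300.0, leading_trim=0, trailing_trim=0)
        t = np.arange(0.0, 2 * sched.period, 5.0)
        o2 = np.full(t.size, 100.0)
        phases = np.empty(t.size, object)
        rate = lambda closed_t: 20.0 if closed_t < 90.0 else 10.0
        for k, tk in enumerate(t):
            local = tk % sched.period
            cycle = int(tk // sched.period)
            phases[k] = "closed" if local < 300.0 else "flush"
            if phases[k] == "closed":
                accum0 = cycle * 300.0  # closed time already accumulated
                a, b = accum0, accum0 + local
                drop = 20.0 * max(min(b, 90.0) - min(a, 90.0), 0.0)
                drop += 10.0 * (max(b, 90.0) - max(a, 90.0))
                o2[k] = 100.0 - drop / 3600.0
        return make_trace(t, o2, phases), sched

    def test_early_fast_decline_selected(self, spec):
        trace, sched = self._two_rate_trace()
        sample, window = find_mmr(trace, spec, sched)
        assert window.window_start == 0.0
        assert window.slope == pytest.approx(20.0, rel=1e-9)

    def test_constant_rate_equals_whole_cycle(self, schedule, spec):
        trace = linear_decline_trace(schedule, 10.0, n_cycles=3)
        sample, window = find_mmr(trace, spec, schedule)
        whole = compute_mo2(segment_cycles(trace, schedule)[0], spec)
        assert sample.mo2 == pytest.approx(whole.mo2, rel=1e-9)

    def test_no_closed_window_is_error(self, schedule, spec):
        t = np.arange(0.0, 100.0, 5.0)
        trace = make_trace(t, np.full(t.size, 100.0), np.full(t.size, "flush"))
        with pytest.raises(RespirometryError):
            find_mmr(trace, spec, schedule)


class TestEstimateSMR:
    def test_textbook_twenty_values(self):
        smr, n = estimate_smr(list(range(1, 21)))
        assert smr == pytest.approx(1.5)
        assert n == 2

    def test_identical_values(self):
        smr, n = estimate_smr([3.0] * 12)
        assert smr == 3.0

    def test_permutation_invariance(self):
        rng = np.random.default_rng(0)
        vals = rng.gamma(2.0, 1.0, 37)
        a, _ = estimate_smr(vals)
        b, _ = estimate_smr(rng.permutation(vals))
        assert a == pytest.approx(b, rel=1e-12)

    def test_empty_is_error(self):
        with pytest.raises(RespirometryError):
            estimate_smr([])


class TestRecoveryDetection:
    def _series(self, values, spacing_s=60.0, t0=0.0):
        return [
            MO2Sample(time_mid=t0 + i * spacing_s, mo2=v, source="fine_60s")
            for i, v in enumerate(values)
        ]

    def test_first_of_three_consecutive_rule(self):
        series = self._series([5.0, 3.0, 2.2, 2.05, 2.04, 2.02])
        t, recovered = find_recovery_time(series, smr=2.0, mmr_time=0.0)
        assert recovered
        assert t == pytest.approx(2 * 60.0 / 3600.0)  # the 2.2 sample

    def test_all_within_band_recovers_at_first_sample(self):
        series = self._series([2.0, 2.1, 1.9, 2.0])
        t, recovered = find_recovery_time(series, smr=2.0, mmr_time=0.0)
        assert recovered and t == 0.0

    def test_never_recovered_flagged(self):
        series = self._series([5.0, 4.0, 3.0])
        t, recovered = find_recovery_time(
            series, smr=2.0, mmr_time=0.0, trace_end=7200.0
        )
        assert not recovered and t == pytest.approx(2.0)


class TestEPOC:
    def test_zero_when_at_smr(self):
        series = [
            MO2Sample(time_mid=t, mo2=2.0, source="fine_60s")
            for t in np.arange(60.0, 3600.0, 60.0)
        ]
        mmr = MO2Sample(time_mid=0.0, mo2=2.0, source="mmr_window")
        assert compute_epoc(series, 2.0, mmr, 1.0) == 0.0

    def test_exponential_excess_matches_closed_form(self):
        # excess 3 mg O2/h/kg decaying with tau = 1 h to t_r = 2 h
        t = np.arange(0.0, 2.0 + 1e-9, 1.0 / 60.0)  # 1-min grid, hours
        series = [
            MO2Sample(time_mid=tk * 3600.0, mo2=2.0 + 3.0 * math.exp(-tk),
                      source="fine_60s")
            for tk in t[1:]
        ]
        mmr = MO2Sample(time_mid=0.0, mo2=5.0, source="mmr_window")
        epoc = compute_epoc(series, 2.0, mmr, 2.0)
        assert epoc == pytest.approx(3.0 * (1 - math.exp(-2.0)), rel=0.01)

    def test_linearity_in_excess(self):
        t = np.arange(1.0, 60.0) * 60.0
        mk = lambda scale: (
            [
                MO2Sample(time_mid=tk, mo2=2.0 + scale * 1.0, source="fine_60s")
                for tk in t
            ],
            MO2Sample(time_mid=0.0, mo2=2.0 + scale * 3.0, source="mmr_window"),
        )
        s1, m1 = mk(1.0)
        s2, m2 = mk(2.0)
        e1 = compute_epoc(s1, 2.0, m1, 1.0)
        e2 = compute_epoc(s2, 2.0, m2, 1.0)
        assert e2 == pytest.approx(2 * e1, rel=1e-12)


class TestCohortAlignment:
    def _series(self, times):
        return [
            MO2Sample(time_mid=t, mo2=3.0, source="fine_60s") for t in times
        ]

    def test_identical_grids_untouched(self):
        grid = list(np.arange(0.0, 600.0, 60.0))
        out = align_cohort_timepoints(
            {"a": self._series(grid), "b": self._series(grid)}
        )
        assert all(len(v) == len(grid) for v in out.values())

    def test_missing_point_dropped_for_all(self):
        grid = list(np.arange(0.0, 600.0, 60.0))
        partial = [t for t in grid if t != 300.0]
        out = align_cohort_timepoints(
            {"a": self._series(grid), "b": self._series(partial)},
            tolerance_s=10.0,
        )
        assert len(out["a"]) == len(grid) - 1
        assert all(s.time_mid != 300.0 for s in out["a"])

    def test_coarse_samples_left_untouched(self):
        fine = self._series([0.0, 60.0])
        coarse = [MO2Sample(time_mid=9000.0, mo2=2.0, source="coarse_3min")]
        out = align_cohort_timepoints(
            {"a": fine + coarse, "b": self._series([60.0])},
            tolerance_s=10.0,
        )
        assert [s.time_mid for s in out["a"]] == [60.0, 9000.0]


class TestSummaries:
    def test_recovery_series_subwindow_count(self, zero_noise_trace, spec,
                                             schedule):
        # (540 - 180) / 60 = 6 fine sub-windows per 9-min closed cycle
        trace, _ = zero_noise_trace
        from thermoperf.respirometry import build_recovery_series

        series = build_recovery_series(trace, spec, schedule, mmr_time=30.0)
        fine = [s for s in series if s.source == "fine_60s"]
        per_cycle = (
            pd.Series([s.time_mid // schedule.period for s in fine])
            .value_counts()
            .sort_index()
        )
        # full cycles inside the fine horizon hold exactly 6
        assert (per_cycle.iloc[:-1] == 6).all()

    def test_aas_is_exact_difference(self, zero_noise_trace, spec, schedule):
        trace, _ = zero_noise_trace
        summary, _ = summarize_fish(trace, spec, schedule)
        assert summary.aas == summary.mmr - summary.smr

    def test_time_translation_invariance(self, spec, schedule):
        params = RespirometrySimParams(
            true_smr=2.0, true_mmr=5.0, recovery_tau=1.0,
            schedule=schedule, spec=spec, duration_h=8.0,
            background_rate=0.5, noise_sd=0.0,
        )
        trace, _ = simulate_o2_trace(params)
        shifted = O2Trace(
            fish_id=trace.fish_id,
            test_temperature=trace.test_temperature,
            data=trace.data.assign(time_s=trace.data["time_s"] + 1234.0),
        )
        a, _ = summarize_fish(trace, spec, schedule)
        b, _ = summarize_fish(shifted, spec, schedule)
        assert b.smr == pytest.approx(a.smr, rel=1e-9)
        assert b.mmr == pytest.approx(a.mmr, rel=1e-9)
        assert b.epoc == pytest.approx(a.epoc, rel=1e-9)
        assert b.recovery_time == pytest.approx(a.recovery_time, rel=1e-9)

    def test_mmr_dominates_whole_cycle_means(self, spec, schedule):
        params = RespirometrySimParams(
            true_smr=2.0, true_mmr=6.0, recovery_tau=0.5,
            schedule=schedule, spec=spec, duration_h=6.0,
            background_rate=0.0, noise_sd=0.02, seed=11,
        )
        trace, _ = simulate_o2_trace(params)
        summary, detail = summarize_fish(trace, spec, schedule)
        cycle_mo2 = [s.mo2 for s in detail["whole_cycle_samples"]]
        assert summary.mmr >= max(cycle_mo2) - 1e-9
        assert summary.smr <= np.mean(cycle_mo2) + 1e-9


def test_oxygen_solubility_plausible_seawater_values():
    # fresh water at 0 degC holds ~14.6 mg/L; seawater holds less and
    # solubility falls with warming
    assert oxygen_solubility(0.0, 0.0) == pytest.approx(14.6, abs=0.2)
    assert oxygen_solubility(14.0, 32.0) == pytest.approx(8.3, abs=0.4)
    assert oxygen_solubility(26.0, 32.0) < oxygen_solubility(2.0, 32.0)
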