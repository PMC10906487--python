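"""Intermittent-closed respirometry analysis.

Converts a per-fish oxygen time series (percent air saturation with
flush/closed/background phase labels) into standard metabolic rate
(SMR), maximum metabolic rate (MMR), absolute aerobic scope (AAS),
excess post-exercise oxygen consumption (EPOC) and recovery time.

Oxygen consumption rate is computed from the slope of the within-chamber
O2 decline during each sealed (closed) phase:

    MO2 = s * (V_loop - V_fish) * alpha / M      [mg O2 h^-1 kg^-1]

with ``s`` the magnitude of the decline in % air saturation h^-1,
volumes in litres, ``alpha`` the oxygen solubility
(mg O2 L^-1 %sat^-1) and ``M`` the fish mass in kg.  Raw fitted slopes
are negative (O2 declines); all slope records store the magnitude and
the equation above is applied to magnitudes.

Background (fish-free chamber) respiration is subtracted on the slope
scale, before the conversion to MO2, because it is measured on the same
%-saturation scale in the same chamber.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .config import AnalysisParams, CycleSchedule, RespirometerSpec

logger = logging.getLogger(__name__)

PHASE_CLOSED = "closed"
PHASE_FLUSH = "flush"
PHASE_BACKGROUND = "background"


class RespirometryError(ValueError):
    """Raised when a trace cannot be analysed."""


@dataclass
class O2Trace:
    """Timestamped % air-saturation record for one respirometer.

    ``data`` has columns ``time_s`` (strictly increasing),
    ``o2_percent_sat`` (within [0, 110]) and ``phase`` (one of
    ``closed``/``flush``/``background``).
    """

    fish_id: str
    test_temperature: float
    data: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"time_s", "o2_percent_sat", "phase"}
        missing = required - set(self.data.columns)
        if missing:
            raise RespirometryError(f"trace missing columns {sorted(missing)}")
        t = self.data["time_s"].to_numpy(float)
        bad = np.nonzero(np.diff(t) <= 0)[0]
        if bad.size:
            raise RespirometryError(
                f"time not strictly increasing at row {int(bad[0]) + 1}"
            )
        o2 = self.data["o2_percent_sat"].to_numpy(float)
        if np.any(o2 < 0) or np.any(o2 > 110):
            raise RespirometryError("o2_percent_sat outside [0, 110]")

    @property
    def times(self) -> np.ndarray:
        return self.data["time_s"].to_numpy(float)

    @property
    def o2(self) -> np.ndarray:
        return self.data["o2_percent_sat"].to_numpy(float)

    @property
    def phases(self) -> np.ndarray:
        return self.data["phase"].to_numpy()


@dataclass(frozen=True)
class SlopeRecord:
    """One fitted O2-decline slope (magnitude, % air sat h^-1)."""

    window_start: float
    window_end: float
    slope: float
    source: str
    n_samples: int = 0
    clamped: bool = False

    def __post_init__(self) -> None:
        if self.window_end <= self.window_start:
            raise RespirometryError("window_end must exceed window_start")
        if self.slope < 0:
            raise RespirometryError("slope records store magnitudes (>= 0)")

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.window_start + self.window_end)


@dataclass(frozen=True)
class MO2Sample:
    """One mass-specific oxygen consumption value (mg O2 h^-1 kg^-1)."""

    time_mid: float
    mo2: float
    source: str
    flagged: bool = False


@dataclass
class MetabolicSummary:
    """Per-fish metabolic phenotype.

    ``aas = mmr - smr`` exactly; ``epoc`` in mg O2 kg^-1;
    ``recovery_time`` in hours post-MMR.
    """

    fish_id: str
    smr: float
    mmr: float
    aas: float
    epoc: float
    recovery_time: float
    recovered: bool
    mmr_window_start: float
    n_smr_slopes_used: int
    alpha: float = float("nan")
    alpha_source: str = "config"


def oxygen_solubility(temperature_c: float, salinity: float = 0.0) -> float:
    """Dissolved O2 at 100% air saturation (mg O2 L^-1).

    Benson & Krause (1984) equilibrium fit, with the standard salinity
    correction, valid for 0-40 degC and salinities to ~40.  Divide by 100
    to obtain alpha in mg O2 L^-1 (% air sat)^-1.
    """
    t = temperature_c + 273.15
    ln_do = (
        -139.34411
        + 1.575701e5 / t
        - 6.642308e7 / t**2
        + 1.2438e10 / t**3
        - 8.621949e11 / t**4
    )
    ln_do -= salinity * (0.017674 - 10.754 / t + 2140.7 / t**2)
    return math.exp(ln_do)


def alpha_for(temperature_c: float, salinity: float = 32.0) -> float:
    """Oxygen solubility per % air saturation (mg O2 L^-1 %sat^-1)."""
    return oxygen_solubility(temperature_c, salinity) / 100.0


def fit_slope(times_s: np.ndarray, o2: np.ndarray, source: str) -> SlopeRecord:
    """Least-squares O2 slope over a window; magnitude, % air sat h^-1.

    A (non-physical) rising fit is clamped to slope 0 and flagged.
    """
    times_s = np.asarray(times_s, float)
    o2 = np.asarray(o2, float)
    if times_s.size < 2:
        raise RespirometryError("need >= 2 samples to fit a slope")
    coef = np.polyfit(times_s, o2, 1)
    per_hour = -coef[0] * 3600.0
    clamped = per_hour < 0
    return SlopeRecord(
        window_start=float(times_s[0]),
        window_end=float(times_s[-1]),
        slope=max(per_hour, 0.0),
        source=source,
        n_samples=int(times_s.size),
        clamped=bool(clamped),
    )


def compute_mo2(slope: SlopeRecord, spec: RespirometerSpec) -> MO2Sample:
    """Convert a slope magnitude to mass-specific oxygen consumption."""
    if spec.effective_volume <= 0:
        raise RespirometryError("effective respirometer volume must be > 0")
    mo2 = slope.slope * spec.effective_volume * spec.alpha / spec.mass
    return MO2Sample(
        time_mid=slope.midpoint,
        mo2=mo2,
        source=slope.source,
        flagged=slope.clamped,
    )


def mean_background_slope(background: Sequence[SlopeRecord]) -> float:
    """Mean fish-free chamber O2 slope (% air sat h^-1)."""
    if not background:
        raise RespirometryError("at least one background cycle is required")
    return float(np.mean([rec.slope for rec in background]))


def correct_background(
    records: Sequence[SlopeRecord], background: Sequence[SlopeRecord]
) -> list[SlopeRecord]:
    """Subtract the mean background slope from each fish slope.

    Corrected slopes that would go negative are clamped at 0 and flagged
    (they are later excluded from the SMR pool).
    """
    bg = mean_background_slope(background)
    out = []
    for rec in records:
        corrected = rec.slope - bg
        clamp = corrected < 0
        if clamp:
            logger.warning(
                "slope at %.0f-%.0f s below background (%.3g < %.3g); "
                "clamped to 0",
                rec.window_start,
                rec.window_end,
                rec.slope,
                bg,
            )
        out.append(
            SlopeRecord(
                window_start=rec.window_start,
                window_end=rec.window_end,
                slope=max(corrected, 0.0),
                source=rec.source,
                n_samples=rec.n_samples,
                clamped=rec.clamped or clamp,
            )
        )
    return out


def _phase_segments(trace: O2Trace, phase: str) -> list[tuple[int, int]]:
    """Contiguous index runs [i, j) of a given phase label."""
    mask = trace.phases == phase
    if not mask.any():
        return []
    edges = np.diff(mask.astype(int))
    starts = list(np.nonzero(edges == 1)[0] + 1)
    ends = list(np.nonzero(edges == -1)[0] + 1)
    if mask[0]:
        starts.insert(0, 0)
    if mask[-1]:
        ends.append(mask.size)
    return list(zip(starts, ends))


def segment_cycles(
    trace: O2Trace,
    schedule: CycleSchedule,
    phase: str = PHASE_CLOSED,
) -> list[SlopeRecord]:
    """One whole-cycle slope per closed (or background) phase.

    Each slope is fitted over the trimmed window
    ``[cycle_start + leading_trim, cycle_start + closed - trailing_trim]``;
    cycles whose trimmed window holds fewer than 2 samples are skipped
    with a warning.
    """
    source = "whole_cycle" if phase == PHASE_CLOSED else PHASE_BACKGROUND
    times, o2 = trace.times, trace.o2
    records = []
    for i, j in _phase_segments(trace, phase):
        t0 = times[i]
        lo = t0 + schedule.leading_trim
        hi = t0 + schedule.closed_duration - schedule.trailing_trim
        sel = (times >= lo) & (times <= hi)
        sel[:i] = False
        sel[j:] = False
        if sel.sum() < 2:
            logger.warning(
                "cycle starting at %.0f s: trimmed window has <2 samples; "
                "skipped",
                t0,
            )
            continue
        records.append(fit_slope(times[sel], o2[sel], source))
    return records


def find_mmr(
    trace: O2Trace,
    spec: RespirometerSpec,
    schedule: CycleSchedule,
    params: AnalysisParams | None = None,
    background: Sequence[SlopeRecord] | None = None,
) -> tuple[MO2Sample, SlopeRecord]:
    """Maximum metabolic rate from a sliding-window slope search.

    Candidate windows are all ``mmr_window_s`` spans whose start falls at
    0, ``mmr_step_s``, 2*``mmr_step_s``, ... of *accumulated closed-phase
    time* within the first ``mmr_search_s`` of closed time; windows never
    span a flush (slopes are undefined across a re-oxygenation).  MMR is
    the maximum background-corrected window slope converted to MO2;
    the earliest window wins ties.
    """
    params = params or AnalysisParams()
    times, o2 = trace.times, trace.o2
    segments = _phase_segments(trace, PHASE_CLOSED)
    if not segments:
        raise RespirometryError("trace has no closed phases")

    window, step, horizon = (
        params.mmr_window_s,
        params.mmr_step_s,
        params.mmr_search_s,
    )
    best: SlopeRecord | None = None
    offset = 0.0  # accumulated closed time at current segment start
    for i, j in segments:
        if offset >= horizon:
            break
        seg_start = times[i]
        # nominal closed extent runs to the first flush sample
        seg_len = (times[j] if j < times.size else times[j - 1]) - seg_start
        c = math.ceil(offset / step) * step  # first grid point in segment
        while c + window <= min(offset + seg_len, horizon) + 1e-9:
            lo = seg_start + (c - offset)
            hi = lo + window
            sel = (times >= lo - 1e-9) & (times <= hi + 1e-9)
            sel[:i] = False
            sel[j:] = False
            if sel.sum() >= 2:
                rec = fit_slope(times[sel], o2[sel], "mmr_window")
                # earliest window wins ties (to within fit round-off)
                if best is None or rec.slope > best.slope * (1 + 1e-9) + 1e-12:
                    best = rec
            c += step
        offset += seg_len
    if best is None:
        raise RespirometryError(
            "no complete MMR window within the closed-time search horizon"
        )
    if background:
        best = correct_background([best], background)[0]
    return compute_mo2(best, spec), best


def estimate_smr(values: Sequence[float]) -> tuple[float, int]:
    """SMR as the mean of the lowest-quantile whole-cycle MO2 values.

    Takes the lowest 10% of values (count ``ceil(0.10 * n)``), computes
    their mean and sample SD, excludes members outside mean +/- 2 SD in a
    single pass, and returns the mean of the survivors together with the
    survivor count.  With fewer than 10 values, all values form the pool
    (logged).
    """
    values = np.asarray(list(values), float)
    if values.size == 0:
        raise RespirometryError("cannot estimate SMR from an empty series")
    if values.size < 10:
        logger.warning(
            "only %d whole-cycle values; SMR pool uses all of them",
            values.size,
        )
    k = max(1, math.ceil(0.10 * values.size))
    pool = np.sort(values)[:k]
    mean = pool.mean()
    sd = pool.std(ddof=1) if pool.size > 1 else 0.0
    keep = np.abs(pool - mean) <= 2.0 * sd if pool.size > 1 else np.ones(1, bool)
    if not keep.any():  # degenerate: keep everything rather than nothing
        keep[:] = True
    survivors = pool[keep]
    return float(survivors.mean()), int(survivors.size)


def build_recovery_series(
    trace: O2Trace,
    spec: RespirometerSpec,
    schedule: CycleSchedule,
    mmr_time: float,
    params: AnalysisParams | None = None,
    background: Sequence[SlopeRecord] | None = None,
) -> list[MO2Sample]:
    """Post-MMR MO2 recovery series: fine 60-s windows, then coarse.

    For the first ``fine_horizon_s`` after the MMR window midpoint, one
    MO2 value per sequential ``fine_window_s`` sub-window inside each
    trimmed closed phase; afterwards, one ``coarse_window_s`` window at
    the start of a trimmed closed phase roughly every
    ``coarse_spacing_s`` until the fish is removed.
    """
    params = params or AnalysisParams()
    times, o2 = trace.times, trace.o2
    records: list[SlopeRecord] = []
    fine_end = mmr_time + params.fine_horizon_s
    last_coarse_start = None

    for i, j in _phase_segments(trace, PHASE_CLOSED):
        t0 = times[i]
        lo = t0 + schedule.leading_trim
        hi = t0 + schedule.closed_duration - schedule.trailing_trim
        hi = min(hi, times[j - 1])
        if hi <= lo:
            continue
        if lo <= fine_end:
            # sequential fine sub-windows within the trimmed span
            start = lo
            while start + params.fine_window_s <= hi + 1e-9:
                end = start + params.fine_window_s
                if start > mmr_time and start <= fine_end:
                    sel = (times >= start - 1e-9) & (times <= end + 1e-9)
                    sel[:i] = False
                    sel[j:] = False
                    if sel.sum() >= 2:
                        records.append(
                            fit_slope(times[sel], o2[sel], "fine_60s")
                        )
                start = end
        elif (
            last_coarse_start is None
            and lo > fine_end
            or last_coarse_start is not None
            and lo - last_coarse_start >= params.coarse_spacing_s - 1e-9
        ):
            end = min(lo + params.coarse_window_s, hi)
            sel = (times >= lo - 1e-9) & (times <= end + 1e-9)
            sel[:i] = False
            sel[j:] = False
            if sel.sum() >= 2:
                records.append(fit_slope(times[sel], o2[sel], "coarse_3min"))
                last_coarse_start = lo

    if background:
        records = correct_background(records, background)
    return [compute_mo2(rec, spec) for rec in records]


def find_recovery_time(
    series: Sequence[MO2Sample],
    smr: float,
    mmr_time: float,
    params: AnalysisParams | None = None,
    trace_end: float | None = None,
) -> tuple[float, bool]:
    """Time (h post-MMR) at which metabolic rate has returned to SMR.

    Recovery is the time of the FIRST sample of the earliest run of
    ``recovery_run_length`` consecutive samples all within
    SMR * (1 +/- recovery_band).  If no such run exists the trace end is
    returned with ``recovered=False``.
    """
    params = params or AnalysisParams()
    run = params.recovery_run_length
    lo, hi = smr * (1 - params.recovery_band), smr * (1 + params.recovery_band)
    samples = sorted(series, key=lambda s: s.time_mid)
    inside = [lo <= s.mo2 <= hi for s in samples]
    for i in range(len(samples) - run + 1):
        if all(inside[i : i + run]):
            return (samples[i].time_mid - mmr_time) / 3600.0, True
    end = trace_end if trace_end is not None else (
        samples[-1].time_mid if samples else mmr_time
    )
    return (end - mmr_time) / 3600.0, False


def compute_epoc(
    series: Sequence[MO2Sample],
    smr: float,
    mmr_sample: MO2Sample,
    recovery_time_h: float,
) -> float:
    """Excess post-exercise oxygen consumption (mg O2 kg^-1).

    Trapezoidal integral of max(MO2(t) - SMR, 0) from the time of MMR to
    the recovery time, on the irregular recovery-sample grid with the
    MMR point prepended.
    """
    if not series:
        raise RespirometryError("cannot integrate EPOC over an empty series")
    mmr_time = mmr_sample.time_mid
    recovery_abs = mmr_time + recovery_time_h * 3600.0
    pts = [(mmr_time, mmr_sample.mo2)] + [
        (s.time_mid, s.mo2)
        for s in sorted(series, key=lambda s: s.time_mid)
        if mmr_time < s.time_mid <= recovery_abs + 1e-9
    ]
    t = np.array([p[0] for p in pts]) / 3600.0  # hours
    excess = np.clip(np.array([p[1] for p in pts]) - smr, 0.0, None)
    return float(np.trapezoid(excess, t))


def align_cohort_timepoints(
    series_by_fish: dict[str, Sequence[MO2Sample]],
    tolerance_s: float = 30.0,
    window: tuple[float, float] | None = None,
) -> dict[str, list[MO2Sample]]:
    """Keep only fine-series time points present for every fish in a trial.

    Fish enter their respirometers at different moments within a closed
    cycle, so some fine time points exist for one fish but fall in
    another fish's flush.  Within the fine window (optionally restricted
    to ``window = (start, end)`` in absolute seconds), a time point is
    retained only if every fish has a sample within ``tolerance_s`` of
    it; coarse samples are left untouched.
    """
    if len(series_by_fish) < 2:
        return {k: list(v) for k, v in series_by_fish.items()}

    def in_window(s: MO2Sample) -> bool:
        if s.source != "fine_60s":
            return False
        if window is None:
            return True
        return window[0] <= s.time_mid <= window[1]

    fine_times = {
        fid: np.array(sorted(s.time_mid for s in series if in_window(s)))
        for fid, series in series_by_fish.items()
    }

    def supported(t: float) -> bool:
        return all(
            times.size > 0 and np.min(np.abs(times - t)) <= tolerance_s
            for times in fine_times.values()
        )

    out: dict[str, list[MO2Sample]] = {}
    for fid, series in series_by_fish.items():
        kept = [
            s
            for s in series
            if not in_window(s) or supported(s.time_mid)
        ]
        dropped = len(list(series)) - len(kept)
        if dropped:
            logger.info("%s: dropped %d unshared fine time points", fid, dropped)
        out[fid] = kept
    return out


def summarize_fish(
    trace: O2Trace,
    spec: RespirometerSpec,
    schedule: CycleSchedule,
    params: AnalysisParams | None = None,
) -> tuple[MetabolicSummary, dict]:
    """Full per-fish respirometry analysis.

    Returns the metabolic summary and a detail dict with the recovery
    series, whole-cycle samples and a slope audit table (every window,
    slope, inclusion flag).
    """
    params = params or AnalysisParams()
    background = segment_cycles(trace, schedule, phase=PHASE_BACKGROUND)
    if not background:
        raise RespirometryError(
            f"{trace.fish_id}: no background cycles in trace"
        )

    mmr_sample, mmr_window = find_mmr(
        trace, spec, schedule, params, background=background
    )
    mmr_time = mmr_sample.time_mid

    whole = segment_cycles(trace, schedule)
    whole_corr = correct_background(whole, background)
    # exclude the cycle containing the MMR window from the SMR pool so a
    # post-exercise peak cannot contaminate the lowest-10% subset
    smr_pool, whole_samples = [], []
    for rec in whole_corr:
        sample = compute_mo2(rec, spec)
        whole_samples.append(sample)
        contains_mmr = rec.window_start - schedule.leading_trim <= mmr_time <= (
            rec.window_start - schedule.leading_trim + schedule.closed_duration
        )
        if not contains_mmr and not sample.flagged:
            smr_pool.append(sample.mo2)
    smr, n_used = estimate_smr(smr_pool)

    series = build_recovery_series(
        trace, spec, schedule, mmr_time, params, background=background
    )
    recovery_time, recovered = find_recovery_time(
        series, smr, mmr_time, params, trace_end=float(trace.times[-1])
    )
    epoc = compute_epoc(series, smr, mmr_sample, recovery_time)

    summary = MetabolicSummary(
        fish_id=trace.fish_id,
        smr=smr,
        mmr=mmr_sample.mo2,
        aas=mmr_sample.mo2 - smr,
        epoc=epoc,
        recovery_time=recovery_time,
        recovered=recovered,
        mmr_window_start=mmr_window.window_start,
        n_smr_slopes_used=n_used,
        alpha=spec.alpha,
        alpha_source=spec.alpha_source,
    )
    audit = pd.DataFrame(
        {
            "window_start": [r.window_start for r in whole_corr + background],
            "window_end": [r.window_end for r in whole_corr + background],
            "slope": [r.slope for r in whole_corr + background],
            "source": [r.source for r in whole_corr + background],
            "clamped": [r.clamped for r in whole_corr + background],
        }
    )
    detail = {
        "recovery_series": series,
        "whole_cycle_samples": whole_samples,
        "slope_audit": audit,
        "mmr_sample": mmr_sample,
        "background_slope": mean_background_slope(background),
    }
    return summary, detail
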