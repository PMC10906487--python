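"""Synthetic study generator with known ground truth.

Emulates the experimental design the pipeline consumes: acute exposure
(3 degC h^-1) of 14 degC-acclimated fish to 26-2 degC, and multi-week
acclimation to 14-2 degC, bracketing a winter dormancy threshold
temperature (WDTT) near 8 degC.

Components:

* :func:`simulate_o2_trace` — intermittent-closed respirometry record:
  instantaneous re-oxygenation to 100% saturation during flushes, linear
  within-cycle O2 decline set by a true mass-specific oxygen consumption
  that relaxes mono-exponentially from MMR to SMR after exhaustive
  exercise, constant background (fish-free) respiration, pointwise
  Gaussian probe noise, and three trailing fish-free background cycles.
  The mono-exponential recovery gives closed-form ground truth for EPOC
  and recovery time.
* :func:`simulate_cstart_trajectory` — straight-line constant-
  acceleration burst paths sampled at the camera frame rate and
  converted to pixels, with optional tracking jitter.
* :func:`simulate_performance_dataset` — multi-temperature group means
  following a piecewise Q10 model (one Q10 above the WDTT, another
  below, with a compensation multiplier for acclimated groups below the
  WDTT), individuals drawn lognormally at a stated coefficient of
  variation.
* :func:`simulate_study` — every raw input of a full acute + acclimated
  study (respirometry traces, burst trajectories, chase trials),
  parameterised by per-metric reference values at 14 degC.

All randomness flows through explicit integer seeds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import AnalysisParams, CycleSchedule, RespirometerSpec
from .kinematics import TrackTrajectory
from .respirometry import (
    O2Trace,
    PHASE_BACKGROUND,
    PHASE_CLOSED,
    PHASE_FLUSH,
    alpha_for,
)


class SimulationError(ValueError):
    """Raised on invalid simulation parameters."""


# --------------------------------------------------------------------------
# respirometry traces


@dataclass
class RespirometrySimParams:
    """Ground-truth parameters of one simulated respirometry trial.

    Rates in mg O2 h^-1 kg^-1, ``recovery_tau`` in hours,
    ``background_rate`` in % air sat h^-1, ``noise_sd`` in % air sat.
    """

    true_smr: float
    true_mmr: float
    recovery_tau: float
    schedule: CycleSchedule
    spec: RespirometerSpec
    duration_h: float = 14.0
    background_rate: float = 1.0
    noise_sd: float = 0.05
    sample_period_s: float = 1.0
    recovery_band: float = 0.10
    seed: int = 0
    fish_id: str = "sim"
    test_temperature: float = 14.0

    def __post_init__(self) -> None:
        if not self.true_mmr >= self.true_smr > 0:
            raise SimulationError("need true_mmr >= true_smr > 0")
        if self.recovery_tau <= 0:
            raise SimulationError("recovery_tau must be > 0")
        if self.duration_h * 3600.0 < 3 * self.schedule.period:
            raise SimulationError("duration must cover >= 3 cycles")


def analytic_recovery_time(params: RespirometrySimParams) -> float:
    """Hours after trial start at which MO2(t) crosses SMR*(1+band)."""
    excess = params.true_mmr - params.true_smr
    threshold = params.recovery_band * params.true_smr
    if excess <= threshold:
        return 0.0
    return params.recovery_tau * math.log(excess / threshold)


def analytic_epoc(params: RespirometrySimParams) -> float:
    """Closed-form EPOC (mg O2 kg^-1) integrated to the recovery time.

    For MO2(t) = SMR + (MMR - SMR) exp(-t/tau), the excess above SMR
    integrated from 0 to t_r is (MMR - SMR) * tau * (1 - exp(-t_r/tau)).
    """
    t_r = analytic_recovery_time(params)
    excess = params.true_mmr - params.true_smr
    return excess * params.recovery_tau * (1.0 - math.exp(-t_r / params.recovery_tau))


def simulate_o2_trace(
    params: RespirometrySimParams,
) -> tuple[O2Trace, dict[str, float]]:
    """Simulate one intermittent-closed respirometry trace.

    The fish period starts with a closed phase at time 0 (exercised fish
    enter the sealed chamber immediately post-chase); three fish-free
    background cycles follow removal, their closed phases labelled
    ``background``.
    """
    sched = params.schedule
    spec = params.spec
    dt = params.sample_period_s
    fish_end = params.duration_h * 3600.0
    total = fish_end + 3 * sched.period
    t = np.arange(0.0, total, dt)

    # per-fish decline rate in % sat per hour at MO2 = 1 mg O2/h/kg
    conv = spec.mass / (spec.effective_volume * spec.alpha)
    smr, excess, tau_s = (
        params.true_smr,
        params.true_mmr - params.true_smr,
        params.recovery_tau * 3600.0,
    )

    def mo2_integral(a: np.ndarray | float, b: np.ndarray | float) -> np.ndarray:
        """Integral of MO2(t) dt over [a, b] in mg O2 kg^-1 (t in s)."""
        a = np.asarray(a, float)
        b = np.asarray(b, float)
        return (
            smr * (b - a) + excess * tau_s * (np.exp(-a / tau_s) - np.exp(-b / tau_s))
        ) / 3600.0

    o2 = np.full(t.size, 100.0)
    phase = np.full(t.size, PHASE_FLUSH, dtype=object)
    cycle_starts = np.arange(0.0, total, sched.period)
    for start in cycle_starts:
        close_end = start + sched.closed_duration
        closed = (t >= start) & (t < close_end)
        if not closed.any():
            continue
        is_background = start >= fish_end
        phase[closed] = PHASE_BACKGROUND if is_background else PHASE_CLOSED
        tc = t[closed]
        drop = params.background_rate * (tc - start) / 3600.0
        if not is_background:
            drop = drop + conv * mo2_integral(start, tc)
        o2[closed] = 100.0 - drop

    if params.noise_sd > 0:
        rng = np.random.default_rng(params.seed)
        o2 = o2 + rng.normal(0.0, params.noise_sd, size=o2.size)
    o2 = np.clip(o2, 0.0, 110.0)

    trace = O2Trace(
        fish_id=params.fish_id,
        test_temperature=params.test_temperature,
        data=pd.DataFrame(
            {"time_s": t, "o2_percent_sat": o2, "phase": phase}
        ),
    )
    truth = {
        "smr": params.true_smr,
        "mmr": params.true_mmr,
        "recovery_tau_h": params.recovery_tau,
        "recovery_time_h": analytic_recovery_time(params),
        "epoc": analytic_epoc(params),
        "background_rate": params.background_rate,
    }
    return trace, truth


# --------------------------------------------------------------------------
# burst trajectories


def simulate_cstart_trajectory(
    v0_cms: float,
    accel_ms2: float,
    fps: float = 240.0,
    duration_s: float = 0.075,
    pixels_per_cm: float = 10.0,
    noise_px: float = 0.0,
    seed: int = 0,
    heading_deg: float = 30.0,
    origin_px: tuple[float, float] = (400.0, 300.0),
    fish_id: str = "sim",
    attempt_id: str = "a1",
    stimulus_type: str = "tube_drop",
    pre_contact_response: bool = True,
) -> tuple[TrackTrajectory, dict[str, float]]:
    """Straight constant-acceleration burst path in pixel coordinates.

    Ground truth: Umax = v0 + 100 * accel * duration (cm s^-1) and
    Amax = accel (m s^-2).
    """
    if fps <= 0:
        raise SimulationError("fps must be > 0")
    if duration_s < 0.075:
        raise SimulationError("duration must cover the 75-ms analysis window")
    n = int(round(duration_s * fps)) + 1
    t = np.arange(n) / fps
    accel_cms2 = 100.0 * accel_ms2
    path_cm = v0_cms * t + 0.5 * accel_cms2 * t**2
    theta = math.radians(heading_deg)
    x_px = origin_px[0] + path_cm * math.cos(theta) * pixels_per_cm
    y_px = origin_px[1] + path_cm * math.sin(theta) * pixels_per_cm
    if noise_px > 0:
        rng = np.random.default_rng(seed)
        x_px = x_px + rng.normal(0.0, noise_px, n)
        y_px = y_px + rng.normal(0.0, noise_px, n)
    traj = TrackTrajectory(
        fish_id=fish_id,
        attempt_id=attempt_id,
        stimulus_type=stimulus_type,
        pre_contact_response=pre_contact_response,
        time_s=t,
        x_px=x_px,
        y_px=y_px,
        fps=fps,
        pixels_per_cm=pixels_per_cm,
        cstart_onset=0.0,
    )
    truth = {
        "u_max_cms": v0_cms + accel_cms2 * duration_s,
        "a_max_ms2": abs(accel_ms2),
    }
    return traj, truth


# --------------------------------------------------------------------------
# performance datasets


@dataclass
class PerformanceSimParams:
    """Piecewise-Q10 model of one performance metric across temperature.

    Group means follow ``R_ref * q10_above ** ((T - 14)/10)`` at and
    above the WDTT and ``R(WDTT) * q10_below ** ((T - WDTT)/10)`` below
    it; acclimated groups below the WDTT are multiplied by
    ``compensation_factor`` (>1 models compensatory plasticity).
    Individuals are lognormal with the stated coefficient of variation.
    """

    temperatures: tuple[float, ...] = (26, 23, 20, 17, 14, 11, 8, 5, 2)
    acclimated_temperatures: tuple[float, ...] | None = None
    wdtt: float = 8.0
    q10_above: float = 2.0
    q10_below: float = 5.0
    compensation_factor: float = 1.7
    reference_rate: float = 100.0
    reference_temperature: float = 14.0
    cv: float = 0.15
    n_per_group: int = 12
    metric: str = "performance"
    is_rate: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.q10_above <= 0 or self.q10_below <= 0:
            raise SimulationError("Q10 parameters must be > 0")
        if not 0 <= self.cv < 1:
            raise SimulationError("cv must be in [0, 1)")
        if self.n_per_group < 2:
            raise SimulationError("n_per_group must be >= 2")
        if self.acclimated_temperatures is None:
            self.acclimated_temperatures = tuple(
                t for t in self.temperatures if t <= self.reference_temperature
            )


def piecewise_mean(
    temperature: float,
    treatment: str,
    params: PerformanceSimParams,
) -> float:
    """Expected group mean of the metric at one temperature/treatment."""
    p = params
    if temperature >= p.wdtt:
        mean = p.reference_rate * p.q10_above ** (
            (temperature - p.reference_temperature) / 10.0
        )
    else:
        at_wdtt = p.reference_rate * p.q10_above ** (
            (p.wdtt - p.reference_temperature) / 10.0
        )
        mean = at_wdtt * p.q10_below ** ((temperature - p.wdtt) / 10.0)
        if treatment == "acclimated":
            mean *= p.compensation_factor
    return mean


def _lognormal_group(
    rng: np.random.Generator, mean: float, cv: float, n: int
) -> np.ndarray:
    """Lognormal sample with the given arithmetic mean and CV."""
    if cv == 0 or mean == 0:
        return np.full(n, mean)
    sigma2 = math.log(1.0 + cv**2)
    mu = math.log(mean) - sigma2 / 2.0
    return rng.lognormal(mu, math.sqrt(sigma2), n)


def simulate_performance_dataset(
    params: PerformanceSimParams,
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Tidy performance table for one metric, plus true parameters.

    Acute groups exist at every listed temperature; acclimated groups
    only at ``acclimated_temperatures`` (no acclimation above the
    reference temperature by design).
    """
    rng = np.random.default_rng(params.seed)
    rows = []
    for treatment, temps in (
        ("acute", params.temperatures),
        ("acclimated", params.acclimated_temperatures),
    ):
        for temp in temps:
            mean = piecewise_mean(temp, treatment, params)
            values = _lognormal_group(rng, mean, params.cv, params.n_per_group)
            for i, v in enumerate(values):
                rows.append(
                    {
                        "fish_id": f"{treatment[:3]}{temp:g}_{i:02d}",
                        "metric": params.metric,
                        "value": float(v),
                        "temperature": float(temp),
                        "treatment": treatment,
                        "is_rate": params.is_rate,
                    }
                )
    truth = {
        "q10_above": params.q10_above,
        "q10_below": params.q10_below,
        "wdtt": params.wdtt,
        "compensation_factor": params.compensation_factor,
        "reference_rate": params.reference_rate,
    }
    return pd.DataFrame(rows), truth


# --------------------------------------------------------------------------
# full-study generator


@dataclass
class MetricModel:
    """Reference value at 14 degC plus piecewise-Q10 shape of one metric."""

    reference: float
    q10_above: float
    q10_below: float
    compensation: float
    cv: float = 0.15


#: Default per-metric models for the full-study generator.  Reference
#: values are plausible for a small temperate wrasse at 14 degC; the
#: shape parameters reproduce the qualitative study contrast (passive
#: sensitivity above the dormancy threshold, a steep acute constraint
#: below it, partial compensation after cold acclimation) rather than
#: any measured animal.  "responsiveness" is a response probability (its
#: q10 fields are effective steepness parameters for the same piecewise
#: machinery); "chase_duration" is a non-rate endurance time.
DEFAULT_METRIC_MODELS: dict[str, MetricModel] = {
    "umax": MetricModel(50.0, 1.6, 2.5, 1.36, cv=0.15),  # cm/s
    "uchase": MetricModel(2.5, 1.1, 3.0, 1.17, cv=0.15),  # BL/s
    "chase_duration": MetricModel(300.0, 1.5, 3.5, 1.5, cv=0.20),  # s
    "smr": MetricModel(60.0, 2.5, 2.5, 1.0, cv=0.10),  # mg O2/h/kg
    "mmr": MetricModel(250.0, 1.9, 3.9, 1.49, cv=0.10),  # mg O2/h/kg
    "responsiveness": MetricModel(0.85, 1.0, 10.1, 1.31, cv=0.0),  # prob
}


@dataclass
class StudyDesign:
    """Sample sizes, temperatures and instrument constants of one study."""

    acute_temperatures: tuple[float, ...] = (26, 23, 20, 17, 14, 11, 8, 5, 2)
    acclimated_temperatures: tuple[float, ...] = (14, 11, 8, 5, 2)
    n_kinematics: int = 12
    n_respirometry: int = 8
    n_attempts: int = 5
    recovery_tau_h: float = 1.0
    trace_duration_h: float = 14.0
    sample_period_s: float = 1.0
    noise_sd: float = 0.05
    background_rate: float = 1.0
    loop_volume: float = 0.160
    salinity: float = 32.0
    fps: float = 240.0
    pixels_per_cm: float = 10.0
    track_noise_px: float = 0.2
    mean_body_length_cm: float = 8.8
    metric_models: dict[str, MetricModel] = field(
        default_factory=lambda: dict(DEFAULT_METRIC_MODELS)
    )

    def metric_mean(self, metric: str, temperature: float, treatment: str) -> float:
        m = self.metric_models[metric]
        p = PerformanceSimParams(
            temperatures=(temperature,),
            wdtt=8.0,
            q10_above=m.q10_above,
            q10_below=m.q10_below,
            compensation_factor=m.compensation,
            reference_rate=m.reference,
            cv=m.cv,
            metric=metric,
        )
        return piecewise_mean(temperature, treatment, p)


def _groups(design: StudyDesign):
    for t in design.acute_temperatures:
        yield "acute", float(t)
    for t in design.acclimated_temperatures:
        yield "acclimated", float(t)


def _body(rng: np.random.Generator, design: StudyDesign) -> tuple[float, float]:
    """(body_length_cm, mass_kg) with mass from a cubic condition factor."""
    bl = float(_lognormal_group(rng, design.mean_body_length_cm, 0.08, 1)[0])
    mass = 3.67e-5 * bl**3
    return bl, mass


@dataclass
class SyntheticStudy:
    """Raw inputs plus ground truth for one simulated study."""

    traces: list[O2Trace]
    fish_meta: pd.DataFrame  # fish_id, experiment, temperature, treatment, ...
    trajectories: dict[str, list[TrackTrajectory]]
    swim_trials: pd.DataFrame
    chase_records: pd.DataFrame  # per respirometry fish
    truth: pd.DataFrame


def simulate_study(
    design: StudyDesign,
    schedules: dict[float, CycleSchedule],
    seed: int = 0,
) -> SyntheticStudy:
    """Generate every raw input of a full acute + acclimated study.

    Burst-experiment fish get ``n_attempts`` startle attempts each (the
    response probability and per-attempt peak speed follow the metric
    models; failed tube-drop attempts yield no usable track, failed
    forceps attempts yield a contact-triggered track that counts as a
    non-response).  Respirometry-experiment fish get a chase-duration
    record and a full O2 trace.
    """
    rng = np.random.default_rng(seed)
    traces: list[O2Trace] = []
    trajectories: dict[str, list[TrackTrajectory]] = {}
    meta_rows, swim_rows, chase_rows, truth_rows = [], [], [], []

    for treatment, temp in _groups(design):
        alpha = alpha_for(temp, design.salinity)
        schedule = schedules[temp]
        p_respond = min(
            design.metric_mean("responsiveness", temp, treatment), 1.0
        )
        umax_mean = design.metric_mean("umax", temp, treatment)
        uchase_mean = design.metric_mean("uchase", temp, treatment)
        chase_mean = design.metric_mean("chase_duration", temp, treatment)
        smr_mean = design.metric_mean("smr", temp, treatment)
        mmr_mean = design.metric_mean("mmr", temp, treatment)

        # experiment 1: burst escape + annular chase
        for i in range(design.n_kinematics):
            fid = f"e1_{treatment[:3]}{temp:g}_{i:02d}"
            bl, mass = _body(rng, design)
            attempts = []
            for a in range(design.n_attempts):
                stimulus = "tube_drop" if a < 3 else "forceps"
                responded = bool(rng.random() < p_respond)
                if not responded and stimulus == "tube_drop":
                    continue  # no C-start, no usable track
                target = float(
                    _lognormal_group(
                        rng, umax_mean, design.metric_models["umax"].cv, 1
                    )[0]
                )
                v0 = 0.25 * target
                accel = (target - v0) / 0.075 / 100.0  # m/s^2
                traj, _ = simulate_cstart_trajectory(
                    v0_cms=v0,
                    accel_ms2=accel,
                    fps=design.fps,
                    duration_s=0.09,
                    pixels_per_cm=design.pixels_per_cm,
                    noise_px=design.track_noise_px,
                    seed=int(rng.integers(2**31)),
                    heading_deg=float(rng.uniform(0, 360)),
                    fish_id=fid,
                    attempt_id=f"{fid}_a{a}",
                    stimulus_type=stimulus,
                    pre_contact_response=responded,
                )
                attempts.append(traj)
            trajectories[fid] = attempts
            u_chase = float(
                _lognormal_group(
                    rng, uchase_mean, design.metric_models["uchase"].cv, 1
                )[0]
            )
            duration = float(
                _lognormal_group(
                    rng,
                    chase_mean,
                    design.metric_models["chase_duration"].cv,
                    1,
                )[0]
            )
            laps = u_chase * bl * duration / 176.0
            swim_rows.append(
                {
                    "fish_id": fid,
                    "temperature": temp,
                    "treatment": treatment,
                    "laps": laps,
                    "chase_duration_s": duration,
                    "body_length_cm": bl,
                }
            )
            meta_rows.append(
                {
                    "fish_id": fid,
                    "experiment": "burst",
                    "temperature": temp,
                    "treatment": treatment,
                    "body_length_cm": bl,
                    "body_mass_kg": mass,
                    "n_attempts": design.n_attempts,
                }
            )

        # experiment 2A: exhaustive chase + respirometry
        for i in range(design.n_respirometry):
            fid = f"e2_{treatment[:3]}{temp:g}_{i:02d}"
            bl, mass = _body(rng, design)
            smr = float(_lognormal_group(rng, smr_mean, 0.10, 1)[0])
            mmr = max(
                float(_lognormal_group(rng, mmr_mean, 0.10, 1)[0]), 1.5 * smr
            )
            duration = float(
                _lognormal_group(
                    rng,
                    chase_mean,
                    design.metric_models["chase_duration"].cv,
                    1,
                )[0]
            )
            spec = RespirometerSpec(
                loop_volume=design.loop_volume,
                fish_volume=mass / 1.0,  # ~neutral buoyancy, 1 kg/L
                alpha=alpha,
                mass=mass,
                alpha_source="computed (Benson-Krause, salinity-corrected)",
            )
            params = RespirometrySimParams(
                true_smr=smr,
                true_mmr=mmr,
                recovery_tau=design.recovery_tau_h,
                schedule=schedule,
                spec=spec,
                duration_h=design.trace_duration_h,
                background_rate=design.background_rate,
                noise_sd=design.noise_sd,
                sample_period_s=design.sample_period_s,
                seed=int(rng.integers(2**31)),
                fish_id=fid,
                test_temperature=temp,
            )
            trace, truth = simulate_o2_trace(params)
            traces.append(trace)
            chase_rows.append(
                {
                    "fish_id": fid,
                    "temperature": temp,
                    "treatment": treatment,
                    "chase_duration_s": duration,
                }
            )
            meta_rows.append(
                {
                    "fish_id": fid,
                    "experiment": "respirometry",
                    "temperature": temp,
                    "treatment": treatment,
                    "body_length_cm": bl,
                    "body_mass_kg": mass,
                    "loop_volume_l": spec.loop_volume,
                    "fish_volume_l": spec.fish_volume,
                    "alpha": alpha,
                }
            )
            truth_rows.append({"fish_id": fid, **truth})

    return SyntheticStudy(
        traces=traces,
        fish_meta=pd.DataFrame(meta_rows),
        trajectories=trajectories,
        swim_trials=pd.DataFrame(swim_rows),
        chase_records=pd.DataFrame(chase_rows),
        truth=pd.DataFrame(truth_rows),
    )
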