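"""Shared domain records and pipeline configuration.

Conventions used throughout the package:

* time is in seconds from trial start (0-based), phase intervals are
  half-open ``[start, end)``;
* temperatures are in degrees Celsius everywhere (the temperature
  coefficient Q10 only ever uses Celsius differences);
* a respirometry cycle begins with the *closed* (sealed, O2-decline)
  phase and ends with the flush: exercised fish enter a sealed chamber
  immediately post-chase so the maximum-metabolic-rate window sits at
  the start of the record.

Configuration files are TOML.  Every analysis constant (window lengths,
quantiles, band widths, consecutive-sample rules) lives in
:class:`AnalysisParams` so tests can tighten or vary them.
"""

from __future__ import annotations

import tomllib
from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Any

TREATMENTS = ("acute", "acclimated")

#: Closed-phase duration (s) by test temperature (degC) for the
#: intermittent-closed respirometry protocol.  The closed period grows as
#: water cools because the slope of oxygen decline shrinks with metabolic
#: rate; the flush is 3 min everywhere except 2 min at the warmest
#: temperature.
DEFAULT_SCHEDULES: dict[float, tuple[float, float]] = {
    26.0: (120.0, 300.0),
    23.0: (180.0, 300.0),
    20.0: (180.0, 360.0),
    17.0: (180.0, 420.0),
    14.0: (180.0, 540.0),
    11.0: (180.0, 540.0),
    8.0: (180.0, 1020.0),
    5.0: (180.0, 1620.0),
    2.0: (180.0, 2520.0),
}


class ConfigError(ValueError):
    """Raised when a configuration file or record fails validation."""


@dataclass(frozen=True)
class FishRecord:
    """Identity and morphometrics of one experimental fish.

    ``body_mass`` is in kg (enters the oxygen-consumption equation),
    ``body_length`` in cm (used for body-length normalisation of swim
    speeds).
    """

    fish_id: str
    body_mass: float
    body_length: float
    treatment: str
    test_temperature: float
    acclimation_temperature: float

    def __post_init__(self) -> None:
        if self.body_mass <= 0:
            raise ConfigError(f"{self.fish_id}: body_mass must be > 0")
        if self.body_length <= 0:
            raise ConfigError(f"{self.fish_id}: body_length must be > 0")
        if self.treatment not in TREATMENTS:
            raise ConfigError(
                f"{self.fish_id}: treatment must be one of {TREATMENTS}, "
                f"got {self.treatment!r}"
            )
        if not 0.0 <= self.test_temperature <= 30.0:
            raise ConfigError(
                f"{self.fish_id}: test_temperature {self.test_temperature} "
                "outside [0, 30] degC"
            )


@dataclass(frozen=True)
class CycleSchedule:
    """Flush/closed timing of one intermittent-closed respirometry cycle.

    ``leading_trim``/``trailing_trim`` exclude the start and end of each
    closed phase from whole-cycle slope fits, to allow mixing
    equilibration after the flush and to avoid sampling the start of the
    next flush.
    """

    flush_duration: float
    closed_duration: float
    leading_trim: float = 120.0
    trailing_trim: float = 60.0

    def __post_init__(self) -> None:
        if self.flush_duration <= 0 or self.closed_duration <= 0:
            raise ConfigError("flush and closed durations must be > 0")
        if self.leading_trim < 0 or self.trailing_trim < 0:
            raise ConfigError("trims must be >= 0")
        if self.closed_duration <= self.leading_trim + self.trailing_trim:
            raise ConfigError(
                f"closed_duration ({self.closed_duration} s) must exceed "
                f"leading_trim + trailing_trim "
                f"({self.leading_trim + self.trailing_trim} s)"
            )

    @property
    def period(self) -> float:
        """Full cycle length (s): closed phase followed by flush."""
        return self.closed_duration + self.flush_duration


@dataclass(frozen=True)
class RespirometerSpec:
    """Geometry and calibration of one respirometer loop.

    ``alpha`` is the oxygen solubility of the water,
    mg O2 L^-1 (% air saturation)^-1, at the trial temperature and
    barometric pressure; its provenance (measured, tabulated or computed)
    should be carried in output metadata.
    """

    loop_volume: float  # L
    fish_volume: float  # L
    alpha: float  # mg O2 / L / % air sat
    mass: float  # kg
    alpha_source: str = "config"

    def __post_init__(self) -> None:
        if self.fish_volume < 0:
            raise ConfigError("fish_volume must be >= 0")
        if self.loop_volume <= self.fish_volume:
            raise ConfigError(
                f"loop_volume ({self.loop_volume} L) must exceed fish_volume "
                f"({self.fish_volume} L)"
            )
        if self.alpha <= 0:
            raise ConfigError("alpha must be > 0")
        if self.mass <= 0:
            raise ConfigError("mass must be > 0")

    @property
    def effective_volume(self) -> float:
        """Respirometer loop volume minus the fish volume (L)."""
        return self.loop_volume - self.fish_volume


@dataclass
class AnalysisParams:
    """Every tunable analysis constant, with protocol defaults.

    Defaults: 60-s maximum-metabolic-rate window searched in 30-s steps
    over the first 15 min of accumulated closed time; standard metabolic
    rate from the lowest 10% of whole-cycle values with a 2-SD outlier
    pass; recovery at the first of 3 consecutive values within +/-10% of
    SMR; a 4-h fine (60-s) recovery series then 3-min windows every
    45 min; 75-ms burst-kinematics window.
    """

    mmr_window_s: float = 60.0
    mmr_step_s: float = 30.0
    mmr_search_s: float = 900.0
    smr_quantile: float = 0.10
    smr_sd_limit: float = 2.0
    recovery_band: float = 0.10
    recovery_run_length: int = 3
    fine_window_s: float = 60.0
    fine_horizon_s: float = 4.0 * 3600.0
    coarse_window_s: float = 180.0
    coarse_spacing_s: float = 45.0 * 60.0
    cohort_tolerance_s: float = 30.0
    kinematics_window_ms: float = 75.0
    kinematics_smooth_frames: int = 0

    def __post_init__(self) -> None:
        positive = (
            "mmr_window_s",
            "mmr_step_s",
            "mmr_search_s",
            "fine_window_s",
            "fine_horizon_s",
            "coarse_window_s",
            "coarse_spacing_s",
            "kinematics_window_ms",
        )
        for name in positive:
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be > 0")
        if not 0 < self.smr_quantile <= 1:
            raise ConfigError("smr_quantile must be in (0, 1]")
        if self.recovery_run_length < 1:
            raise ConfigError("recovery_run_length must be >= 1")
        if not 0 < self.recovery_band < 1:
            raise ConfigError("recovery_band must be in (0, 1)")


@dataclass
class PipelineConfig:
    """Validated configuration for a full pipeline run."""

    schedules: dict[float, CycleSchedule] = field(
        default_factory=lambda: {
            t: CycleSchedule(flush, closed)
            for t, (flush, closed) in DEFAULT_SCHEDULES.items()
        }
    )
    analysis: AnalysisParams = field(default_factory=AnalysisParams)
    loop_volume: float = 0.160
    fish_volume: float = 0.025
    salinity: float = 32.0
    alpha_by_temperature: dict[float, float] = field(default_factory=dict)
    seed: int = 0
    simulation: dict[str, Any] | None = None
    out_dir: str = "results"

    def schedule_for(self, temperature: float) -> CycleSchedule:
        try:
            return self.schedules[float(temperature)]
        except KeyError:
            raise ConfigError(
                f"no cycle schedule configured for {temperature} degC "
                f"(configured: {sorted(self.schedules)})"
            ) from None

    def require_schedules(self, temperatures) -> None:
        """Fail fast if any test temperature lacks a cycle schedule."""
        missing = sorted(
            {float(t) for t in temperatures} - set(self.schedules)
        )
        if missing:
            raise ConfigError(
                f"missing cycle schedule for temperatures {missing}"
            )


def _schedule_from_table(tab: dict[str, Any]) -> tuple[float, CycleSchedule]:
    try:
        temp = float(tab["temperature"])
        flush = float(tab["flush_s"])
        closed = float(tab["closed_s"])
    except KeyError as exc:
        raise ConfigError(f"schedule entry missing key {exc}") from None
    sched = CycleSchedule(
        flush_duration=flush,
        closed_duration=closed,
        leading_trim=float(tab.get("leading_trim_s", 120.0)),
        trailing_trim=float(tab.get("trailing_trim_s", 60.0)),
    )
    return temp, sched


def load_config(path: str | Path) -> PipelineConfig:
    """Load and validate a TOML pipeline configuration.

    Recognised sections: top-level ``seed``/``out_dir``, ``[[schedule]]``
    tables (``temperature``, ``flush_s``, ``closed_s`` and optional
    trims), ``[respirometer]``, ``[analysis]`` (any
    :class:`AnalysisParams` field) and ``[simulation]`` (passed through
    to the synthetic-study generator).  Omitted sections fall back to
    the protocol defaults.
    """
    path = Path(path)
    with path.open("rb") as fh:
        raw = tomllib.load(fh)

    cfg = PipelineConfig()
    if "seed" in raw:
        cfg.seed = int(raw["seed"])
    if "out_dir" in raw:
        cfg.out_dir = str(raw["out_dir"])

    if "schedule" in raw:
        cfg.schedules = dict(
            _schedule_from_table(tab) for tab in raw["schedule"]
        )

    resp = raw.get("respirometer", {})
    cfg.loop_volume = float(resp.get("loop_volume_l", cfg.loop_volume))
    cfg.fish_volume = float(resp.get("fish_volume_l", cfg.fish_volume))
    cfg.salinity = float(resp.get("salinity_psu", cfg.salinity))
    if "alpha_by_temperature" in resp:
        cfg.alpha_by_temperature = {
            float(k): float(v)
            for k, v in resp["alpha_by_temperature"].items()
        }

    analysis = raw.get("analysis", {})
    known = {f.name for f in fields(AnalysisParams)}
    unknown = set(analysis) - known
    if unknown:
        raise ConfigError(f"unknown analysis parameters: {sorted(unknown)}")
    cfg.analysis = AnalysisParams(**analysis)

    if "simulation" in raw:
        cfg.simulation = dict(raw["simulation"])
        sim_temps = list(cfg.simulation.get("acute_temperatures", [])) + list(
            cfg.simulation.get("acclimated_temperatures", [])
        )
        if sim_temps:
            cfg.require_schedules(sim_temps)

    return cfg
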