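"""Thermal-sensitivity statistics: interval Q10, percent change, omnibus.

The temperature coefficient

    Q10 = (R2 / R1) ** (10 / (T2 - T1))

expresses the factor by which a biological rate changes per 10 degC,
generalised to arbitrary temperature intervals (Celsius differences
only).  Because each fish is tested at a single temperature, interval
Q10 values are computed from the arithmetic group-mean rates at the two
endpoint temperatures, yielding one Q10 per metric, treatment and
interval; "omnibus" summaries then average the per-metric values.

Percent change is signed in the cooling direction:
100 * (mean_cold - mean_warm) / mean_warm, so a performance loss on
cooling is negative.  Q10 is restricted to rate metrics; percent change
applies to all performance metrics.  SMR is carried through the tables
but excluded from omnibus summaries (it is a maintenance cost, not a
performance metric).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Metrics not expressed per unit time, for which Q10 is inappropriate.
NON_RATE_METRICS = frozenset(
    {"chase_duration", "recovery_time", "responsiveness"}
)

#: Excluded from omnibus summaries (basic maintenance cost).
OMNIBUS_EXCLUDED = frozenset({"smr"})

#: (treatment, (T_low, T_high)) intervals bracketing the winter dormancy
#: threshold temperature, plus the acute warming interval.  No
#: acclimation above 14 degC exists by design.
DEFAULT_INTERVALS = (
    ("acute", (14.0, 20.0)),
    ("acute", (8.0, 14.0)),
    ("acute", (2.0, 8.0)),
    ("acclimated", (8.0, 14.0)),
    ("acclimated", (2.0, 8.0)),
)


class SensitivityError(ValueError):
    """Raised on invalid sensitivity inputs."""


@dataclass(frozen=True)
class Q10Result:
    metric: str
    treatment: str
    t_low: float
    t_high: float
    mean_low: float
    mean_high: float
    q10: float | None
    percent_change: float | None

    @property
    def interval_label(self) -> str:
        return f"{self.treatment} {self.t_high:g}-{self.t_low:g}"


@dataclass
class SensitivitySummary:
    """Omnibus (across-metric) thermal sensitivity for one interval."""

    treatment: str
    t_low: float
    t_high: float
    mode: str
    omnibus_mean: float
    omnibus_sd: float
    omnibus_sem: float
    q1: float
    median: float
    q3: float
    n_metrics: int
    metrics: tuple[str, ...]


def q10(r1: float, r2: float, t1: float, t2: float) -> float:
    """Temperature coefficient for rates r1 at t1 and r2 at t2 (degC)."""
    if r1 <= 0 or r2 <= 0:
        raise SensitivityError("Q10 undefined for non-positive rates")
    if t1 == t2:
        raise SensitivityError("Q10 undefined for a zero temperature span")
    return (r2 / r1) ** (10.0 / (t2 - t1))


def percent_change(mean_cold: float, mean_warm: float) -> float:
    """Signed % change with cooling: 100 * (cold - warm) / warm."""
    if mean_warm == 0:
        raise SensitivityError("percent change undefined for a zero reference")
    return 100.0 * (mean_cold - mean_warm) / mean_warm


def validate_performance_table(table: pd.DataFrame) -> pd.DataFrame:
    """Check the tidy performance table and normalise the is_rate flag."""
    required = {"fish_id", "metric", "value", "temperature", "treatment"}
    missing = required - set(table.columns)
    if missing:
        raise SensitivityError(
            f"performance table missing columns {sorted(missing)}"
        )
    table = table.copy()
    if "is_rate" not in table.columns:
        table["is_rate"] = ~table["metric"].isin(NON_RATE_METRICS)
    mislabeled = table.loc[
        table["metric"].isin(NON_RATE_METRICS) & table["is_rate"].astype(bool)
    ]
    if len(mislabeled):
        raise SensitivityError(
            "non-rate metrics flagged as rates: "
            f"{sorted(mislabeled['metric'].unique())}"
        )
    return table


def interval_sensitivity(
    table: pd.DataFrame,
    intervals=DEFAULT_INTERVALS,
) -> list[Q10Result]:
    """Per metric x treatment x interval Q10 and percent change.

    Group means are taken over all fish of one metric at each endpoint
    temperature (different fish per temperature).  Q10 is computed only
    for rate metrics with positive endpoint means; percent change for
    every metric.  Intervals with a missing endpoint group are skipped
    with a warning.
    """
    table = validate_performance_table(table)
    means = (
        table.groupby(["metric", "treatment", "temperature"], sort=True)[
            "value"
        ]
        .mean()
        .to_dict()
    )
    is_rate = dict(
        table.drop_duplicates("metric")[["metric", "is_rate"]].to_numpy()
    )
    results: list[Q10Result] = []
    for metric in sorted(table["metric"].unique()):
        for treatment, (t_low, t_high) in intervals:
            lo = means.get((metric, treatment, t_low))
            hi = means.get((metric, treatment, t_high))
            if lo is None or hi is None:
                logger.warning(
                    "%s %s %g-%g degC: missing endpoint group; skipped",
                    metric,
                    treatment,
                    t_high,
                    t_low,
                )
                continue
            q = None
            if is_rate[metric] and lo > 0 and hi > 0:
                q = q10(lo, hi, t_low, t_high)
            elif is_rate[metric]:
                logger.warning(
                    "%s %s: non-positive mean rate; Q10 undefined",
                    metric,
                    treatment,
                )
            pc = percent_change(lo, hi) if hi != 0 else None
            results.append(
                Q10Result(
                    metric=metric,
                    treatment=treatment,
                    t_low=t_low,
                    t_high=t_high,
                    mean_low=lo,
                    mean_high=hi,
                    q10=q,
                    percent_change=pc,
                )
            )
    return results


def q10_results_frame(results: list[Q10Result]) -> pd.DataFrame:
    """Tidy frame of interval-sensitivity results."""
    return pd.DataFrame(
        {
            "metric": [r.metric for r in results],
            "treatment": [r.treatment for r in results],
            "t_low": [r.t_low for r in results],
            "t_high": [r.t_high for r in results],
            "mean_low": [r.mean_low for r in results],
            "mean_high": [r.mean_high for r in results],
            "q10": [r.q10 for r in results],
            "percent_change": [r.percent_change for r in results],
        }
    )


def omnibus(
    results: list[Q10Result],
    treatment: str,
    t_low: float,
    t_high: float,
    mode: str = "q10_rates_only",
    rate_metrics: set[str] | None = None,
) -> SensitivitySummary:
    """Across-metric mean thermal sensitivity for one interval.

    ``mode='q10_rates_only'`` averages the Q10 values of rate metrics;
    ``mode='percent_change_all'`` averages percent changes of all
    performance metrics.  SMR is excluded in both modes.
    """
    if mode not in ("q10_rates_only", "percent_change_all"):
        raise SensitivityError(f"unknown omnibus mode {mode!r}")
    values, metrics = [], []
    for r in results:
        if (r.treatment, r.t_low, r.t_high) != (treatment, t_low, t_high):
            continue
        if r.metric in OMNIBUS_EXCLUDED:
            continue
        if mode == "q10_rates_only":
            if rate_metrics is not None and r.metric not in rate_metrics:
                continue
            if r.q10 is None:
                continue
            values.append(r.q10)
        else:
            if r.percent_change is None:
                continue
            values.append(r.percent_change)
        metrics.append(r.metric)
    if not values:
        raise SensitivityError(
            f"no per-metric values for {treatment} {t_high:g}-{t_low:g} degC"
        )
    arr = np.asarray(values, float)
    q1, med, q3 = np.percentile(arr, [25, 50, 75])
    sd = arr.std(ddof=1) if arr.size > 1 else 0.0
    return SensitivitySummary(
        treatment=treatment,
        t_low=t_low,
        t_high=t_high,
        mode=mode,
        omnibus_mean=float(arr.mean()),
        omnibus_sd=float(sd),
        omnibus_sem=float(sd / np.sqrt(arr.size)),
        q1=float(q1),
        median=float(med),
        q3=float(q3),
        n_metrics=int(arr.size),
        metrics=tuple(metrics),
    )


def omnibus_frame(
    results: list[Q10Result],
    intervals=DEFAULT_INTERVALS,
) -> pd.DataFrame:
    """Omnibus summaries for every interval and both modes."""
    rows = []
    for mode in ("q10_rates_only", "percent_change_all"):
        for treatment, (t_low, t_high) in intervals:
            try:
                s = omnibus(results, treatment, t_low, t_high, mode)
            except SensitivityError:
                continue
            rows.append(
                {
                    "treatment": s.treatment,
                    "t_low": s.t_low,
                    "t_high": s.t_high,
                    "mode": s.mode,
                    "omnibus_mean": s.omnibus_mean,
                    "omnibus_sd": s.omnibus_sd,
                    "omnibus_sem": s.omnibus_sem,
                    "q1": s.q1,
                    "median": s.median,
                    "q3": s.q3,
                    "n_metrics": s.n_metrics,
                }
            )
    return pd.DataFrame(rows)
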