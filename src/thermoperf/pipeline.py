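"""Stage orchestration: simulate -> respirometry -> kinematics ->
performance -> sensitivity -> stats.

Each stage logs one line with input/output record counts and timing.
Any stage failure aborts the run naming the stage and cause.  With a
fixed seed the result bundle is bit-identical across runs.
"""

from __future__ import annotations

import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import kinematics as kin
from . import respirometry as resp
from . import sensitivity as sens
from . import stats as st
from .config import PipelineConfig, RespirometerSpec
from .io import write_results
from .performance import SwimTrial, compute_effort, compute_u_chase
from .synthetic import MetricModel, StudyDesign, SyntheticStudy, simulate_study

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and cause."""


def _stage(name):
    def deco(fn):
        def wrapped(*args, **kwargs):
            t0 = time.perf_counter()
            try:
                out = fn(*args, **kwargs)
            except Exception as exc:
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
            logger.info("stage %s finished in %.2f s", name, time.perf_counter() - t0)
            return out

        return wrapped

    return deco


def _design_from_config(cfg: PipelineConfig) -> StudyDesign:
    sim = dict(cfg.simulation or {})
    design = StudyDesign()
    for key in (
        "n_kinematics",
        "n_respirometry",
        "n_attempts",
        "recovery_tau_h",
        "trace_duration_h",
        "sample_period_s",
        "noise_sd",
        "background_rate",
        "fps",
        "pixels_per_cm",
        "track_noise_px",
        "mean_body_length_cm",
    ):
        if key in sim:
            setattr(design, key, type(getattr(design, key))(sim[key]))
    if "acute_temperatures" in sim:
        design.acute_temperatures = tuple(float(t) for t in sim["acute_temperatures"])
    if "acclimated_temperatures" in sim:
        design.acclimated_temperatures = tuple(
            float(t) for t in sim["acclimated_temperatures"]
        )
    design.loop_volume = cfg.loop_volume
    design.salinity = cfg.salinity
    if "metrics" in sim:  # per-metric model overrides
        for metric, fieldsmap in sim["metrics"].items():
            base = design.metric_models[metric]
            design.metric_models[metric] = MetricModel(
                reference=float(fieldsmap.get("reference", base.reference)),
                q10_above=float(fieldsmap.get("q10_above", base.q10_above)),
                q10_below=float(fieldsmap.get("q10_below", base.q10_below)),
                compensation=float(
                    fieldsmap.get("compensation", base.compensation)
                ),
                cv=float(fieldsmap.get("cv", base.cv)),
            )
    return design


@_stage("simulate")
def run_simulate(cfg: PipelineConfig) -> SyntheticStudy:
    design = _design_from_config(cfg)
    cfg.require_schedules(
        list(design.acute_temperatures) + list(design.acclimated_temperatures)
    )
    study = simulate_study(design, cfg.schedules, seed=cfg.seed)
    logger.info(
        "simulated %d O2 traces, %d burst fish, %d swim trials",
        len(study.traces),
        len(study.trajectories),
        len(study.swim_trials),
    )
    return study


@_stage("respirometry")
def run_respirometry(
    traces: list[resp.O2Trace],
    fish_meta: pd.DataFrame,
    cfg: PipelineConfig,
) -> pd.DataFrame:
    """Per-fish metabolic summaries with cohort time-point alignment.

    Fish measured in the same temperature-by-treatment trial share one
    fine recovery grid; time points lacking a value for every fish are
    dropped before recovery detection and EPOC integration.
    """
    meta = fish_meta.set_index("fish_id")
    params = cfg.analysis
    prepared = {}
    for trace in traces:
        row = meta.loc[trace.fish_id]
        schedule = cfg.schedule_for(trace.test_temperature)
        spec = RespirometerSpec(
            loop_volume=float(row["loop_volume_l"]),
            fish_volume=float(row["fish_volume_l"]),
            alpha=float(row["alpha"]),
            mass=float(row["body_mass_kg"]),
            alpha_source="computed (Benson-Krause, salinity-corrected)",
        )
        background = resp.segment_cycles(
            trace, schedule, phase=resp.PHASE_BACKGROUND
        )
        mmr_sample, mmr_window = resp.find_mmr(
            trace, spec, schedule, params, background=background
        )
        whole = resp.correct_background(
            resp.segment_cycles(trace, schedule), background
        )
        pool = []
        for rec in whole:
            sample = resp.compute_mo2(rec, spec)
            cyc_start = rec.window_start - schedule.leading_trim
            in_mmr_cycle = (
                cyc_start <= mmr_sample.time_mid <= cyc_start + schedule.closed_duration
            )
            if not in_mmr_cycle and not sample.flagged:
                pool.append(sample.mo2)
        smr, n_used = resp.estimate_smr(pool)
        series = resp.build_recovery_series(
            trace, spec, schedule, mmr_sample.time_mid, params, background=background
        )
        key = (float(trace.test_temperature), str(row["treatment"]))
        prepared[trace.fish_id] = {
            "trial": key,
            "trace": trace,
            "smr": smr,
            "n_used": n_used,
            "mmr_sample": mmr_sample,
            "mmr_window": mmr_window,
            "series": series,
            "alpha": spec.alpha,
        }

    # cohort alignment within each trial's shared fine window
    trials: dict[tuple, list[str]] = {}
    for fid, rec in prepared.items():
        trials.setdefault(rec["trial"], []).append(fid)
    for fids in trials.values():
        if len(fids) < 2:
            continue
        aligned = resp.align_cohort_timepoints(
            {fid: prepared[fid]["series"] for fid in fids},
            tolerance_s=params.cohort_tolerance_s,
        )
        for fid, series in aligned.items():
            prepared[fid]["series"] = series

    rows = []
    for fid, rec in prepared.items():
        mmr_sample = rec["mmr_sample"]
        recovery_time, recovered = resp.find_recovery_time(
            rec["series"],
            rec["smr"],
            mmr_sample.time_mid,
            params,
            trace_end=float(rec["trace"].times[-1]),
        )
        epoc = resp.compute_epoc(
            rec["series"], rec["smr"], mmr_sample, recovery_time
        )
        temp, treatment = rec["trial"]
        rows.append(
            {
                "fish_id": fid,
                "temperature": temp,
                "treatment": treatment,
                "smr": rec["smr"],
                "mmr": mmr_sample.mo2,
                "aas": mmr_sample.mo2 - rec["smr"],
                "epoc": epoc,
                "recovery_time_h": recovery_time,
                "recovered": recovered,
                "mmr_window_start_s": rec["mmr_window"].window_start,
                "n_smr_slopes_used": rec["n_used"],
                "alpha": rec["alpha"],
            }
        )
    out = pd.DataFrame(rows)
    logger.info("respirometry: %d traces -> %d summaries", len(traces), len(out))
    return out


@_stage("kinematics")
def run_kinematics(
    trajectories: dict[str, list[kin.TrackTrajectory]],
    fish_meta: pd.DataFrame,
    cfg: PipelineConfig,
) -> pd.DataFrame:
    meta = fish_meta.set_index("fish_id")
    rows = []
    for fish_id, attempts in trajectories.items():
        row = meta.loc[fish_id]
        result = kin.summarize_fish(
            attempts,
            body_length=float(row["body_length_cm"]),
            window_ms=cfg.analysis.kinematics_window_ms,
            smooth_frames=cfg.analysis.kinematics_smooth_frames,
        )
        if result is None:
            # fish without any analyzable attempt still scores responsiveness
            responsiveness = (
                kin.score_responsiveness(
                    [a.pre_contact_response for a in attempts]
                )
                if attempts
                else np.nan
            )
            rows.append(
                {
                    "fish_id": fish_id,
                    "temperature": float(row["temperature"]),
                    "treatment": str(row["treatment"]),
                    "u_max_bls": np.nan,
                    "u_max_cms": np.nan,
                    "a_max_ms2": np.nan,
                    "responsiveness": responsiveness,
                    "best_attempt_id": "",
                    "n_attempts": int(row.get("n_attempts", len(attempts))),
                }
            )
            continue
        # attempts absent from the tracker output (no C-start at all)
        # still count toward responsiveness
        n_total = int(row.get("n_attempts", result.n_attempts))
        n_responses = sum(a.pre_contact_response for a in attempts)
        responsiveness = 100.0 * n_responses / n_total
        rows.append(
            {
                "fish_id": fish_id,
                "temperature": float(row["temperature"]),
                "treatment": str(row["treatment"]),
                "u_max_bls": result.u_max_bls,
                "u_max_cms": result.u_max_cms,
                "a_max_ms2": result.a_max_ms2,
                "responsiveness": responsiveness,
                "best_attempt_id": result.best_attempt_id,
                "n_attempts": n_total,
            }
        )
    out = pd.DataFrame(rows)
    logger.info("kinematics: %d fish", len(out))
    return out


@_stage("performance")
def run_performance(
    swim_trials: pd.DataFrame,
    chase_records: pd.DataFrame,
    metabolic: pd.DataFrame,
    cstart: pd.DataFrame,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Assemble the tidy performance table and the effort/EPOC records."""
    speeds = []
    for row in swim_trials.itertuples(index=False):
        bls, cms = compute_u_chase(
            SwimTrial(
                fish_id=row.fish_id,
                laps=float(row.laps),
                chase_duration=float(row.chase_duration_s),
                body_length=float(row.body_length_cm),
            )
        )
        speeds.append(
            {
                "fish_id": row.fish_id,
                "temperature": float(row.temperature),
                "treatment": str(row.treatment),
                "u_chase_bls": bls,
                "u_chase_cms": cms,
            }
        )
    speeds = pd.DataFrame(speeds)

    def tidy(df, column, metric, is_rate):
        out = df[["fish_id", "temperature", "treatment", column]].rename(
            columns={column: "value"}
        )
        out["metric"] = metric
        out["is_rate"] = is_rate
        return out.dropna(subset=["value"])

    parts = [
        tidy(cstart, "u_max_bls", "umax", True),
        tidy(cstart, "a_max_ms2", "amax", True),
        tidy(cstart, "responsiveness", "responsiveness", False),
        tidy(speeds, "u_chase_bls", "uchase", True),
        tidy(
            chase_records.rename(columns={"chase_duration_s": "value"}).assign(
                metric="chase_duration", is_rate=False
            ),
            "value",
            "chase_duration",
            False,
        ),
        tidy(metabolic, "smr", "smr", True),
        tidy(metabolic, "mmr", "mmr", True),
        tidy(metabolic, "aas", "aas", True),
        tidy(metabolic, "epoc", "epoc", True),
        tidy(metabolic, "recovery_time_h", "recovery_time", False),
    ]
    table = pd.concat(parts, ignore_index=True)[
        ["fish_id", "metric", "value", "temperature", "treatment", "is_rate"]
    ]

    # effort (group means: chase duration from the respirometry
    # experiment x Uchase from the swim experiment) joined to mean EPOC
    mean_duration = chase_records.groupby(["temperature", "treatment"])[
        "chase_duration_s"
    ].mean()
    mean_uchase = speeds.groupby(["temperature", "treatment"])[
        "u_chase_bls"
    ].mean()
    mean_epoc = metabolic.groupby(["temperature", "treatment"])["epoc"].mean()
    effort_rows = []
    for key in sorted(set(mean_duration.index) & set(mean_uchase.index)):
        effort_rows.append(
            {
                "temperature": key[0],
                "treatment": key[1],
                "mean_chase_duration_s": mean_duration[key],
                "mean_u_chase_bls": mean_uchase[key],
                "effort_bl": compute_effort(mean_duration[key], mean_uchase[key]),
                "mean_epoc": mean_epoc.get(key, np.nan),
            }
        )
    effort = pd.DataFrame(effort_rows)
    logger.info(
        "performance: %d table rows, %d effort records", len(table), len(effort)
    )
    return table, effort


@_stage("sensitivity")
def run_sensitivity(
    table: pd.DataFrame,
) -> tuple[pd.DataFrame, pd.DataFrame, list[sens.Q10Result]]:
    results = sens.interval_sensitivity(table)
    q10_frame = sens.q10_results_frame(results)
    summary = sens.omnibus_frame(results)
    logger.info(
        "sensitivity: %d interval results, %d omnibus rows",
        len(q10_frame),
        len(summary),
    )
    return q10_frame, summary, results


@_stage("stats")
def run_stats(
    table: pd.DataFrame,
    q10_frame: pd.DataFrame,
    effort: pd.DataFrame,
    shared_range: tuple[float, float] = (2.0, 14.0),
) -> dict[str, pd.DataFrame]:
    lo, hi = shared_range
    shared = table[(table["temperature"] >= lo) & (table["temperature"] <= hi)]
    two_way_rows, one_way_rows, tukey_rows, levene_rows = [], [], [], []
    for metric, grp in shared.groupby("metric"):
        grp = grp.dropna(subset=["value"])
        if grp["treatment"].nunique() == 2:
            try:
                res = st.two_way_anova(grp)
            except st.StatsError as exc:
                logger.warning("two-way ANOVA skipped for %s: %s", metric, exc)
            else:
                for r in res.terms.itertuples(index=False):
                    two_way_rows.append({"metric": metric, **r._asdict()})
                if res.tukey is not None:
                    tk = res.tukey.copy()
                    tk.insert(0, "metric", metric)
                    tk.insert(1, "design", "two_way")
                    tukey_rows.append(tk)
            groups = [
                g["value"].to_numpy(float)
                for _, g in grp.groupby(["temperature", "treatment"])
                if len(g) >= 2
            ]
            # degenerate inputs (zero-spread groups, or all-pair groups
            # whose absolute deviations are constant) leave the statistic
            # undefined; record only finite results
            if len(groups) >= 2 and all(np.ptp(g) > 0 for g in groups):
                with np.errstate(divide="ignore", invalid="ignore"):
                    w, p = st.levene(groups)
                if np.isfinite(w):
                    levene_rows.append({"metric": metric, "W": w, "p": p})
                else:
                    logger.warning(
                        "Levene undefined for %s (degenerate groups)", metric
                    )
    acute = table[table["treatment"] == "acute"].dropna(subset=["value"])
    for metric, grp in acute.groupby("metric"):
        try:
            res = st.one_way_anova(grp)
        except st.StatsError as exc:
            logger.warning("one-way ANOVA skipped for %s: %s", metric, exc)
            continue
        for r in res.terms.itertuples(index=False):
            one_way_rows.append({"metric": metric, **r._asdict()})
        if res.tukey is not None:
            tk = res.tukey.copy()
            tk.insert(0, "metric", metric)
            tk.insert(1, "design", "one_way_acute")
            tukey_rows.append(tk)

    # omnibus sensitivity ANOVA: metrics are the replicates per level
    sens_tables = {}
    for mode, col in (
        ("q10", "q10"),
        ("percent_change", "percent_change"),
    ):
        df = q10_frame.dropna(subset=[col]).copy()
        df = df[~df["metric"].isin(sens.OMNIBUS_EXCLUDED)]
        df["level"] = (
            df["treatment"]
            + " "
            + df["t_high"].map("{:g}".format)
            + "-"
            + df["t_low"].map("{:g}".format)
        )
        df = df.rename(columns={col: "value"})[["level", "value", "metric"]]
        try:
            res = st.sensitivity_anova(df)
        except st.StatsError as exc:
            logger.warning("sensitivity ANOVA (%s) skipped: %s", mode, exc)
            continue
        terms = res.terms.copy()
        terms.insert(0, "mode", mode)
        sens_tables[mode] = terms
        if res.tukey is not None:
            tk = res.tukey.copy()
            tk.insert(0, "metric", f"omnibus_{mode}")
            tk.insert(1, "design", "sensitivity")
            tukey_rows.append(tk)

    out: dict[str, pd.DataFrame] = {
        "anova_two_way": pd.DataFrame(two_way_rows),
        "anova_one_way_acute": pd.DataFrame(one_way_rows),
        "levene_results": pd.DataFrame(levene_rows),
        "anova_sensitivity": (
            pd.concat(sens_tables.values(), ignore_index=True)
            if sens_tables
            else pd.DataFrame()
        ),
        "tukey_tables": (
            pd.concat(tukey_rows, ignore_index=True)
            if tukey_rows
            else pd.DataFrame()
        ),
    }

    # effort vs EPOC regression over the shared temperature range
    reg = effort[
        (effort["temperature"] >= lo) & (effort["temperature"] <= hi)
    ].rename(columns={"effort_bl": "effort", "mean_epoc": "epoc"})
    try:
        comparison = st.effort_epoc_regression(reg)
    except st.StatsError as exc:
        logger.warning("effort-EPOC regression skipped: %s", exc)
        out["regression_results"] = pd.DataFrame()
    else:
        per_group = comparison.per_group.copy()
        per_group["interaction_p"] = comparison.interaction_p
        per_group["slopes_differ"] = comparison.slopes_differ
        out["regression_results"] = per_group
    return out


def run_pipeline(
    config: PipelineConfig | str | Path,
    out_dir: str | Path | None = None,
    write: bool = True,
) -> dict[str, pd.DataFrame]:
    """Execute the full stage graph and return the result bundle.

    ``config`` may be a :class:`PipelineConfig` or a path to a TOML
    file.  A ``[simulation]`` section is required for now (the pipeline
    generates its inputs; individual stages are importable for measured
    data).
    """
    from .config import load_config

    cfg = config if isinstance(config, PipelineConfig) else load_config(config)
    if cfg.simulation is None:
        raise PipelineError(
            "stage 'simulate' failed: config has no [simulation] section"
        )
    out_dir = Path(out_dir) if out_dir is not None else Path(cfg.out_dir)

    study = run_simulate(cfg)
    metabolic = run_respirometry(study.traces, study.fish_meta, cfg)
    cstart = run_kinematics(study.trajectories, study.fish_meta, cfg)
    table, effort = run_performance(
        study.swim_trials, study.chase_records, metabolic, cstart
    )
    q10_frame, summary, _ = run_sensitivity(table)
    stats_tables = run_stats(table, q10_frame, effort)

    bundle: dict[str, pd.DataFrame] = {
        "fish_meta": study.fish_meta,
        "ground_truth": study.truth,
        "metabolic_summary": metabolic,
        "cstart_results": cstart,
        "performance_table": table,
        "effort_epoc": effort,
        "q10_results": q10_frame,
        "sensitivity_summary": summary,
        **stats_tables,
    }
    if write:
        manifest = write_results(bundle, out_dir)
        logger.info("wrote %d tables to %s", len(manifest), out_dir)
    return bundle
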