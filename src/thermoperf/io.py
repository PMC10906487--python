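"""Tidy CSV readers and writers for all pipeline inputs and outputs.

All files are comma-separated UTF-8 with a mandatory header row and '.'
decimal separator.  Phase labels absent from an O2 trace are inferred
from the cycle schedule by modular arithmetic on time: each cycle is
``closed_duration`` of sealed measurement followed by
``flush_duration`` of re-oxygenation, starting closed at t = 0 (the
fish enters the sealed chamber immediately post-chase), with half-open
phase intervals [start, end).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .config import CycleSchedule
from .kinematics import TrackTrajectory
from .respirometry import (
    O2Trace,
    PHASE_CLOSED,
    PHASE_FLUSH,
    RespirometryError,
)


class IOError_(ValueError):
    """Raised on malformed input files."""


def infer_phases(times_s: np.ndarray, schedule: CycleSchedule) -> np.ndarray:
    """Phase label per sample from the cycle schedule.

    ``closed`` for ``t mod period`` in [0, closed_duration), ``flush``
    otherwise.
    """
    offset = np.mod(np.asarray(times_s, float), schedule.period)
    return np.where(
        offset < schedule.closed_duration, PHASE_CLOSED, PHASE_FLUSH
    ).astype(object)


def read_o2_trace(
    path: str | Path,
    schedule: CycleSchedule | None = None,
    fish_id: str | None = None,
    test_temperature: float = float("nan"),
) -> O2Trace:
    """Read an O2 trace CSV (``time_s``, ``o2_percent_sat`` [, ``phase``]).

    When the ``phase`` column is absent a schedule is required and
    phases are inferred by modular arithmetic on time.  Non-monotone
    time is rejected naming the offending row.
    """
    path = Path(path)
    df = pd.read_csv(path)
    required = {"time_s", "o2_percent_sat"}
    missing = required - set(df.columns)
    if missing:
        raise IOError_(
            f"{path.name}: missing columns {sorted(missing)} "
            f"(found {list(df.columns)})"
        )
    t = df["time_s"].to_numpy(float)
    bad = np.nonzero(np.diff(t) <= 0)[0]
    if bad.size:
        raise IOError_(
            f"{path.name}: time not strictly increasing at row "
            f"{int(bad[0]) + 1}"
        )
    if "phase" not in df.columns:
        if schedule is None:
            raise IOError_(
                f"{path.name}: no phase column and no schedule to infer it"
            )
        df = df.assign(phase=infer_phases(t, schedule))
    try:
        return O2Trace(
            fish_id=fish_id or path.stem,
            test_temperature=test_temperature,
            data=df[["time_s", "o2_percent_sat", "phase"]],
        )
    except RespirometryError as exc:
        raise IOError_(f"{path.name}: {exc}") from exc


def write_o2_trace(trace: O2Trace, path: str | Path) -> Path:
    path = Path(path)
    trace.data.to_csv(path, index=False)
    return path


def read_trajectories(
    frames_path: str | Path,
    attempts_path: str | Path,
    fps: float,
    pixels_per_cm: float,
) -> dict[str, list[TrackTrajectory]]:
    """Read tracked frames plus attempt metadata into per-fish attempts.

    ``frames_path`` columns: attempt_id, frame, time_s, x_px, y_px.
    ``attempts_path`` columns: fish_id, attempt_id, stimulus_type,
    pre_contact_response, onset_s (empty when no C-start occurred).
    """
    frames = pd.read_csv(frames_path)
    meta = pd.read_csv(attempts_path)
    for name, df, cols in (
        ("frames", frames, {"attempt_id", "frame", "time_s", "x_px", "y_px"}),
        (
            "attempts",
            meta,
            {"fish_id", "attempt_id", "stimulus_type", "pre_contact_response"},
        ),
    ):
        missing = cols - set(df.columns)
        if missing:
            raise IOError_(f"{name} file missing columns {sorted(missing)}")
    out: dict[str, list[TrackTrajectory]] = {}
    grouped = frames.sort_values(["attempt_id", "frame"]).groupby("attempt_id")
    for row in meta.itertuples(index=False):
        onset = getattr(row, "onset_s", None)
        if onset is not None and pd.isna(onset):
            onset = None
        try:
            grp = grouped.get_group(row.attempt_id)
            t = grp["time_s"].to_numpy(float)
            x = grp["x_px"].to_numpy(float)
            y = grp["y_px"].to_numpy(float)
        except KeyError:
            t = x = y = np.empty(0)
        traj = TrackTrajectory(
            fish_id=str(row.fish_id),
            attempt_id=str(row.attempt_id),
            stimulus_type=str(row.stimulus_type),
            pre_contact_response=bool(row.pre_contact_response),
            time_s=t,
            x_px=x,
            y_px=y,
            fps=fps,
            pixels_per_cm=pixels_per_cm,
            cstart_onset=None if onset is None else float(onset),
        )
        out.setdefault(traj.fish_id, []).append(traj)
    return out


def write_trajectories(
    trajectories: dict[str, list[TrackTrajectory]],
    frames_path: str | Path,
    attempts_path: str | Path,
) -> None:
    frame_rows, meta_rows = [], []
    for fish_id, attempts in trajectories.items():
        for traj in attempts:
            meta_rows.append(
                {
                    "fish_id": fish_id,
                    "attempt_id": traj.attempt_id,
                    "stimulus_type": traj.stimulus_type,
                    "pre_contact_response": traj.pre_contact_response,
                    "onset_s": traj.cstart_onset,
                }
            )
            for k in range(traj.time_s.size):
                frame_rows.append(
                    {
                        "attempt_id": traj.attempt_id,
                        "frame": k,
                        "time_s": traj.time_s[k],
                        "x_px": traj.x_px[k],
                        "y_px": traj.y_px[k],
                    }
                )
    pd.DataFrame(frame_rows).to_csv(frames_path, index=False)
    pd.DataFrame(meta_rows).to_csv(attempts_path, index=False)


def read_swim_trials(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {
        "fish_id",
        "temperature",
        "treatment",
        "laps",
        "chase_duration_s",
        "body_length_cm",
    }
    missing = required - set(df.columns)
    if missing:
        raise IOError_(f"swim trials missing columns {sorted(missing)}")
    return df


def read_performance_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"fish_id", "metric", "value", "temperature", "treatment"}
    missing = required - set(df.columns)
    if missing:
        raise IOError_(
            f"performance table missing columns {sorted(missing)}"
        )
    return df


def write_results(
    tables: dict[str, pd.DataFrame], out_dir: str | Path
) -> list[Path]:
    """Write one tidy CSV per table; returns the manifest of files.

    Column order is as given in each table (stable across runs).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = []
    for name, table in tables.items():
        path = out_dir / f"{name}.csv"
        table.to_csv(path, index=False)
        manifest.append(path)
    return manifest
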