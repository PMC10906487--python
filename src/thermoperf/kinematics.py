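"""C-start burst escape-response kinematics.

Computes peak burst velocity (Umax), the associated peak acceleration
(Amax) and responsiveness from tracked head-coordinate time series of
startle attempts recorded at high frame rate (240 frames s^-1 in the
reference protocol).

A fixed window (default 75 ms, roughly stage 1 + stage 2 of the
C-start) following the annotated C-start onset is analysed per attempt.
Speed is the magnitude of the first derivative of the (x, y) path and
acceleration the derivative of speed (tangential); both use
second-order finite differences (``numpy.gradient``), which are exact
for constant-acceleration motion including at the window edges.  No
smoothing is applied by default; an optional centred moving average over
the pixel coordinates is available for noisy tracking.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


class KinematicsError(ValueError):
    """Raised when an attempt cannot be analysed."""


@dataclass
class TrackTrajectory:
    """One tracked startle attempt.

    ``time_s``/``x_px``/``y_px`` are per-frame arrays; ``cstart_onset``
    is the annotated response-onset time (s) or ``None`` when no C-start
    occurred.  ``pre_contact_response`` is True when the C-start was
    elicited before physical contact with the stimulus.
    """

    fish_id: str
    attempt_id: str
    stimulus_type: str
    pre_contact_response: bool
    time_s: np.ndarray
    x_px: np.ndarray
    y_px: np.ndarray
    fps: float
    pixels_per_cm: float
    cstart_onset: float | None = None

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, float)
        self.x_px = np.asarray(self.x_px, float)
        self.y_px = np.asarray(self.y_px, float)
        if self.pixels_per_cm <= 0:
            raise KinematicsError("pixels_per_cm must be > 0")
        if self.fps <= 0:
            raise KinematicsError("fps must be > 0")
        if not (self.time_s.size == self.x_px.size == self.y_px.size):
            raise KinematicsError("frame arrays must have equal length")


@dataclass
class AttemptKinematics:
    """Peak speed and acceleration of one analysed attempt."""

    fish_id: str
    attempt_id: str
    u_max_cms: float
    u_max_bls: float
    a_max_ms2: float


@dataclass
class CStartResult:
    """Per-fish C-start phenotype.

    ``a_max_ms2`` is taken from the same attempt as the best ``u_max``
    even if another attempt peaked higher in acceleration.
    """

    fish_id: str
    u_max_bls: float
    u_max_cms: float
    a_max_ms2: float
    responsiveness: float
    best_attempt_id: str
    n_attempts: int


def calibrate(px_length: float, known_length_cm: float) -> float:
    """Pixels-per-cm ratio from a reference length in the arena."""
    if px_length <= 0 or known_length_cm <= 0:
        raise KinematicsError("calibration lengths must be > 0")
    return px_length / known_length_cm


def _smooth(a: np.ndarray, frames: int) -> np.ndarray:
    if frames <= 1:
        return a
    return (
        pd.Series(a)
        .rolling(frames, center=True, min_periods=1)
        .mean()
        .to_numpy()
    )


def analyze_cstart(
    traj: TrackTrajectory,
    body_length: float,
    window_ms: float = 75.0,
    smooth_frames: int = 0,
) -> AttemptKinematics:
    """Peak speed and tangential acceleration over the onset window.

    Raises :class:`KinematicsError` when the onset annotation is missing
    (such attempts still count toward responsiveness) or the window
    holds fewer than 3 frames.
    """
    if traj.cstart_onset is None:
        raise KinematicsError(
            f"{traj.attempt_id}: no C-start onset annotation"
        )
    if body_length <= 0:
        raise KinematicsError("body_length must be > 0")
    t0 = traj.cstart_onset
    t1 = t0 + window_ms / 1000.0
    sel = (traj.time_s >= t0 - 1e-9) & (traj.time_s <= t1 + 1e-9)
    if sel.sum() < 3:
        raise KinematicsError(
            f"{traj.attempt_id}: <3 frames in the analysis window"
        )
    t = traj.time_s[sel]
    x = _smooth(traj.x_px[sel], smooth_frames) / traj.pixels_per_cm
    y = _smooth(traj.y_px[sel], smooth_frames) / traj.pixels_per_cm
    vx = np.gradient(x, t, edge_order=2)
    vy = np.gradient(y, t, edge_order=2)
    speed = np.hypot(vx, vy)  # cm/s
    accel = np.gradient(speed, t, edge_order=2)  # cm/s^2, tangential
    u_max = float(speed.max())
    a_max = float(np.abs(accel).max()) / 100.0  # m/s^2
    return AttemptKinematics(
        fish_id=traj.fish_id,
        attempt_id=traj.attempt_id,
        u_max_cms=u_max,
        u_max_bls=u_max / body_length,
        a_max_ms2=a_max,
    )


def select_best(attempts: list[AttemptKinematics]) -> AttemptKinematics:
    """Attempt with the highest Umax; its Amax is reported alongside.

    Ties are broken in favour of the earliest attempt (list order).
    """
    if not attempts:
        raise KinematicsError("no analyzable attempts")
    best = attempts[0]
    for att in attempts[1:]:
        if att.u_max_cms > best.u_max_cms:
            best = att
    return best


def score_responsiveness(pre_contact_flags: list[bool]) -> float:
    """% of startle attempts with a pre-contact C-start response.

    Contact-triggered C-starts count as non-responses: the metric
    reflects visual/mechanoacoustic rather than tactile sensing.
    """
    if not pre_contact_flags:
        raise KinematicsError("responsiveness undefined for zero attempts")
    return 100.0 * sum(bool(f) for f in pre_contact_flags) / len(
        pre_contact_flags
    )


def summarize_fish(
    trajectories: list[TrackTrajectory],
    body_length: float,
    window_ms: float = 75.0,
    smooth_frames: int = 0,
) -> CStartResult | None:
    """Per-fish Umax/Amax/responsiveness across all attempts.

    Attempts without an onset annotation are excluded from kinematics
    but still count for responsiveness.  Returns ``None`` (fish excluded
    from the Umax/Amax tables) when no attempt is analyzable.
    """
    if not trajectories:
        return None
    fish_id = trajectories[0].fish_id
    responsiveness = score_responsiveness(
        [traj.pre_contact_response for traj in trajectories]
    )
    analysed = []
    for traj in trajectories:
        try:
            analysed.append(
                analyze_cstart(traj, body_length, window_ms, smooth_frames)
            )
        except KinematicsError as exc:
            logger.info("%s: attempt excluded from kinematics (%s)", fish_id, exc)
    if not analysed:
        logger.warning("%s: no analyzable C-start attempts", fish_id)
        return None
    best = select_best(analysed)
    return CStartResult(
        fish_id=fish_id,
        u_max_bls=best.u_max_bls,
        u_max_cms=best.u_max_cms,
        a_max_ms2=best.a_max_ms2,
        responsiveness=responsiveness,
        best_attempt_id=best.attempt_id,
        n_attempts=len(trajectories),
    )
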