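"""Trial-level performance measures for FOV trajectories.

Each trial is one attempt to drive the vehicle from a fixed start point to a
target 2.5 m away, within 3 minutes.  Three measures characterise a trial:

* **success** — whether the final trajectory point lies in the target area
  (at most 6 successes per session, one per trial);
* **angular error** — the signed angle between the start-to-end direction and
  the start-to-target direction, positive clockwise (so an unadapted animal
  under a +45 deg rightward rotation of the control mapping shows positive
  error);
* **adjusted distance** — the polyline path length, augmented on failed
  trials by an estimated additional length (EAL): the end-to-target distance
  scaled by the session's efficiency ``eff = sum(len) / sum(SE)``.

Sessions (six trials on one experimental day) are summarised by success
counts and medians, and a baseline advancement criterion decides when an
animal has learned the unperturbed task.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import median_filter

__all__ = [
    "Stage",
    "EndReason",
    "TrialRecord",
    "TrialMetrics",
    "SessionMetrics",
    "EmptyTrialError",
    "DegenerateSessionError",
    "clean_trajectory",
    "path_length",
    "angular_error",
    "is_success",
    "session_efficiency",
    "adjusted_distance",
    "compute_trial_metrics",
    "summarize_session",
    "compute_metrics",
    "baseline_criterion",
]

MAX_TRIAL_SECONDS = 180.0
OPTIMAL_DISTANCE_M = 2.5
DEFAULT_TARGET_RADIUS_M = 0.25
TRIALS_PER_SESSION = 6


class Stage(str, Enum):
    """Experimental stages, in chronological order."""

    BASELINE = "baseline"
    ROTATION = "rotation"
    WASHOUT = "washout"
    SAVINGS = "savings"
    FINAL = "final"

    @property
    def order(self) -> int:
        return list(Stage).index(self)


class EndReason(str, Enum):
    TARGET_REACHED = "target_reached"
    TIMEOUT = "timeout"
    BOUNDARY = "boundary"


class EmptyTrialError(ValueError):
    """Raised when a trial has fewer than two valid samples ("empty trial")."""


class DegenerateSessionError(ValueError):
    """Raised when a session's total start-to-end displacement is zero."""


@dataclass
class TrialRecord:
    """One trial's identity, cleaned trajectory, and geometry.

    ``samples`` is an (n, 3) array of ``(t_s, x_m, y_m)`` rows in the
    arena-fixed frame (metres, y-up), with strictly increasing timestamps.
    """

    fish_id: str
    stage: Stage
    session_index: int
    trial_index: int
    samples: np.ndarray
    start_point: tuple[float, float]
    target_point: tuple[float, float]
    end_reason: EndReason | None = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2 or self.samples.shape[1] != 3:
            raise ValueError("samples must be an (n, 3) array of (t, x, y)")
        if len(self.samples) == 0:
            raise EmptyTrialError("empty trial: no samples")
        t = self.samples[:, 0]
        if np.any(np.diff(t) <= 0):
            raise ValueError("timestamps must be strictly increasing")
        if t[-1] - t[0] > MAX_TRIAL_SECONDS + 1e-9:
            raise ValueError(f"trial duration exceeds {MAX_TRIAL_SECONDS} s")
        self.stage = Stage(self.stage)
        if self.end_reason is not None:
            self.end_reason = EndReason(self.end_reason)

    @property
    def end_point(self) -> tuple[float, float]:
        return float(self.samples[-1, 1]), float(self.samples[-1, 2])

    @property
    def duration(self) -> float:
        return float(self.samples[-1, 0] - self.samples[0, 0])


@dataclass
class TrialMetrics:
    """Per-trial performance measures.  Distances in metres, angles degrees."""

    fish_id: str
    stage: Stage
    session_index: int
    trial_index: int
    success: bool
    angular_error: float  # signed degrees; NaN when end == start
    path_length: float
    se: float  # straight-line start -> end
    et: float  # straight-line end -> target
    eal: float = np.nan  # efficiency * et on failed trials, 0 on success
    adjusted_distance: float = np.nan


@dataclass
class SessionMetrics:
    """Per-session summaries: counts, efficiency, and medians across trials."""

    fish_id: str
    stage: Stage
    session_index: int
    n_trials: int
    success_count: int
    efficiency: float
    median_angular_error: float
    median_adjusted_distance: float
    trial_angular_errors: np.ndarray = field(default_factory=lambda: np.empty(0), repr=False)
    trial_adjusted_distances: np.ndarray = field(default_factory=lambda: np.empty(0), repr=False)


def clean_trajectory(
    t: np.ndarray,
    x: np.ndarray,
    y: np.ndarray,
    *,
    max_gap_s: float = 1.0,
    smooth_window: int = 3,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Repair dropout gaps and smooth a raw trajectory.

    Frames where the tracker lost the fish arrive as NaN positions.  Such
    frames are dropped, then re-filled by linear interpolation at their
    original timestamps provided the surrounding gap is shorter than
    ``max_gap_s``; longer gaps stay removed.  A centred moving-median filter
    of ``smooth_window`` samples (nearest-edge padding) is then applied to
    each coordinate.  Timestamps are never altered.

    Raises :class:`EmptyTrialError` if fewer than two valid samples remain.
    """
    t = np.asarray(t, float)
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    valid = np.isfinite(x) & np.isfinite(y) & np.isfinite(t)
    if valid.sum() < 2:
        raise EmptyTrialError("empty trial: fewer than 2 valid samples")

    tv, xv, yv = t[valid], x[valid], y[valid]
    # Re-insert dropped frames whose enclosing gap between valid neighbours
    # is short enough to trust linear motion across it.
    t_fill = []
    for ti in t[~valid]:
        j = np.searchsorted(tv, ti)
        if 0 < j < len(tv) and (tv[j] - tv[j - 1]) <= max_gap_s:
            t_fill.append(ti)
    if t_fill:
        t_out = np.sort(np.concatenate([tv, np.asarray(t_fill)]))
    else:
        t_out = tv
    x_out = np.interp(t_out, tv, xv)
    y_out = np.interp(t_out, tv, yv)

    if smooth_window and smooth_window > 1:
        x_out = median_filter(x_out, size=smooth_window, mode="nearest")
        y_out = median_filter(y_out, size=smooth_window, mode="nearest")
    return t_out, x_out, y_out


def path_length(x: Sequence[float], y: Sequence[float]) -> float:
    """Polyline length: sum of consecutive Euclidean segment lengths."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size < 2:
        warnings.warn("path_length of a single sample is 0", stacklevel=2)
        return 0.0
    return float(np.sum(np.hypot(np.diff(x), np.diff(y))))


def angular_error(
    start: Sequence[float], end: Sequence[float], target: Sequence[float]
) -> float:
    """Signed angle (degrees) from the start->target to the start->end direction.

    Positive is clockwise in the arena frame (y-up), the direction of a
    rightward rotation of the control mapping: an unadapted animal under a
    +45 deg perturbation yields +45 deg.  Range ``(-180, 180]``.  Returns NaN
    (with a warning) when the end point coincides with the start, where the
    direction is undefined.
    """
    start = np.asarray(start, float)
    u = np.asarray(target, float) - start  # ideal direction
    v = np.asarray(end, float) - start  # actual direction
    if np.allclose(v, 0.0):
        warnings.warn("angular_error undefined: end point equals start point", stacklevel=2)
        return float("nan")
    if np.allclose(u, 0.0):
        raise ValueError("target must differ from start")
    # CCW angle from u to v, negated for the clockwise-positive convention.
    ang = -np.degrees(np.arctan2(u[0] * v[1] - u[1] * v[0], u[0] * v[0] + u[1] * v[1]))
    if ang <= -180.0:
        ang += 360.0
    return float(ang)


def is_success(
    end_point: Sequence[float],
    target_point: Sequence[float],
    *,
    target_radius: float = DEFAULT_TARGET_RADIUS_M,
    recorded: bool | None = None,
) -> bool:
    """Whether a trial ended in the target area.

    A recorded outcome flag, when present in the data, takes precedence over
    the geometric test.  The geometric target is a closed disc: a final point
    exactly on the boundary counts as success.
    """
    if recorded is not None:
        return bool(recorded)
    d = float(np.hypot(*(np.asarray(end_point, float) - np.asarray(target_point, float))))
    return d <= target_radius


def session_efficiency(
    lens: Sequence[float], ses: Sequence[float], *, allow_degenerate: bool = False
) -> float:
    """Session efficiency ``eff = sum(len_T) / sum(SE_T)`` over the session's trials.

    Raises :class:`DegenerateSessionError` when every trial has zero
    start-to-end displacement; with ``allow_degenerate=True`` the
    conventional fallback ``eff = 1`` is returned with a warning.
    """
    total_se = float(np.sum(np.asarray(ses, float)))
    total_len = float(np.sum(np.asarray(lens, float)))
    if total_se <= 0.0:
        if allow_degenerate:
            warnings.warn("degenerate session (sum SE = 0); using eff = 1", stacklevel=2)
            return 1.0
        raise DegenerateSessionError("session efficiency undefined: sum of SE is zero")
    return total_len / total_se


def adjusted_distance(path_len: float, et: float, success: bool, eff: float) -> float:
    """Adjusted distance ``d``: the path length, plus ``EAL = eff * ET`` on failures."""
    return float(path_len) if success else float(path_len) + float(eff) * float(et)


def compute_trial_metrics(
    record: TrialRecord,
    *,
    target_radius: float = DEFAULT_TARGET_RADIUS_M,
    recorded_success: bool | None = None,
) -> TrialMetrics:
    """Geometry-only measures for one trial (EAL and ``d`` need the session)."""
    x = record.samples[:, 1]
    y = record.samples[:, 2]
    end = record.end_point
    start = record.start_point
    tgt = record.target_point
    if recorded_success is None and record.end_reason == EndReason.TARGET_REACHED:
        recorded_success = True
    succ = is_success(end, tgt, target_radius=target_radius, recorded=recorded_success)
    se = float(np.hypot(end[0] - start[0], end[1] - start[1]))
    et = float(np.hypot(tgt[0] - end[0], tgt[1] - end[1]))
    if se == 0.0:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ang = float("nan")
    else:
        ang = angular_error(start, end, tgt)
    return TrialMetrics(
        fish_id=record.fish_id,
        stage=record.stage,
        session_index=record.session_index,
        trial_index=record.trial_index,
        success=succ,
        angular_error=ang,
        path_length=path_length(x, y),
        se=se,
        et=et,
    )


def _finalize_session(trials: list[TrialMetrics], *, allow_degenerate: bool) -> float:
    eff = session_efficiency(
        [tm.path_length for tm in trials],
        [tm.se for tm in trials],
        allow_degenerate=allow_degenerate,
    )
    for tm in trials:
        tm.eal = 0.0 if tm.success else eff * tm.et
        tm.adjusted_distance = adjusted_distance(tm.path_length, tm.et, tm.success, eff)
    return eff


def summarize_session(
    trials: Iterable[TrialMetrics], *, allow_degenerate: bool = False
) -> SessionMetrics:
    """Summarise one session: success count, efficiency, medians across trials.

    Completes each trial's EAL and adjusted distance in place (they require
    the session efficiency).  Trials with undefined angular error (zero
    displacement) are excluded from the angular median but still count as
    failures; if no trial has a defined error the median is NaN, with a
    warning.  Even-length medians use the mean of the two middle values.
    """
    trials = list(trials)
    if not 1 <= len(trials) <= TRIALS_PER_SESSION:
        raise ValueError(f"a session holds 1-{TRIALS_PER_SESSION} trials, got {len(trials)}")
    eff = _finalize_session(trials, allow_degenerate=allow_degenerate)
    angs = np.asarray([tm.angular_error for tm in trials], float)
    defined = angs[np.isfinite(angs)]
    if defined.size == 0:
        warnings.warn("no trial with defined angular error in session", stacklevel=2)
        med_ang = float("nan")
    else:
        med_ang = float(np.median(defined))
    dists = np.asarray([tm.adjusted_distance for tm in trials], float)
    first = trials[0]
    return SessionMetrics(
        fish_id=first.fish_id,
        stage=first.stage,
        session_index=first.session_index,
        n_trials=len(trials),
        success_count=int(sum(tm.success for tm in trials)),
        efficiency=eff,
        median_angular_error=med_ang,
        median_adjusted_distance=float(np.median(dists)),
        trial_angular_errors=angs,
        trial_adjusted_distances=dists,
    )


def compute_metrics(
    records: Iterable[TrialRecord],
    *,
    target_radius: float = DEFAULT_TARGET_RADIUS_M,
    allow_degenerate: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run the full measurement pipeline over many trials.

    Returns a tidy per-trial frame (one row per trial) and a per-session
    frame, both keyed by ``(fish_id, stage, session, trial)``.
    """
    by_session: dict[tuple, list[TrialMetrics]] = {}
    for rec in records:
        tm = compute_trial_metrics(rec, target_radius=target_radius)
        by_session.setdefault((rec.fish_id, rec.stage, rec.session_index), []).append(tm)

    trial_rows, session_rows = [], []
    for (fish, stage, ses), tms in sorted(
        by_session.items(), key=lambda kv: (kv[0][0], Stage(kv[0][1]).order, kv[0][2])
    ):
        tms.sort(key=lambda tm: tm.trial_index)
        sm = summarize_session(tms, allow_degenerate=allow_degenerate)
        for tm in tms:
            trial_rows.append(
                dict(
                    fish_id=fish,
                    stage=Stage(stage).value,
                    session=ses,
                    trial=tm.trial_index,
                    success=tm.success,
                    angular_error_deg=tm.angular_error,
                    len_m=tm.path_length,
                    SE_m=tm.se,
                    ET_m=tm.et,
                    EAL_m=tm.eal,
                    d_m=tm.adjusted_distance,
                )
            )
        session_rows.append(
            dict(
                fish_id=fish,
                stage=Stage(stage).value,
                session=ses,
                n_trials=sm.n_trials,
                success_count=sm.success_count,
                eff=sm.efficiency,
                median_angular_error_deg=sm.median_angular_error,
                median_d_m=sm.median_adjusted_distance,
            )
        )
    return pd.DataFrame(trial_rows), pd.DataFrame(session_rows)


def baseline_criterion(
    sessions: Sequence[SessionMetrics],
    *,
    min_successes: float = 4.0,
    max_abs_angle: float = 15.0,
    max_distance: float = 4.5,
    max_sessions: int = 25,
    window: int = 3,
) -> tuple[bool, int | None]:
    """Baseline advancement: has the animal learned the unperturbed task?

    Scans chronologically ordered baseline sessions for the first window of
    ``window`` consecutive sessions in which the median success count is at
    least ``min_successes``, the median angular error over the window's
    trials is within ``max_abs_angle`` degrees of zero, and the median
    adjusted distance over the window's trials is below ``max_distance``
    metres.  A window must close by session ``max_sessions`` (animals not
    reaching criterion in 25 sessions leave the experiment).

    Returns ``(passed, index)`` where ``index`` is the 0-based session index
    of the last session of the first qualifying window, or None.
    """
    sessions = list(sessions)
    if len(sessions) < window:
        return False, None
    for end in range(window - 1, min(len(sessions), max_sessions)):
        win = sessions[end - window + 1 : end + 1]
        med_succ = float(np.median([s.success_count for s in win]))
        angs = np.concatenate([np.asarray(s.trial_angular_errors, float) for s in win])
        angs = angs[np.isfinite(angs)]
        dists = np.concatenate([np.asarray(s.trial_adjusted_distances, float) for s in win])
        if angs.size == 0:
            continue
        if (
            med_succ >= min_successes
            and abs(float(np.median(angs))) < max_abs_angle
            and float(np.median(dists)) < max_distance
        ):
            return True, end
    return False, None
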