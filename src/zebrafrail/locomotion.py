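"""Open-field locomotor summaries.

The behavioral protocol records each fish for 20 minutes after a 3-minute
adaptation stage; the tracker emits a planar path from which three variables
are quantified: total distance traveled (cm), mean speed (cm/s) and maximum
speed (cm/s).

Definitions used here:

* total distance — sum of Euclidean step lengths along the polyline;
* mean speed — total distance divided by elapsed time, which is
  sampling-rate invariant (not the mean of per-step speeds);
* maximum speed — maximum per-step speed after an optional centered
  rolling-median smoothing (default window 3) that damps single-frame
  tracking jitter. ``smooth_window=1`` disables smoothing, in which case
  ``max_speed >= mean_speed`` holds exactly; an aggressive window on a
  path dominated by one brief burst can pull the reported maximum below
  the mean, which is reported as-is, never clamped.

Gaps in the recording appear as single long steps; no interpolation is done.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datatypes import LocomotorSummary, Trajectory
from .errors import ValidationError

DEFAULT_TRIM_S = 180.0  # adaptation stage discarded before scoring
DEFAULT_RECORD_S = 1200.0  # scored recording window
DEFAULT_SMOOTH_WINDOW = 3


def trim_adaptation(
    traj: Trajectory,
    trim_s: float = DEFAULT_TRIM_S,
    record_s: float = DEFAULT_RECORD_S,
) -> Trajectory:
    """Drop the adaptation stage and clip to the recording window.

    Keeps samples with time in ``[trim_s, trim_s + record_s)`` (measured
    from the first sample) and re-bases times to start at 0.
    """
    if trim_s < 0:
        raise ValidationError("trim_s must be >= 0")
    if record_s <= 0:
        raise ValidationError("record_s must be > 0")
    t0 = traj.t_s[0]
    rel = traj.t_s - t0
    keep = (rel >= trim_s) & (rel < trim_s + record_s)
    if keep.sum() < 2:
        raise ValidationError(
            f"fish {traj.fish_id!r}: fewer than 2 samples left after trimming "
            f"{trim_s} s (trajectory spans {traj.duration_s} s)"
        )
    t = rel[keep] - trim_s
    return Trajectory(traj.fish_id, t, traj.x_cm[keep], traj.y_cm[keep])


def step_speeds(traj: Trajectory) -> np.ndarray:
    """Per-step speeds (cm/s): Euclidean step length over step duration."""
    dx = np.diff(traj.x_cm)
    dy = np.diff(traj.y_cm)
    dt = np.diff(traj.t_s)
    return np.hypot(dx, dy) / dt


def summarize_trajectory(
    traj: Trajectory, smooth_window: int = DEFAULT_SMOOTH_WINDOW
) -> LocomotorSummary:
    """Compute the three locomotor variables for one trajectory.

    ``smooth_window`` is the odd width of the centered rolling median
    applied to per-step speeds before taking the maximum; 1 means none.
    """
    if len(traj) < 2:
        raise ValidationError(f"fish {traj.fish_id!r}: need >= 2 samples")
    if smooth_window < 1 or smooth_window % 2 == 0:
        raise ValidationError("smooth_window must be a positive odd integer")
    steps = np.hypot(np.diff(traj.x_cm), np.diff(traj.y_cm))
    dt = np.diff(traj.t_s)
    total = float(steps.sum())
    duration = traj.duration_s
    speeds = steps / dt
    if smooth_window > 1:
        speeds = (
            pd.Series(speeds)
            .rolling(smooth_window, center=True, min_periods=1)
            .median()
            .to_numpy()
        )
    return LocomotorSummary(
        fish_id=traj.fish_id,
        total_distance_cm=total,
        mean_speed_cms=total / duration,
        max_speed_cms=float(speeds.max()),
        duration_s=duration,
        n_samples=len(traj),
    )


@dataclass(frozen=True)
class BatchFailure:
    """Per-fish failure record from a batch run."""

    fish_id: str
    error: str


def batch_locomotion(
    trajs: list[Trajectory],
    trim_s: float | None = None,
    record_s: float = DEFAULT_RECORD_S,
    smooth_window: int = DEFAULT_SMOOTH_WINDOW,
) -> tuple[list[LocomotorSummary], list[BatchFailure]]:
    """Summarize a batch of trajectories, one summary per fish in input
    order. A failing fish yields a :class:`BatchFailure` instead of
    aborting the batch; an all-failed batch raises."""
    summaries: list[LocomotorSummary] = []
    failures: list[BatchFailure] = []
    for traj in trajs:
        try:
            if trim_s is not None:
                traj = trim_adaptation(traj, trim_s, record_s)
            summaries.append(summarize_trajectory(traj, smooth_window))
        except ValidationError as exc:
            failures.append(BatchFailure(fish_id=traj.fish_id, error=str(exc)))
    if trajs and not summaries:
        raise ValidationError(
            "all trajectories in the batch failed: "
            + "; ".join(f.error for f in failures[:3])
        )
    return summaries, failures
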