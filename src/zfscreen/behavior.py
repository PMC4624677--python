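"""Behavioural endpoints from a tracked (or simulated) trajectory.

The screen's per-animal endpoints are: the number of spontaneous movement
bouts, total swimming distance, vertical (top-half) occupancy and 2-D/3-D
trace maps. "Instance of movement" is operationalised here as a
threshold-crossing bout: a contiguous run of smoothed speed above
``speed_threshold`` lasting at least ``min_bout_duration``, with runs
separated by less than ``merge_gap`` merged into one episode.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .synth import ArenaSpec

__all__ = [
    "BoutParams",
    "MovementBout",
    "BehaviorSummary",
    "instantaneous_speed",
    "detect_bouts",
    "path_length",
    "summarize",
    "trace_map",
    "plot_trace_map",
]


@dataclass(frozen=True)
class BoutParams:
    speed_threshold: float = 2.0  # mm/s
    min_bout_duration: float = 0.12  # s
    merge_gap: float = 0.2  # s
    smoothing_window: int = 5  # frames, odd

    def __post_init__(self) -> None:
        if self.speed_threshold <= 0 or self.min_bout_duration <= 0:
            raise ValueError("speed_threshold and min_bout_duration must be > 0")
        if self.merge_gap <= 0:
            raise ValueError("merge_gap must be > 0")
        if self.smoothing_window < 1 or self.smoothing_window % 2 == 0:
            raise ValueError("smoothing_window must be a positive odd integer")


@dataclass(frozen=True)
class MovementBout:
    start_time: float
    end_time: float
    distance: float  # mm
    peak_speed: float  # mm/s

    def __post_init__(self) -> None:
        if self.end_time <= self.start_time:
            raise ValueError("end_time must exceed start_time")
        if self.distance < 0:
            raise ValueError("distance must be >= 0")


@dataclass(frozen=True)
class BehaviorSummary:
    bout_count: int
    total_distance: float  # cm
    top_half_fraction: float
    time_moving_fraction: float
    session_duration: float  # s

    def __post_init__(self) -> None:
        if not 0.0 <= self.top_half_fraction <= 1.0:
            raise ValueError("top_half_fraction must lie in [0, 1]")
        if not 0.0 <= self.time_moving_fraction <= 1.0:
            raise ValueError("time_moving_fraction must lie in [0, 1]")
        if self.total_distance < 0:
            raise ValueError("total_distance must be >= 0")


def instantaneous_speed(traj, smoothing_window: int = 5) -> np.ndarray:
    """Per-frame speed in mm/s: finite differences smoothed with a boxcar.

    ``speed[0]`` is 0 by convention; ``speed[i] = |pos[i] - pos[i-1]| / dt``.
    Works on any object with ``times`` and ``positions`` (tracked or
    ground-truth trajectories). Carried-forward frames have raw speed 0.
    """
    times = np.asarray(traj.times, dtype=float)
    pos = np.asarray(traj.positions, dtype=float)
    if len(times) < 2:
        raise ValueError("need at least 2 frames to compute speed")
    dt = np.diff(times)
    raw = np.zeros(len(times))
    raw[1:] = np.linalg.norm(np.diff(pos, axis=0), axis=1) / dt
    if smoothing_window > 1:
        if smoothing_window % 2 == 0:
            raise ValueError("smoothing_window must be odd")
        kern = np.ones(smoothing_window) / smoothing_window
        raw = np.convolve(raw, kern, mode="same")
    return raw


def detect_bouts(
    speeds: np.ndarray, fps: float, params: BoutParams | None = None
) -> list[MovementBout]:
    """Threshold-crossing movement bouts from a per-frame speed series.

    Runs of ``speed > speed_threshold`` separated by gaps shorter than
    ``merge_gap`` are merged, then runs shorter than ``min_bout_duration``
    are dropped. The result is non-overlapping, time-ordered and invariant
    under reversal of the speed sequence.
    """
    params = params or BoutParams()
    s = np.asarray(speeds, dtype=float)
    if np.any(s < 0):
        raise ValueError("speeds must be nonnegative")
    above = s > params.speed_threshold
    if not above.any():
        return []
    edges = np.diff(above.astype(np.int8))
    starts = np.nonzero(edges == 1)[0] + 1
    ends = np.nonzero(edges == -1)[0] + 1  # exclusive
    if above[0]:
        starts = np.concatenate([[0], starts])
    if above[-1]:
        ends = np.concatenate([ends, [len(s)]])

    # merge runs separated by less than the merge gap
    gap_frames = params.merge_gap * fps
    brk = np.flatnonzero(starts[1:] - ends[:-1] >= gap_frames)
    st = starts[np.concatenate([[0], brk + 1])]
    en = ends[np.concatenate([brk, [len(ends) - 1]])]

    keep = en - st >= params.min_bout_duration * fps
    st, en = st[keep], en[keep]
    if len(st) == 0:
        return []
    cums = np.concatenate([[0.0], np.cumsum(s)])
    dists = (cums[en] - cums[st]) / fps
    bounds = np.stack([st, np.minimum(en, len(s) - 1)], axis=1).ravel()
    peaks = np.maximum.reduceat(s, bounds)[::2]
    # reduceat cannot express an empty tail segment; fix runs ending at len(s)
    tail = en == len(s)
    if tail.any():
        peaks = peaks.copy()
        peaks[tail] = np.maximum(peaks[tail], s[-1])
    return [
        MovementBout(
            start_time=float(a / fps),
            end_time=float(b / fps),
            distance=float(d),
            peak_speed=float(p),
        )
        for a, b, d, p in zip(st, en, dists, peaks)
    ]


def path_length(traj, noise_floor: float = 0.1) -> float:
    """Total swimming distance in cm.

    Inter-frame displacements below ``noise_floor`` (mm) are ignored so that
    sub-pixel tracking jitter does not accumulate into spurious distance.
    """
    pos = np.asarray(traj.positions, dtype=float)
    if len(pos) < 2:
        return 0.0
    seg = np.linalg.norm(np.diff(pos, axis=0), axis=1)
    return float(seg[seg >= noise_floor].sum() / 10.0)


def summarize(
    traj,
    bouts: Sequence[MovementBout],
    arena: ArenaSpec,
    noise_floor: float = 0.1,
) -> BehaviorSummary:
    """Session-level summary feeding the group comparisons.

    The vertical coordinate is the trajectory's last axis (z for 3-D traces,
    the second axis for a side-view 2-D track); for top-view-only data the
    top-half fraction is not meaningful.
    """
    times = np.asarray(traj.times, dtype=float)
    pos = np.asarray(traj.positions, dtype=float)
    dt = float(np.median(np.diff(times))) if len(times) > 1 else 0.0
    duration = float(times[-1] - times[0]) + dt
    vertical = pos[:, -1]
    top_frac = float(np.mean(vertical > arena.well_height / 2.0))
    moving = sum(b.end_time - b.start_time for b in bouts)
    return BehaviorSummary(
        bout_count=len(bouts),
        total_distance=path_length(traj, noise_floor=noise_floor),
        top_half_fraction=top_frac,
        time_moving_fraction=min(1.0, moving / duration) if duration > 0 else 0.0,
        session_duration=duration,
    )


def trace_map(
    traj, arena: ArenaSpec, grid: tuple[int, ...] = (24, 24)
) -> tuple[np.ndarray, np.ndarray]:
    """Occupancy grid plus the trajectory polyline.

    Returns ``(occupancy, polyline)`` where occupancy counts sum to the
    number of trajectory samples and the polyline preserves sample order.
    ``grid`` is (nx, ny) for 2-D or (nx, ny, nz) for 3-D trajectories.
    """
    if any(g < 1 for g in grid):
        raise ValueError("grid dimensions must be >= 1")
    pos = np.asarray(traj.positions, dtype=float)
    ndim = min(len(grid), pos.shape[1])
    extents = [arena.well_width, arena.well_width, arena.well_height][:ndim]
    sample = np.clip(pos[:, :ndim], 0.0, extents)
    occupancy, _ = np.histogramdd(
        sample, bins=grid[:ndim], range=[(0.0, e) for e in extents]
    )
    return occupancy.astype(np.int64), pos.copy()


def plot_trace_map(traj, arena: ArenaSpec, path: str | None = None):
    """Render the session trace (red line) like a published trace map."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    pos = np.asarray(traj.positions, dtype=float)
    if pos.shape[1] >= 3:
        fig = plt.figure(figsize=(4, 4))
        ax = fig.add_subplot(projection="3d")
        ax.plot(pos[:, 0], pos[:, 1], pos[:, 2], color="red", lw=0.6)
        ax.set_zlim(0, arena.well_height)
        ax.set_zlabel("z (mm)")
    else:
        fig, ax = plt.subplots(figsize=(4, 4))
        ax.plot(pos[:, 0], pos[:, 1], color="red", lw=0.6)
        ax.set_aspect("equal")
    ax.set_xlim(0, arena.well_width)
    ax.set_ylim(0, arena.well_width)
    ax.set_xlabel("x (mm)")
    ax.set_ylabel("y (mm)")
    if path is not None:
        fig.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(fig)
    return fig
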