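"""Frame-differential video tracking of a single larva per well.

Motion is detected by thresholding the absolute difference of consecutive
frames and cleaning the mask morphologically; the largest connected
component, if large enough, marks the moving animal. Because differencing is
blind to a stationary target, frames without an accepted detection carry the
last known position forward (flagged ``detected=False``) — stillness
contributes exactly zero to path length rather than fabricated interpolated
distance.

Localisation: the centroid of the raw difference mask lags the animal by
half a step (the mask covers both the old and new blob footprints), so by
default the tracker refines each motion-gated candidate with an intensity-
weighted centroid of the dark blob in the *current* frame inside the
detected motion region. Detection stays purely differential; only the
sub-pixel localisation uses the current frame's intensities.

3-D traces are assembled by fusing two orthogonal views (top: x-y, side:
x-z) that share the x axis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import binary_closing, binary_opening
from skimage.measure import label as sk_label
from skimage.morphology import disk

from .synth import ArenaSpec, pixels_to_mm

__all__ = [
    "TrackerParams",
    "Trajectory",
    "frame_difference_mask",
    "detect_blob",
    "track_frames",
    "reconstruct_3d",
]


@dataclass(frozen=True)
class TrackerParams:
    """Tunable knobs of the frame-differential tracker.

    ``diff_threshold`` is in 8-bit gray levels; ``max_jump`` (mm per frame
    interval) is a physical plausibility gate — implausible detections are
    treated as no-detection (stillness).
    """

    diff_threshold: float = 10.0
    min_blob_area: int = 9
    morph_radius: int = 1
    max_jump: float = 50.0
    refine_centroid: bool = True

    def __post_init__(self) -> None:
        if self.diff_threshold < 1:
            raise ValueError("diff_threshold must be >= 1")
        if self.min_blob_area < 1:
            raise ValueError("min_blob_area must be >= 1")
        if self.morph_radius < 0:
            raise ValueError("morph_radius must be >= 0")
        if self.max_jump <= 0:
            raise ValueError("max_jump must be > 0")


@dataclass(frozen=True)
class Trajectory:
    """Tracked positions in mm, one sample per frame from frame 2 onward."""

    times: np.ndarray
    positions: np.ndarray  # (n, 2) or (n, 3), mm
    detected: np.ndarray  # bool; False = position carried forward
    calibration: float  # px per mm

    def __post_init__(self) -> None:
        if len(self.times) != len(self.positions) or len(self.times) != len(
            self.detected
        ):
            raise ValueError("times, positions and detected must align")
        if len(self.times) > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")

    @property
    def ndim(self) -> int:
        return self.positions.shape[1]

    @property
    def detection_rate(self) -> float:
        return float(np.mean(self.detected))


def frame_difference_mask(
    frame_t: np.ndarray, frame_prev: np.ndarray, params: TrackerParams
) -> np.ndarray:
    """Binary motion mask: |frame_t - frame_prev| > threshold, cleaned up.

    Cleanup is a morphological opening followed by closing with a disk of
    radius ``morph_radius`` (no cleanup when the radius is 0).
    """
    a = np.asarray(frame_t)
    b = np.asarray(frame_prev)
    if a.shape != b.shape or a.ndim != 2:
        raise ValueError("frames must be single-channel and share a shape")
    diff = np.abs(a.astype(np.int16) - b.astype(np.int16))
    mask = diff > params.diff_threshold
    if params.morph_radius > 0:
        footprint = disk(params.morph_radius).astype(bool)
        mask = binary_opening(mask, structure=footprint)
        mask = binary_closing(mask, structure=footprint)
    return mask


def detect_blob(
    mask: np.ndarray, params: TrackerParams
) -> tuple[tuple[float, float], float] | None:
    """Centroid (row, col) and area of the largest connected component.

    Returns ``None`` when no component reaches ``min_blob_area``.
    """
    labels = sk_label(mask, connectivity=2)
    if labels.max() == 0:
        return None
    areas = np.bincount(labels.ravel())
    areas[0] = 0
    best = int(np.argmax(areas))
    if areas[best] < params.min_blob_area:
        return None
    ys, xs = np.nonzero(labels == best)
    return (float(ys.mean()), float(xs.mean())), float(areas[best])


def _refine_centroid(
    frame_t: np.ndarray,
    centroid_rc: tuple[float, float],
    area: float,
    params: TrackerParams,
) -> tuple[float, float]:
    """Darkness-weighted centroid of the blob around a motion detection."""
    h, w = frame_t.shape
    margin = int(math.ceil(2.0 * math.sqrt(area / math.pi))) + 3
    r0 = max(0, int(centroid_rc[0]) - margin)
    r1 = min(h, int(centroid_rc[0]) + margin + 1)
    c0 = max(0, int(centroid_rc[1]) - margin)
    c1 = min(w, int(centroid_rc[1]) + margin + 1)
    roi = frame_t[r0:r1, c0:c1].astype(np.float64)
    bg = float(np.median(frame_t))
    wgt = np.clip(bg - roi, 0.0, None)
    wgt[wgt < params.diff_threshold] = 0.0
    total = wgt.sum()
    if total <= 0:
        return centroid_rc
    yy, xx = np.mgrid[r0:r1, c0:c1]
    return (float((wgt * yy).sum() / total), float((wgt * xx).sum() / total))


def track_frames(
    frames: np.ndarray,
    arena: ArenaSpec,
    params: TrackerParams | None = None,
    fps: float = 25.0,
    view: str = "top",
) -> Trajectory:
    """Track one animal through a frame stack.

    One position is produced per frame from the second frame onward (output
    length = frame count - 1, always). Frames without an accepted detection
    repeat the previous position (``detected=False``); frames before the
    first detection are back-filled with it. A sequence with no motion at all
    raises, since a never-moving target cannot be localised differentially.
    """
    params = params or TrackerParams()
    frames = np.asarray(frames)
    n = len(frames)
    if n < 2:
        raise ValueError("need at least 2 frames")
    if fps <= 0:
        raise ValueError("fps must be > 0")

    raw: list[tuple[float, float] | None] = []
    last_px: tuple[float, float] | None = None
    max_jump_px = params.max_jump * arena.px_per_mm
    for t in range(1, n):
        mask = frame_difference_mask(frames[t], frames[t - 1], params)
        det = detect_blob(mask, params)
        pos = None
        if det is not None:
            centroid, area = det
            if params.refine_centroid:
                centroid = _refine_centroid(frames[t], centroid, area, params)
            if last_px is None or math.hypot(
                centroid[0] - last_px[0], centroid[1] - last_px[1]
            ) <= max_jump_px:
                pos = centroid
        if pos is not None:
            last_px = pos
        raw.append(pos)

    detected = np.array([p is not None for p in raw], dtype=bool)
    if not detected.any():
        raise ValueError("no motion detected in the entire sequence")

    first = int(np.argmax(detected))
    filled: list[tuple[float, float]] = []
    current = raw[first]
    for t in range(n - 1):
        if t < first:
            filled.append(raw[first])
        else:
            if raw[t] is not None:
                current = raw[t]
            filled.append(current)
    rows = np.array([p[0] for p in filled])
    cols = np.array([p[1] for p in filled])
    positions = pixels_to_mm(cols, rows, arena, view=view)
    times = np.arange(1, n) / fps
    return Trajectory(
        times=times,
        positions=positions,
        detected=detected,
        calibration=arena.px_per_mm,
    )


def reconstruct_3d(
    top: Trajectory, side: Trajectory, x_tolerance: float = 1.0
) -> Trajectory:
    """Fuse a top view (x, y) and a side view (x, z) into a 3-D trajectory.

    The shared x coordinate is averaged across views; frames where the two
    views disagree in x by more than ``x_tolerance`` (mm) are flagged and
    linearly interpolated from consistent neighbours. Raises if every frame
    is inconsistent or the timestamps differ.
    """
    if len(top.times) != len(side.times) or not np.allclose(
        top.times, side.times, rtol=0, atol=1e-9
    ):
        raise ValueError("top and side trajectories must share timestamps")
    x_top = top.positions[:, 0]
    y = top.positions[:, 1]
    x_side = side.positions[:, 0]
    z = side.positions[:, 1]
    inconsistent = np.abs(x_top - x_side) > x_tolerance
    if inconsistent.all():
        raise ValueError(
            "100% of frames exceed the x tolerance: views are inconsistent"
        )
    x = 0.5 * (x_top + x_side)
    if inconsistent.any():
        good = np.nonzero(~inconsistent)[0]
        idx = np.arange(len(x))
        x = x.copy()
        y = y.copy()
        z = z.copy()
        for arr in (x, y, z):
            arr[inconsistent] = np.interp(idx[inconsistent], good, arr[good])
    detected = top.detected & side.detected & ~inconsistent
    positions = np.column_stack([x, y, z])
    return Trajectory(
        times=top.times.copy(),
        positions=positions,
        detected=detected,
        calibration=top.calibration,
    )
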