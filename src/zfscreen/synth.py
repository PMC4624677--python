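"""Synthetic-data generators with known ground truth.

This module emulates the three raw-data classes of a larval-zebrafish
anti-epileptic drug screen so that every downstream analysis stage can be
validated without any recordings:

* single-larva locomotor sessions (two-state still/bout renewal process with a
  correlated random walk during bouts) and rendered well videos,
* micropipette-aspiration recordings of the chorion membrane (linear
  pressure-length samples plus a saturating-exponential shear-force trace),
* developmental-outcome cohorts (per-replicate hatched/dead counts by day).

Presets named after the screen's treatment arms (``control``, ``ptz20``,
``vpa025`` ... ``vpa10``, ``ptz40``) are calibrated so that the mean of the
relevant ground-truth metric matches the condition means reported for the
original screen (e.g. ~832.7 movement bouts and ~931.4 cm swum per 30-min
PTZ-20 session, < 10 cm for controls, chorion force time-to-peak
240/177/149 ms for control / PTZ 20 / PTZ 40 mmol/L).

All randomness flows from one integer seed through named sub-streams
(:mod:`zfscreen._rng`), so identical seeds give bit-identical outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from ._rng import substream
from .chorion import AspirationRecording

__all__ = [
    "BehaviorParams",
    "ArenaSpec",
    "GroundTruthTrajectory",
    "AspirationGroundTruth",
    "simulate_trajectory",
    "render_video",
    "project_to_pixels",
    "pixels_to_mm",
    "simulate_aspiration",
    "simulate_cohort",
    "calibrate_locomotor_preset",
    "BEHAVIOR_PRESETS",
    "ASPIRATION_PRESETS",
    "COHORT_PRESETS",
    "VPA_DOSES_MM",
]

# Shape factor and Poisson ratio of the elastic half-space aspiration model;
# shared with zfscreen.chorion (incompressible membrane, nu = 0.5).
PHI_DEFAULT = 2.1


# ---------------------------------------------------------------------------
# Parameter containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BehaviorParams:
    """Parameters of the two-state (still/bout) locomotor model.

    ``bout_rate`` is the expected number of bout onsets per minute of session;
    ``speed_mean``/``speed_sd`` describe the per-frame swim speed (mm/s) while
    in a bout. ``bout_duration_min`` and ``still_duration_min`` are refractory
    minima: a bout is at least a few tail beats long and bouts are separated
    by a minimum quiescent interval, which keeps bout episodes well defined
    for downstream detection.
    """

    bout_rate: float
    bout_duration_mean: float = 1.0
    speed_mean: float = 2.0
    speed_sd: float = 0.5
    turn_sd: float = 0.6
    top_half_bias: float = 0.0
    session_duration: float = 1800.0
    fps: float = 25.0
    bout_duration_min: float = 0.2
    still_duration_min: float = 0.4
    vertical_step_fraction: float = 0.6

    def __post_init__(self) -> None:
        if self.fps <= 0:
            raise ValueError("fps must be > 0")
        if self.session_duration <= 0:
            raise ValueError("session_duration must be > 0")
        for name in (
            "bout_rate",
            "bout_duration_mean",
            "speed_mean",
            "speed_sd",
            "turn_sd",
            "bout_duration_min",
            "still_duration_min",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0.0 <= self.top_half_bias <= 1.0:
            raise ValueError("top_half_bias must lie in [0, 1]")
        if not 0.0 < self.vertical_step_fraction <= 1.0:
            raise ValueError("vertical_step_fraction must lie in (0, 1]")
        if self.bout_rate > 0 and self.bout_duration_mean < self.bout_duration_min:
            raise ValueError("bout_duration_mean must be >= bout_duration_min")

    @property
    def n_frames(self) -> int:
        return int(round(self.session_duration * self.fps))


@dataclass(frozen=True)
class ArenaSpec:
    """Geometry of one well plus the camera calibration.

    ``well_width`` is the horizontal extent (mm, square well assumed, matching
    one well of a 48-well plate), ``well_height`` the vertical water column
    used for 3-D traces. The well is centred in the image; ``px_per_mm``
    converts between the two coordinate systems.
    """

    well_width: float = 11.0
    well_height: float = 15.0
    px_per_mm: float = 8.0
    image_width: int = 112
    image_height: int = 144

    def __post_init__(self) -> None:
        if self.px_per_mm <= 0:
            raise ValueError("px_per_mm must be > 0")
        if self.image_width < 16 or self.image_height < 16:
            raise ValueError("image dimensions must be >= 16 px")
        if self.well_width <= 0 or self.well_height <= 0:
            raise ValueError("well dimensions must be > 0")


@dataclass(frozen=True)
class GroundTruthTrajectory:
    """A simulated session: positions in mm plus the generating state sequence.

    ``state_sequence`` is a boolean array, ``True`` on frames where the larva
    is in a swim bout. The ground-truth bout count and path length are
    recomputable from ``state_sequence`` and ``positions``.
    """

    times: np.ndarray
    positions: np.ndarray  # (n, 2) or (n, 3), mm
    state_sequence: np.ndarray  # (n,) bool, True = bout
    seed: int

    def __post_init__(self) -> None:
        if len(self.times) != len(self.positions) or len(self.times) != len(
            self.state_sequence
        ):
            raise ValueError("times, positions and state_sequence must align")
        if len(self.times) > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")

    @property
    def ndim(self) -> int:
        return self.positions.shape[1]

    @property
    def bout_count(self) -> int:
        """Number of still-to-bout onsets (a bout in progress at t=0 counts)."""
        m = self.state_sequence
        onsets = int(np.count_nonzero(m[1:] & ~m[:-1]))
        return onsets + int(bool(m[0]))

    @property
    def path_length_mm(self) -> float:
        return float(np.sum(np.linalg.norm(np.diff(self.positions, axis=0), axis=1)))

    def top_half_fraction(self, well_height: float) -> float:
        """Fraction of frames spent in the upper half of the water column."""
        if self.ndim < 3:
            raise ValueError("trajectory has no vertical (z) coordinate")
        return float(np.mean(self.positions[:, 2] > well_height / 2.0))


@dataclass(frozen=True)
class AspirationGroundTruth:
    """Ground truth for one simulated aspiration recording.

    ``pressure_slope_vs_length`` is the slope of the linear P-L relation
    implied by the shear modulus under the elastic half-space model
    (G = phi * R_p * slope / (2 pi) at nu = 0.5). ``rise_time_constant`` sets
    the saturating-exponential force rise F(t) = 1 - exp(-t / tau); the
    time-to-peak at the q = 0.99 criterion is tau * ln(100).
    """

    shear_modulus: float
    pipette_radius: float
    pressure_slope_vs_length: float
    rise_time_constant: float
    sampling_interval: float = 1e-3
    noise_sd: float = 0.0

    def __post_init__(self) -> None:
        for name in (
            "shear_modulus",
            "pipette_radius",
            "pressure_slope_vs_length",
            "rise_time_constant",
            "sampling_interval",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    @classmethod
    def from_modulus(
        cls,
        shear_modulus: float,
        time_to_peak: float,
        pipette_radius: float = 25e-6,
        sampling_interval: float = 1e-3,
        noise_sd: float = 0.0,
        phi: float = PHI_DEFAULT,
        peak_fraction: float = 0.99,
    ) -> "AspirationGroundTruth":
        """Build ground truth from a shear modulus and a target time-to-peak."""
        slope = 2.0 * math.pi * shear_modulus / (phi * pipette_radius)
        tau = time_to_peak / math.log(1.0 / (1.0 - peak_fraction))
        return cls(
            shear_modulus=shear_modulus,
            pipette_radius=pipette_radius,
            pressure_slope_vs_length=slope,
            rise_time_constant=tau,
            sampling_interval=sampling_interval,
            noise_sd=noise_sd,
        )


# ---------------------------------------------------------------------------
# Locomotor trajectory simulation
# ---------------------------------------------------------------------------


def _fold(x: np.ndarray, lo: float, hi: float) -> np.ndarray:
    """Mirror-fold unconstrained coordinates into [lo, hi] (specular walls)."""
    w = hi - lo
    y = np.mod(x - lo, 2.0 * w)
    return lo + w - np.abs(w - y)


def _draw_state_segments(
    params: BehaviorParams, n_frames: int, rng: np.random.Generator
):
    """Alternating still/bout segment lengths (frames) covering the session.

    Each segment is a refractory minimum plus a geometric tail, so segment
    means equal the values implied by ``bout_rate`` and ``bout_duration_mean``
    exactly at frame resolution.
    """
    fps = params.fps
    bout_mean_f = params.bout_duration_mean * fps
    cycle_f = 60.0 * fps / params.bout_rate
    still_mean_f = cycle_f - bout_mean_f
    b_min = max(1, int(round(params.bout_duration_min * fps)))
    s_min = max(1, int(round(params.still_duration_min * fps)))
    if bout_mean_f < b_min:
        raise ValueError("bout_duration_mean shorter than bout_duration_min")
    if still_mean_f <= s_min:
        raise ValueError(
            "bout_rate too high: mean inter-bout interval falls below the "
            "still refractory minimum"
        )
    p_b = 1.0 / (bout_mean_f - b_min + 1.0)
    p_s = 1.0 / (still_mean_f - s_min + 1.0)

    still_lens: list[np.ndarray] = []
    bout_lens: list[np.ndarray] = []
    covered = 0
    while covered < n_frames:
        k = max(16, int(math.ceil(1.5 * (n_frames - covered) / cycle_f)) + 8)
        s = s_min + rng.geometric(p_s, k) - 1
        b = b_min + rng.geometric(p_b, k) - 1
        still_lens.append(s)
        bout_lens.append(b)
        covered += int(np.sum(s) + np.sum(b))
    return np.concatenate(still_lens), np.concatenate(bout_lens)


def simulate_trajectory(
    params: BehaviorParams, arena: ArenaSpec, seed: int
) -> GroundTruthTrajectory:
    """Simulate one larval session as a 3-D trajectory with known states.

    The larva alternates between stillness (zero displacement, resting at the
    bottom) and swim bouts (correlated random walk at ``speed_mean`` mm/s with
    heading diffusion ``turn_sd`` per frame). Per bout, a target depth is
    drawn in the upper half of the water column with probability
    ``top_half_bias``; part of each step's length budget moves the larva
    toward that depth, the remainder is horizontal, so the 3-D step length
    equals the drawn speed times the frame interval. Walls are specular
    (mirror folding).
    """
    n = params.n_frames
    dt = 1.0 / params.fps
    rng = substream(seed, "trajectory")
    times = np.arange(n) * dt
    W, H = arena.well_width, arena.well_height

    if params.bout_rate <= 0:
        x0 = rng.uniform(0.0, W)
        y0 = rng.uniform(0.0, W)
        pos = np.column_stack(
            [np.full(n, x0), np.full(n, y0), np.zeros(n)]
        )
        return GroundTruthTrajectory(
            times=times,
            positions=pos,
            state_sequence=np.zeros(n, dtype=bool),
            seed=seed,
        )

    still_lens, bout_lens = _draw_state_segments(params, n, rng)

    # Interleave still/bout segments, truncate at the session end.
    lens = np.empty(2 * len(still_lens), dtype=np.int64)
    lens[0::2] = still_lens
    lens[1::2] = bout_lens
    ends = np.cumsum(lens)
    last = int(np.searchsorted(ends, n))
    lens = lens[: last + 1].copy()
    lens[-1] -= int(ends[last]) - n
    moving = np.repeat((np.arange(len(lens)) % 2).astype(bool), lens)

    k = int(np.count_nonzero(moving))
    speeds = np.zeros(n)
    if k:
        speeds[moving] = np.clip(
            rng.normal(params.speed_mean, params.speed_sd, k), 0.0, None
        )
    step_len = speeds * dt

    # Headings: reset uniformly at each bout onset, then diffuse.
    bout_seg_lens = lens[1::2]
    bout_seg_lens = bout_seg_lens[bout_seg_lens > 0]
    n_bouts = len(bout_seg_lens)
    dz = np.zeros(n)
    dx = np.zeros(n)
    dy = np.zeros(n)
    if n_bouts:
        dtheta = rng.normal(0.0, params.turn_sd, k)
        theta0 = rng.uniform(-math.pi, math.pi, n_bouts)
        starts_m = np.concatenate([[0], np.cumsum(bout_seg_lens)[:-1]])
        c = np.cumsum(dtheta)
        offset = np.repeat(c[starts_m] - theta0, bout_seg_lens)
        theta_m = c - offset

        # Vertical dynamics: per-bout target depth, approached with up to
        # vertical_step_fraction of each step's length budget.
        top = rng.uniform(0.0, 1.0, n_bouts) < params.top_half_bias
        z_targets = np.where(
            top,
            rng.uniform(H / 2.0, H, n_bouts),
            rng.uniform(0.0, H / 2.0, n_bouts),
        )
        L_m = step_len[moving]
        beta = params.vertical_step_fraction
        seg_id = np.repeat(np.arange(n_bouts), bout_seg_lens)
        seg_ends = np.cumsum(bout_seg_lens)
        cs = np.cumsum(beta * L_m)
        cs0 = np.concatenate([[0.0], cs[seg_ends[:-1] - 1]])
        within = cs - cs0[seg_id]  # cumulative vertical budget inside each bout
        budget_total = within[seg_ends - 1]
        # scalar recurrence: each bout starts where the previous one left off
        z0 = np.empty(n_bouts)
        deltas = np.empty(n_bouts)
        z_cur = 0.0
        for j in range(n_bouts):
            z0[j] = z_cur
            d = z_targets[j] - z_cur
            deltas[j] = d
            z_cur += math.copysign(1.0, d) * min(budget_total[j], abs(d))
        adv = np.minimum(within, np.abs(deltas)[seg_id])
        z_m = z0[seg_id] + np.sign(deltas)[seg_id] * adv
        dz_m = np.empty(k)
        dz_m[1:] = np.diff(z_m)
        dz_m[starts_m] = z_m[starts_m] - z0
        h_m = np.sqrt(np.maximum(L_m**2 - dz_m**2, 0.0))
        dz[moving] = dz_m
        dx[moving] = h_m * np.cos(theta_m)
        dy[moving] = h_m * np.sin(theta_m)

    x0 = rng.uniform(0.0, W)
    y0 = rng.uniform(0.0, W)
    x = _fold(x0 + np.cumsum(dx), 0.0, W)
    y = _fold(y0 + np.cumsum(dy), 0.0, W)
    z = np.clip(np.cumsum(dz), 0.0, H)
    pos = np.column_stack([x, y, z])
    return GroundTruthTrajectory(
        times=times, positions=pos, state_sequence=moving, seed=seed
    )


# ---------------------------------------------------------------------------
# Video rendering
# ---------------------------------------------------------------------------


def project_to_pixels(
    positions: np.ndarray, arena: ArenaSpec, view: str = "top"
) -> tuple[np.ndarray, np.ndarray]:
    """Map mm positions to pixel (col, row) for the given camera view.

    The well is centred in the image; the vertical image axis is flipped so
    that larger y (top view) / larger z (side view) is higher in the image.
    """
    if view == "top":
        u, v = positions[:, 0], positions[:, 1]
        extent_v = arena.well_width
    elif view == "side":
        if positions.shape[1] < 3:
            raise ValueError("side view requires a z coordinate")
        u, v = positions[:, 0], positions[:, 2]
        extent_v = arena.well_height
    else:
        raise ValueError(f"unknown view {view!r}")
    ppm = arena.px_per_mm
    mx = (arena.image_width - 1 - arena.well_width * ppm) / 2.0
    my = (arena.image_height - 1 - extent_v * ppm) / 2.0
    col = mx + u * ppm
    row = my + (extent_v - v) * ppm
    return col, row


def pixels_to_mm(
    cols: np.ndarray, rows: np.ndarray, arena: ArenaSpec, view: str = "top"
) -> np.ndarray:
    """Inverse of :func:`project_to_pixels`; returns (n, 2) mm coordinates."""
    extent_v = arena.well_width if view == "top" else arena.well_height
    ppm = arena.px_per_mm
    mx = (arena.image_width - 1 - arena.well_width * ppm) / 2.0
    my = (arena.image_height - 1 - extent_v * ppm) / 2.0
    u = (np.asarray(cols) - mx) / ppm
    v = extent_v - (np.asarray(rows) - my) / ppm
    return np.column_stack([u, v])


BACKGROUND_GRAY = 235.0
BLOB_DEPTH = 195.0


def render_video(
    traj: GroundTruthTrajectory,
    arena: ArenaSpec,
    blob_radius: float = 4.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    view: str = "top",
    axis_ratio: float = 1.0,
    flicker: float = 0.0,
) -> np.ndarray:
    """Render a session as a uint8 grayscale frame stack (n, height, width).

    The larva is a dark elliptical Gaussian blob (sigma = blob_radius / 1.5,
    optionally elongated along the heading by ``axis_ratio``) on a light
    background, with optional additive pixel noise and global illumination
    flicker (1 Hz sinusoidal gain). Memory is n * height * width bytes, so
    render short clips, not full 30-min sessions.
    """
    cols, rows = project_to_pixels(traj.positions, arena, view=view)
    sigma = blob_radius / 1.5
    r_cut = int(math.ceil(3.0 * sigma * math.sqrt(max(axis_ratio, 1.0))))
    h, w = arena.image_height, arena.image_width
    bad = np.nonzero(
        (cols - r_cut < 0)
        | (cols + r_cut > w - 1)
        | (rows - r_cut < 0)
        | (rows + r_cut > h - 1)
    )[0]
    if len(bad):
        shown = ", ".join(str(i) for i in bad[:10])
        more = "" if len(bad) <= 10 else f" (+{len(bad) - 10} more)"
        raise ValueError(f"blob out of frame at frame indices: {shown}{more}")

    n = len(cols)
    rng = substream(seed, "render")
    frames = np.full((n, h, w), BACKGROUND_GRAY, dtype=np.float64)

    if axis_ratio != 1.0:
        d = np.diff(np.column_stack([cols, rows]), axis=0)
        angles = np.zeros(n)
        ang = 0.0
        for i in range(1, n):
            if np.hypot(*d[i - 1]) > 1e-9:
                ang = math.atan2(d[i - 1][1], d[i - 1][0])
            angles[i] = ang
        angles[0] = angles[1] if n > 1 else 0.0
        s_major = sigma * math.sqrt(axis_ratio)
        s_minor = sigma / math.sqrt(axis_ratio)
    for i in range(n):
        cx, cy = cols[i], rows[i]
        c0, c1 = int(math.floor(cx)) - r_cut, int(math.ceil(cx)) + r_cut + 1
        r0, r1 = int(math.floor(cy)) - r_cut, int(math.ceil(cy)) + r_cut + 1
        yy, xx = np.mgrid[r0:r1, c0:c1]
        ux, uy = xx - cx, yy - cy
        if axis_ratio != 1.0:
            ca, sa = math.cos(angles[i]), math.sin(angles[i])
            a = ux * ca + uy * sa
            b = -ux * sa + uy * ca
            g = np.exp(-0.5 * ((a / s_major) ** 2 + (b / s_minor) ** 2))
        else:
            g = np.exp(-0.5 * (ux**2 + uy**2) / sigma**2)
        frames[i, r0:r1, c0:c1] -= BLOB_DEPTH * g

    if flicker > 0:
        gain = 1.0 + flicker * np.sin(2.0 * math.pi * 1.0 * traj.times)
        frames *= gain[:, None, None]
    if noise_sd > 0:
        frames += rng.normal(0.0, noise_sd, frames.shape)
    return np.clip(np.round(frames), 0, 255).astype(np.uint8)


# ---------------------------------------------------------------------------
# Aspiration and cohort simulation
# ---------------------------------------------------------------------------


def simulate_aspiration(
    gt: AspirationGroundTruth, n_pressure_steps: int = 10, seed: int = 0
) -> AspirationRecording:
    """Simulate one micropipette-aspiration recording.

    The pressure protocol is a deterministic increasing ramp; the measured
    tongue length at each step lies on the line implied by the shear modulus,
    corrupted by multiplicative noise of fractional sd ``noise_sd``. The force
    trace is a saturating exponential F(t) = 1 - exp(-t / tau) sampled at
    ``sampling_interval`` over 12 tau, with additive noise of the same
    fractional sd.
    """
    if n_pressure_steps < 3:
        raise ValueError("n_pressure_steps must be >= 3")
    rng = substream(seed, "aspiration")
    slope = gt.pressure_slope_vs_length
    l_max = 0.5 * gt.pipette_radius
    pressures = np.linspace(slope * l_max / n_pressure_steps, slope * l_max,
                            n_pressure_steps)
    lengths = pressures / slope
    if gt.noise_sd > 0:
        lengths = lengths * (1.0 + rng.normal(0.0, gt.noise_sd, n_pressure_steps))
        lengths = np.clip(lengths, 0.0, None)
    tau = gt.rise_time_constant
    t = np.arange(0.0, 12.0 * tau, gt.sampling_interval)
    forces = 1.0 - np.exp(-t / tau)
    if gt.noise_sd > 0:
        forces = forces + rng.normal(0.0, gt.noise_sd, len(t))
    return AspirationRecording(
        pressures=pressures,
        lengths=lengths,
        force_times=t,
        forces=forces,
        pipette_radius=gt.pipette_radius,
    )


def simulate_cohort(
    n_embryos: int,
    n_replicates: int,
    hatch_prob_by_day: Mapping[int, float],
    death_prob_by_day: Mapping[int, float],
    seed: int = 0,
    condition: str = "cohort",
):
    """Simulate per-replicate hatched/dead counts by day.

    Probabilities are cumulative marginal fractions of all treated embryos
    (``hatch_prob_by_day[d]`` is the expected fraction of embryos hatched and
    alive at day d). Death precludes hatching in the per-day accounting, so
    ``hatch + death <= 1`` is required for every day. Each embryo carries one
    death threshold and one hatch threshold, making outcomes consistent
    across days.

    Returns a tidy :class:`pandas.DataFrame` with columns
    (replicate, condition, day, n_treated, n_hatched, n_dead).
    """
    import pandas as pd

    if n_embryos <= 0 or n_replicates <= 0:
        raise ValueError("n_embryos and n_replicates must be positive")
    days = sorted(hatch_prob_by_day)
    if sorted(death_prob_by_day) != days:
        raise ValueError("hatch and death probability maps must share days")
    h = np.array([hatch_prob_by_day[d] for d in days], dtype=float)
    dth = np.array([death_prob_by_day[d] for d in days], dtype=float)
    if np.any((h < 0) | (h > 1) | (dth < 0) | (dth > 1)):
        raise ValueError("probabilities must lie in [0, 1]")
    if np.any(np.diff(h) < 0) or np.any(np.diff(dth) < 0):
        raise ValueError("cumulative probabilities must be non-decreasing")
    if np.any(h + dth > 1.0 + 1e-12):
        raise ValueError("hatch + death probability exceeds 1 for some day")

    rng = substream(seed, "cohort")
    rows = []
    for rep in range(1, n_replicates + 1):
        u_death = rng.uniform(0.0, 1.0, n_embryos)
        u_hatch = rng.uniform(0.0, 1.0, n_embryos)
        for d, hp, dp in zip(days, h, dth):
            dead = u_death < dp
            h_cond = hp / (1.0 - dp) if dp < 1.0 else 0.0
            hatched = (~dead) & (u_hatch < h_cond)
            rows.append(
                {
                    "replicate": rep,
                    "condition": condition,
                    "day": int(d),
                    "n_treated": n_embryos,
                    "n_hatched": int(np.count_nonzero(hatched)),
                    "n_dead": int(np.count_nonzero(dead)),
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Presets calibrated to the reported condition means
# ---------------------------------------------------------------------------

# PTZ 20 mmol/L targets: 832.7 bouts and 931.4 cm over a 30-min session.
_PTZ_TARGET_BOUTS = 832.7
_PTZ_TARGET_DISTANCE_CM = 931.4

# Calibrated constants for the ptz20 preset (see calibrate_locomotor_preset;
# frozen from a 2000-session calibration run with internal seeds). The speed
# exceeds the naive target-distance/moving-time ratio by the mean path loss at
# specular wall folds in an 11 mm well.
_PTZ_BOUT_RATE = 27.760884  # onsets / min
_PTZ_SPEED_MEAN = 11.315285  # mm/s

VPA_DOSES_MM = (0.25, 0.5, 0.75, 1.0)
_VPA_RESCUE_FRACTIONS = {0.25: 0.1, 0.5: 0.45, 0.75: 0.8, 1.0: 1.0}


def _control_params() -> BehaviorParams:
    return BehaviorParams(
        bout_rate=0.2,
        bout_duration_mean=1.0,
        speed_mean=2.0,
        speed_sd=0.5,
        top_half_bias=0.02,
    )


def _ptz20_params() -> BehaviorParams:
    return BehaviorParams(
        bout_rate=_PTZ_BOUT_RATE,
        bout_duration_mean=1.0,
        speed_mean=_PTZ_SPEED_MEAN,
        speed_sd=2.0,
        top_half_bias=0.5,
    )


def _vpa_params(dose: float) -> BehaviorParams:
    """VPA rescue presets: linear interpolation from ptz20 toward control.

    The rescue fraction per dose follows the graded pattern of the screen
    (no visible change at 0.25 mmol/L, full rescue at 1.0 mmol/L).
    """
    f = _VPA_RESCUE_FRACTIONS[dose]
    ctrl, ptz = _control_params(), _ptz20_params()
    return BehaviorParams(
        bout_rate=ptz.bout_rate + f * (ctrl.bout_rate - ptz.bout_rate),
        bout_duration_mean=1.0,
        speed_mean=ptz.speed_mean + f * (ctrl.speed_mean - ptz.speed_mean),
        speed_sd=ptz.speed_sd + f * (ctrl.speed_sd - ptz.speed_sd),
        top_half_bias=ptz.top_half_bias + f * (ctrl.top_half_bias - ptz.top_half_bias),
    )


BEHAVIOR_PRESETS: dict[str, BehaviorParams] = {
    "control": _control_params(),
    "ptz20": _ptz20_params(),
    "vpa025": _vpa_params(0.25),
    "vpa05": _vpa_params(0.5),
    "vpa075": _vpa_params(0.75),
    "vpa10": _vpa_params(1.0),
}

# Chorion presets: time-to-peak 240 / 177 / 149 ms for control / PTZ 20 /
# PTZ 40 mmol/L; moduli at a plausible chorion scale, equal across PTZ
# concentrations (the screen saw no stiffness differences between doses).
ASPIRATION_PRESETS: dict[str, AspirationGroundTruth] = {
    "control": AspirationGroundTruth.from_modulus(0.5e6, time_to_peak=0.240),
    "ptz20": AspirationGroundTruth.from_modulus(0.75e6, time_to_peak=0.177),
    "ptz40": AspirationGroundTruth.from_modulus(0.75e6, time_to_peak=0.149),
}

# Cohort presets: marginal hatched/dead fractions by day (dpf). Control and
# ptz40 hatch values are the reported means; ptz20 hatch is not reported
# (only "not significantly different from control") and is set to the largest
# values consistent with exclusive hatched/dead accounting.
COHORT_PRESETS: dict[str, dict[str, dict[int, float]]] = {
    "control": {"hatch": {3: 0.786, 5: 0.871}, "death": {3: 0.10, 5: 0.129}},
    "ptz20": {"hatch": {3: 0.75, 5: 0.78}, "death": {3: 0.208, 5: 0.22}},
    "ptz40": {"hatch": {3: 0.05, 5: 0.683}, "death": {3: 0.301, 5: 0.316}},
}


def calibrate_locomotor_preset(
    target_bouts: float = _PTZ_TARGET_BOUTS,
    target_distance_cm: float = _PTZ_TARGET_DISTANCE_CM,
    n_sessions: int = 500,
    seed: int = 321_000,
    arena: ArenaSpec | None = None,
) -> BehaviorParams:
    """One-step Monte-Carlo calibration of the hyperactive preset.

    Starts from the analytic parameter guesses (onset rate = target bouts per
    session minute; speed = target distance / expected moving time), measures
    the realized ground-truth means over ``n_sessions`` simulated sessions,
    and applies a multiplicative correction. This absorbs frame-quantisation
    of segment lengths, session-edge truncation and the small path shortening
    at specular wall folds. The shipped ``ptz20`` preset constants were frozen
    from this routine at n_sessions=2000.
    """
    arena = arena or ArenaSpec()
    rate0 = target_bouts / 30.0
    speed0 = target_distance_cm * 10.0 / target_bouts  # mm per bout-second
    params = BehaviorParams(
        bout_rate=rate0, bout_duration_mean=1.0, speed_mean=speed0,
        speed_sd=2.0, top_half_bias=0.5,
    )
    counts = np.empty(n_sessions)
    dists = np.empty(n_sessions)
    for i in range(n_sessions):
        t = simulate_trajectory(params, arena, seed=seed + i)
        counts[i] = t.bout_count
        dists[i] = t.path_length_mm
    rate1 = rate0 * target_bouts / counts.mean()
    speed1 = speed0 * (target_distance_cm * 10.0 / dists.mean()) * (
        counts.mean() / target_bouts
    )
    return BehaviorParams(
        bout_rate=rate1, bout_duration_mean=1.0, speed_mean=speed1,
        speed_sd=2.0, top_half_bias=0.5,
    )
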