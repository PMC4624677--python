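"""Synthetic-data generator: ground-truth bookkeeping, calibration, rendering."""

import dataclasses

import numpy as np
import pytest

from zfscreen import synth
from zfscreen.synth import (
    ArenaSpec,
    BehaviorParams,
    project_to_pixels,
    render_video,
    simulate_aspiration,
    simulate_cohort,
    simulate_trajectory,
)


def _transition_count(states: np.ndarray) -> int:
    """Brute-force oracle: count still->bout transitions frame by frame."""
    count = 1 if states[0] else 0
    for prev, cur in zip(states[:-1], states[1:]):
        if cur and not prev:
            count += 1
    return count


class TestSimulateTrajectory:
    def test_no_motion_limit(self, arena):
        params = BehaviorParams(bout_rate=0.0, session_duration=10.0)
        t = simulate_trajectory(params, arena, seed=3)
        assert t.bout_count == 0
        assert t.path_length_mm == 0.0
        assert not t.state_sequence.any()

    def test_bout_count_equals_transition_oracle(self, arena):
        params = BehaviorParams(bout_rate=2.0, speed_mean=5.0)
        t = simulate_trajectory(params, arena, seed=11)
        assert t.bout_count == _transition_count(t.state_sequence)

    def test_mean_bout_count_matches_renewal_expectation(self, arena):
        # 2 bouts/min over 30 min => 60 expected onsets per session
        params = BehaviorParams(bout_rate=2.0, speed_mean=5.0)
        counts = np.array(
            [simulate_trajectory(params, arena, seed=s).bout_count for s in range(200)]
        )
        se = counts.std(ddof=1) / np.sqrt(len(counts))
        assert abs(counts.mean() - 60.0) < 3.0 * se

    def test_determinism_bit_identical(self, arena):
        params = synth.BEHAVIOR_PRESETS["ptz20"]
        a = simulate_trajectory(params, arena, seed=7)
        b = simulate_trajectory(params, arena, seed=7)
        assert np.array_equal(a.positions, b.positions)
        assert np.array_equal(a.state_sequence, b.state_sequence)
        c = simulate_trajectory(params, arena, seed=8)
        assert not np.array_equal(a.positions, c.positions)

    def test_positions_stay_inside_arena(self, arena):
        params = dataclasses.replace(
            synth.BEHAVIOR_PRESETS["ptz20"], session_duration=120.0
        )
        t = simulate_trajectory(params, arena, seed=2)
        assert t.positions[:, 0].min() >= 0 and t.positions[:, 0].max() <= arena.well_width
        assert t.positions[:, 1].min() >= 0 and t.positions[:, 1].max() <= arena.well_width
        assert t.positions[:, 2].min() >= 0 and t.positions[:, 2].max() <= arena.well_height

    def test_still_frames_do_not_move(self, arena):
        params = dataclasses.replace(
            synth.BEHAVIOR_PRESETS["ptz20"], session_duration=60.0
        )
        t = simulate_trajectory(params, arena, seed=4)
        still = ~t.state_sequence[1:]
        steps = np.linalg.norm(np.diff(t.positions, axis=0), axis=1)
        assert np.all(steps[still] == 0.0)

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"bout_rate": 1.0, "fps": 0.0},
            {"bout_rate": 1.0, "session_duration": -5.0},
            {"bout_rate": -1.0},
            {"bout_rate": 1.0, "top_half_bias": 1.5},
        ],
    )
    def test_invalid_parameters_rejected(self, kwargs):
        with pytest.raises(ValueError):
            BehaviorParams(**kwargs)

    def test_control_preset_distance_below_10cm(self, arena):
        dists = [
            simulate_trajectory(
                synth.BEHAVIOR_PRESETS["control"], arena, seed=s
            ).path_length_mm
            / 10.0
            for s in range(50)
        ]
        assert np.mean(dists) < 10.0

    def test_ptz20_preset_calibration_within_3se(self, arena):
        params = synth.BEHAVIOR_PRESETS["ptz20"]
        counts, dists = [], []
        for s in range(200):
            t = simulate_trajectory(params, arena, seed=s)
            counts.append(t.bout_count)
            dists.append(t.path_length_mm / 10.0)
        counts, dists = np.array(counts), np.array(dists)
        se_c = counts.std(ddof=1) / np.sqrt(len(counts))
        se_d = dists.std(ddof=1) / np.sqrt(len(dists))
        assert abs(counts.mean() - 832.7) < 3.0 * se_c
        assert abs(dists.mean() - 931.4) < 3.0 * se_d

    def test_top_half_bias_orders_occupancy(self, arena):
        lo = dataclasses.replace(
            synth.BEHAVIOR_PRESETS["ptz20"], top_half_bias=0.0, session_duration=300.0
        )
        hi = dataclasses.replace(lo, top_half_bias=1.0)
        f_lo = simulate_trajectory(lo, arena, seed=1).top_half_fraction(arena.well_height)
        f_hi = simulate_trajectory(hi, arena, seed=1).top_half_fraction(arena.well_height)
        assert f_hi > f_lo


class TestRenderVideo:
    def test_static_trajectory_identical_frames(self, arena):
        params = BehaviorParams(bout_rate=0.0, session_duration=1.0)
        t = simulate_trajectory(params, arena, seed=0)
        frames = render_video(t, arena, noise_sd=0.0)
        assert len(frames) == len(t.times)
        assert all(np.array_equal(frames[0], f) for f in frames[1:])

    def test_noiseless_blob_centred_on_ground_truth(self, arena, short_ptz_params):
        t = simulate_trajectory(short_ptz_params, arena, seed=9)
        frames = render_video(t, arena, noise_sd=0.0)
        cols, rows = project_to_pixels(t.positions, arena, view="top")
        # exhaustive darkness-weighted centroid over the full frame
        yy, xx = np.mgrid[0 : arena.image_height, 0 : arena.image_width]
        for i in range(0, len(frames), 100):
            w = np.clip(235.0 - frames[i].astype(float), 0, None)
            cy = (w * yy).sum() / w.sum()
            cx = (w * xx).sum() / w.sum()
            assert np.hypot(cy - rows[i], cx - cols[i]) < 0.5

    def test_difference_footprint_of_single_displacement(self, arena):
        n = 2
        pos = np.array([[5.0, 5.0, 0.0], [5.0 + 5 / arena.px_per_mm, 5.0, 0.0]])
        t = synth.GroundTruthTrajectory(
            times=np.array([0.0, 0.04]),
            positions=pos,
            state_sequence=np.array([False, True]),
            seed=0,
        )
        frames = render_video(t, arena, blob_radius=4.0, noise_sd=0.0)
        diff = frames[1].astype(int) != frames[0].astype(int)
        cols, rows = project_to_pixels(pos, arena, view="top")
        yy, xx = np.mgrid[0 : arena.image_height, 0 : arena.image_width]
        # the blob is written into a square window of half-width ceil(3 sigma)
        r_cut = np.ceil(3 * (4.0 / 1.5)) + 1
        cheb0 = np.maximum(np.abs(yy - rows[0]), np.abs(xx - cols[0]))
        cheb1 = np.maximum(np.abs(yy - rows[1]), np.abs(xx - cols[1]))
        inside_union = (cheb0 <= r_cut) | (cheb1 <= r_cut)
        assert diff.any()
        assert not diff[~inside_union].any()

    def test_blob_out_of_frame_lists_offending_frames(self, arena):
        pos = np.array([[0.05, 0.05, 0.0], [5.0, 5.0, 0.0]])
        t = synth.GroundTruthTrajectory(
            times=np.array([0.0, 0.04]),
            positions=pos,
            state_sequence=np.array([False, True]),
            seed=0,
        )
        with pytest.raises(ValueError, match="frame indices: 0"):
            render_video(t, arena, blob_radius=8.0, noise_sd=0.0)

    def test_render_deterministic_under_noise(self, arena):
        params = BehaviorParams(bout_rate=0.0, session_duration=0.4)
        t = simulate_trajectory(params, arena, seed=0)
        a = render_video(t, arena, noise_sd=5.0, seed=42)
        b = render_video(t, arena, noise_sd=5.0, seed=42)
        assert np.array_equal(a, b)


class TestSimulateAspiration:
    def test_noiseless_samples_exactly_collinear(self):
        gt = synth.ASPIRATION_PRESETS["control"]
        rec = simulate_aspiration(gt, n_pressure_steps=10, seed=0)
        slope, intercept = np.polyfit(rec.lengths, rec.pressures, 1)
        assert slope == pytest.approx(gt.pressure_slope_vs_length, rel=1e-12)
        assert intercept == pytest.approx(0.0, abs=abs(slope) * 1e-12)

    def test_pressure_protocol_is_increasing(self):
        gt = dataclasses.replace(synth.ASPIRATION_PRESETS["ptz20"], noise_sd=0.05)
        rec = simulate_aspiration(gt, n_pressure_steps=12, seed=5)
        assert np.all(np.diff(rec.pressures) > 0)
        assert np.all(rec.lengths >= 0)

    def test_too_few_steps_rejected(self):
        with pytest.raises(ValueError):
            simulate_aspiration(synth.ASPIRATION_PRESETS["control"], 2, seed=0)


class TestSimulateCohort:
    def test_zero_probabilities_give_all_alive_unhatched(self):
        table = simulate_cohort(30, 3, {3: 0.0, 5: 0.0}, {3: 0.0, 5: 0.0}, seed=1)
        assert (table.n_hatched == 0).all()
        assert (table.n_dead == 0).all()

    def test_counts_conserved_in_every_replicate(self):
        p = synth.COHORT_PRESETS["ptz40"]
        table = simulate_cohort(30, 5, p["hatch"], p["death"], seed=2)
        assert ((table.n_hatched + table.n_dead) <= table.n_treated).all()
        assert (table.n_treated == 30).all()

    def test_certain_outcomes(self):
        hatched = simulate_cohort(20, 2, {3: 1.0}, {3: 0.0}, seed=0)
        assert (hatched.n_hatched == 20).all()
        dead = simulate_cohort(20, 2, {3: 0.0}, {3: 1.0}, seed=0)
        assert (dead.n_dead == 20).all()

    def test_decreasing_cumulative_probabilities_rejected(self):
        with pytest.raises(ValueError, match="non-decreasing"):
            simulate_cohort(10, 1, {3: 0.5, 5: 0.4}, {3: 0.0, 5: 0.0}, seed=0)

    def test_inconsistent_hatch_plus_death_rejected(self):
        with pytest.raises(ValueError, match="exceeds 1"):
            simulate_cohort(10, 1, {3: 0.9}, {3: 0.3}, seed=0)

    def test_ptz40_preset_marginals_within_3se(self):
        p = synth.COHORT_PRESETS["ptz40"]
        table = simulate_cohort(30, 200, p["hatch"], p["death"], seed=3)
        day3 = table[table.day == 3]
        props = day3.n_hatched / day3.n_treated
        se = props.std(ddof=1) / np.sqrt(len(props))
        assert abs(props.mean() - 0.05) < 3 * se + 1e-9
        day5 = table[table.day == 5]
        props5 = day5.n_hatched / day5.n_treated
        se5 = props5.std(ddof=1) / np.sqrt(len(props5))
        assert abs(props5.mean() - 0.683) < 3 * se5

    def test_determinism(self):
        p = synth.COHORT_PRESETS["control"]
        a = simulate_cohort(30, 3, p["hatch"], p["death"], seed=9)
        b = simulate_cohort(30, 3, p["hatch"], p["death"], seed=9)
        assert a.equals(b)


class TestArenaSpec:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"px_per_mm": 0.0},
            {"image_width": 8},
            {"well_width": -1.0},
        ],
    )
    def test_invalid_arena_rejected(self, kwargs):
        with pytest.raises(ValueError):
            ArenaSpec(**kwargs)
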