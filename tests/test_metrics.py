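"""Trajectory filtering, per-trajectory metrics and hourly binning."""

import numpy as np
import pytest

import paratrack as pt
from paratrack.link import Trajectory
from paratrack.metrics import (
    Calibration,
    active_per_frame_hourly,
    filter_trajectories,
    initiation_counts,
    path_length_um,
    per_bin_trajectory_stats,
    trajectory_metrics,
)

CAL = Calibration(um_per_px=1.0, frame_interval_s=1.0)


def make_traj(pid=0, xs=None, ys=None, frames=None, dt=1.0, t0=0.0):
    xs = np.asarray(xs, dtype=float)
    ys = np.zeros_like(xs) if ys is None else np.asarray(ys, dtype=float)
    frames = np.arange(len(xs)) if frames is None else np.asarray(frames)
    return Trajectory(
        particle_id=pid,
        frames=frames.astype(np.int64),
        t_s=t0 + frames * dt,
        x_px=xs,
        y_px=ys,
        mass=np.ones_like(xs),
    )


def straight_traj(length_um, n_steps=100, pid=0, dt=1.0, t0=0.0):
    """Straight path of exactly length_um in n_steps equal steps (exact in float)."""
    step = length_um / n_steps
    return make_traj(pid=pid, xs=step * np.arange(n_steps + 1), dt=dt, t0=t0,
                     frames=np.arange(n_steps + 1))


class TestFilter:
    def test_threshold_is_inclusive(self):
        kept = filter_trajectories([straight_traj(10_000.0)], CAL, 10.0)
        assert len(kept) == 1

    def test_just_below_threshold_excluded(self):
        assert filter_trajectories([straight_traj(9_990.0)], CAL, 10.0) == []

    def test_survivors_are_exactly_those_at_or_above_threshold(self):
        trajs = [straight_traj(1000.0 * L, pid=L) for L in range(1, 21)]
        kept = filter_trajectories(trajs, CAL, 10.0)
        assert [t.particle_id for t in kept] == list(range(10, 21))

    def test_raising_threshold_never_adds_survivors(self):
        rng = np.random.default_rng(0)
        trajs = [straight_traj(rng.uniform(100, 30_000), pid=i) for i in range(30)]
        counts = [len(filter_trajectories(trajs, CAL, m)) for m in (0.0, 5.0, 10.0, 20.0, 50.0)]
        assert counts == sorted(counts, reverse=True)

    def test_calibration_scales_lengths(self):
        t = straight_traj(6_000.0)  # 6 mm at 1 µm/px
        assert filter_trajectories([t], Calibration(um_per_px=2.0), 10.0) == [t]


class TestTrajectoryMetrics:
    def test_two_point_trajectory(self):
        m = trajectory_metrics(make_traj(xs=[0.0, 100.0]), CAL)
        assert m.total_distance_um == 100.0
        assert m.duration_s == 1.0
        assert m.mean_speed_um_s == 100.0

    def test_collinear_points_additive(self):
        m = trajectory_metrics(make_traj(xs=[0.0, 40.0, 100.0]), CAL)
        assert m.total_distance_um == 100.0

    def test_single_point_rejected(self):
        with pytest.raises(ValueError):
            trajectory_metrics(make_traj(xs=[1.0]), CAL)

    def test_unit_coherence_under_calibration_change(self):
        t = make_traj(xs=[0.0, 30.0, 80.0], ys=[0.0, 40.0, 40.0])
        m1 = trajectory_metrics(t, Calibration(um_per_px=1.0))
        m2 = trajectory_metrics(t, Calibration(um_per_px=2.0))
        assert m2.total_distance_um == 2 * m1.total_distance_um
        assert m2.mean_speed_um_s == 2 * m1.mean_speed_um_s
        assert m2.duration_s == m1.duration_s

    def test_simulated_straight_swimmer_speed_recovered(self):
        params = pt.SwimmerParams(
            base_speed_um_s=250.0,
            rotational_diffusion_rad2_s=0.0,
            state_rates=pt.StateRates(0, 0, 0, 0, 0, 0),
            light_speed_gain=pt.ConstantGain(1.0),
        )
        truth = pt.simulate_swimmers(1, 15, params=params, seed=1, initial_state=0,
                                     initial_positions_um=np.array([[7000.0, 5000.0]]))
        traj = make_traj(xs=truth.x_um[0], ys=truth.y_um[0])
        m = trajectory_metrics(traj, Calibration(um_per_px=1.0))
        assert abs(m.mean_speed_um_s - 250.0) / 250.0 < 0.02


class TestInitiationCounts:
    def test_half_open_hour_bins(self):
        trajs = [make_traj(pid=i, xs=[0, 1], t0=t0, frames=np.array([0, 1]))
                 for i, t0 in enumerate([0.0, 3599.0, 3600.0])]
        series = initiation_counts(trajs, 3.0)
        assert series.values.tolist() == [2.0, 1.0, 0.0]

    def test_empty_list_gives_zero_series(self):
        series = initiation_counts([], 4.0)
        assert series.values.tolist() == [0.0] * 4

    def test_counts_conserve_trajectories(self):
        rng = np.random.default_rng(1)
        trajs = [make_traj(pid=i, xs=[0, 1], t0=rng.uniform(0, 6 * 3600 - 10)) for i in range(50)]
        series = initiation_counts(trajs, 6.0)
        assert series.values.sum() == 50

    def test_start_outside_record_rejected(self):
        with pytest.raises(ValueError):
            initiation_counts([make_traj(xs=[0, 1], t0=10 * 3600.0)], 2.0)

    def test_light_phase_rate_doubling_shows_in_hourly_means(self):
        """Start times from an inhomogeneous Poisson process with the light-phase
        rate doubled: light-bin mean count ~ 2x dark-bin mean."""
        rng = np.random.default_rng(7)
        schedule = pt.LDSchedule()
        lam = 40.0  # per hour, dark
        starts = []
        for hour in range(48):
            rate = 2 * lam if schedule.is_light(hour * 3600.0) else lam
            n = rng.poisson(rate)
            starts.extend(hour * 3600.0 + rng.uniform(0, 3600.0, n))
        trajs = [make_traj(pid=i, xs=[0, 1], t0=s) for i, s in enumerate(sorted(starts))]
        series = initiation_counts(trajs, 48.0)
        light = schedule.is_light(series.bin_start_h * 3600.0)
        ratio = series.values[light].mean() / series.values[~light].mean()
        assert 1.7 < ratio < 2.3


class TestActivePerFrame:
    def test_full_coverage_counts_one(self):
        traj = make_traj(xs=np.zeros(3600), frames=np.arange(3600))
        series = active_per_frame_hourly([traj], 3600, 1.0)
        assert series.values[0] == 1.0

    def test_half_coverage_counts_half(self):
        traj = make_traj(xs=np.zeros(1800), frames=np.arange(1800))
        series = active_per_frame_hourly([traj], 3600, 1.0)
        assert series.values[0] == 0.5

    def test_matches_brute_force_recount(self):
        rng = np.random.default_rng(2)
        n_frames = 7200
        trajs = []
        for i in range(25):
            start = rng.integers(0, n_frames - 100)
            length = rng.integers(2, 100)
            frames = np.arange(start, min(start + length, n_frames))
            trajs.append(make_traj(pid=i, xs=np.zeros(len(frames)), frames=frames))
        series = active_per_frame_hourly(trajs, n_frames, 1.0)
        brute = np.zeros(n_frames)
        for t in trajs:
            for f in t.frames:
                brute[f] += 1
        np.testing.assert_allclose(series.values, [brute[:3600].mean(), brute[3600:].mean()])


class TestPerBinStats:
    def test_constant_speed_spans_bins_equally(self):
        # 2 px/s for 2 hours, 1 point per 10 s
        frames = np.arange(0, 721)
        traj = make_traj(xs=20.0 * np.arange(721), frames=frames, dt=10.0)
        out = per_bin_trajectory_stats([traj], CAL, 2.0)
        np.testing.assert_allclose(out["speed"].values, [2.0, 2.0])

    def test_unweighted_mean_across_trajectories(self):
        a = make_traj(pid=0, xs=100.0 * np.arange(11))
        b = make_traj(pid=1, xs=300.0 * np.arange(5))
        out = per_bin_trajectory_stats([a, b], CAL, 1.0)
        assert out["speed"].values[0] == pytest.approx(200.0)

    def test_distance_and_duration_assigned_to_initiation_bin(self):
        # starts in hour 0, extends into hour 1
        frames = np.arange(0, 4000, 10)
        traj = make_traj(xs=5.0 * frames, frames=frames)
        out = per_bin_trajectory_stats([traj], CAL, 2.0)
        assert out["distance"].n_per_bin.tolist() == [1, 0]
        assert np.isnan(out["distance"].values[1])
        assert out["distance"].values[0] == pytest.approx(5.0 * 3990)
        assert out["duration"].values[0] == pytest.approx(3990.0)
        # speed is within-bin: both intersected bins report it
        assert out["speed"].n_per_bin.tolist() == [1, 1]

    def test_empty_bins_are_nan_not_zero(self):
        traj = straight_traj(1000.0)
        out = per_bin_trajectory_stats([traj], CAL, 3.0)
        assert np.isnan(out["speed"].values[1:]).all()

    def test_hour_shift_rotates_series(self):
        xs = np.cumsum(np.abs(np.sin(np.arange(300)))) * 3
        base = make_traj(xs=xs, frames=np.arange(300))
        shifted = make_traj(xs=xs, frames=np.arange(300), t0=2 * 3600.0)
        shifted.frames = shifted.frames + 7200
        a = per_bin_trajectory_stats([base], CAL, 3.0)["speed"].values
        b = per_bin_trajectory_stats([shifted], CAL, 3.0)["speed"].values
        np.testing.assert_allclose(np.roll(a, 2), b, equal_nan=True)


def test_path_length_in_um_uses_calibration():
    t = make_traj(xs=[0.0, 3.0], ys=[0.0, 4.0])
    assert path_length_um(t, Calibration(um_per_px=10.0)) == pytest.approx(50.0)
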