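"""Behavioural statistics on filtered trajectories, with hourly binning.

Five statistics are computed: trajectory-initiation counts per hour, the
hourly mean number of trajectories active per frame, and per-trajectory
total distance, duration and mean speed.  Hour bins are half-open
``[k, k+1)`` hours and aligned to the recording start (frame 0); zeitgeber
labels are attached only for reporting, via the LD schedule.

Distance and duration of a trajectory are attributed whole to its
initiation bin.  Mean speed is additionally computed *within* each bin a
trajectory intersects (its within-bin path length over within-bin time,
segments split proportionally at bin boundaries), because hourly speed
profiles are about when the movement happened, not when the trajectory
started; both views are exposed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .link import Trajectory
from .schedule import LDSchedule

__all__ = [
    "Calibration",
    "TrajectoryMetrics",
    "HourlySeries",
    "path_length_um",
    "filter_trajectories",
    "trajectory_metrics",
    "metrics_table",
    "initiation_counts",
    "active_per_frame_hourly",
    "per_bin_trajectory_stats",
]

_S_PER_H = 3600.0


@dataclass(frozen=True)
class Calibration:
    """Pixel and time calibration (µm per pixel, seconds per frame)."""

    um_per_px: float
    frame_interval_s: float = 1.0

    def __post_init__(self) -> None:
        if not (self.um_per_px > 0 and self.frame_interval_s > 0):
            raise ValueError("calibration values must be > 0")


@dataclass(frozen=True)
class TrajectoryMetrics:
    particle_id: int
    total_distance_um: float
    duration_s: float
    mean_speed_um_s: float
    start_t_s: float


@dataclass
class HourlySeries:
    """A statistic on consecutive 1-hour bins.

    ``values`` holds NaN for empty bins (an empty bin is not zero);
    ``n_per_bin`` counts the contributing items.  ``times_h`` (bin centres)
    is the sampling grid handed to the periodogram.
    """

    name: str
    bin_start_h: np.ndarray
    values: np.ndarray
    n_per_bin: np.ndarray
    zt_offset_h: float | None = None

    @property
    def n_bins(self) -> int:
        return len(self.bin_start_h)

    @property
    def times_h(self) -> np.ndarray:
        return self.bin_start_h + 0.5

    def finite(self) -> tuple[np.ndarray, np.ndarray]:
        """(times, values) with empty bins dropped."""
        m = np.isfinite(self.values)
        return self.times_h[m], self.values[m]

    def to_dataframe(self, schedule: LDSchedule | None = None) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "bin_start_h": self.bin_start_h,
                "statistic": self.name,
                "value": self.values,
                "n": self.n_per_bin,
            }
        )
        offset = self.zt_offset_h
        if schedule is not None:
            offset = schedule.zt_at_record_start
            df["zt_h"] = (self.bin_start_h + offset) % schedule.period_h
        elif offset is not None:
            df["zt_h"] = (self.bin_start_h + offset) % 24.0
        return df


def path_length_um(trajectory: Trajectory, calib: Calibration) -> float:
    """Total path length in µm (sum of consecutive-point Euclidean steps)."""
    return trajectory.path_length_px() * calib.um_per_px


def filter_trajectories(
    trajectories: list[Trajectory], calib: Calibration, min_length_mm: float = 10.0
) -> list[Trajectory]:
    """Keep trajectories whose total path length is >= ``min_length_mm``.

    The threshold is inclusive: a trajectory of exactly the minimum length
    is retained.  Order is preserved.
    """
    thr_um = min_length_mm * 1000.0
    return [t for t in trajectories if path_length_um(t, calib) >= thr_um]


def trajectory_metrics(trajectory: Trajectory, calib: Calibration) -> TrajectoryMetrics:
    """Distance (µm), duration (s) and mean speed (µm/s) of one trajectory.

    Duration is wall-clock span ``(end_frame - start_frame) * frame_interval``
    (memory gaps included); distance likewise includes straight-line chords
    across gaps, so mean speed = distance / duration is self-consistent.
    """
    if trajectory.n_points < 2:
        raise ValueError(f"trajectory {trajectory.particle_id} has fewer than 2 points; metrics undefined")
    dist = path_length_um(trajectory, calib)
    duration = (trajectory.end_frame - trajectory.start_frame) * calib.frame_interval_s
    return TrajectoryMetrics(
        particle_id=trajectory.particle_id,
        total_distance_um=dist,
        duration_s=duration,
        mean_speed_um_s=dist / duration,
        start_t_s=trajectory.start_t_s,
    )


def metrics_table(trajectories: list[Trajectory], calib: Calibration) -> pd.DataFrame:
    """Per-trajectory metrics as a table (single-point trajectories skipped)."""
    rows = [trajectory_metrics(t, calib) for t in trajectories if t.n_points >= 2]
    return pd.DataFrame(
        {
            "particle_id": [m.particle_id for m in rows],
            "start_t_s": [m.start_t_s for m in rows],
            "distance_um": [m.total_distance_um for m in rows],
            "duration_s": [m.duration_s for m in rows],
            "speed_um_s": [m.mean_speed_um_s for m in rows],
        }
    )


def _n_bins(record_duration_h: float) -> int:
    n = int(np.ceil(record_duration_h - 1e-9))
    if n < 1:
        raise ValueError("record_duration_h must cover at least part of one hour")
    return n


def initiation_counts(trajectories: list[Trajectory], record_duration_h: float) -> HourlySeries:
    """Number of trajectories initiated in each 1-hour bin.

    Bin k counts trajectories with start time in ``[k, k+1)`` hours from the
    recording start (half-open).
    """
    n = _n_bins(record_duration_h)
    counts = np.zeros(n, dtype=np.int64)
    for t in trajectories:
        k = int(t.start_t_s // _S_PER_H)
        if not (0 <= k < n):
            raise ValueError(f"trajectory {t.particle_id} starts at {t.start_t_s} s, outside the record")
        counts[k] += 1
    return HourlySeries(
        name="initiations",
        bin_start_h=np.arange(n, dtype=float),
        values=counts.astype(float),
        n_per_bin=counts,
    )


def active_per_frame_hourly(
    trajectories: list[Trajectory],
    n_frames: int,
    frame_interval_s: float,
    t0_s: float = 0.0,
) -> HourlySeries:
    """Hourly mean of the per-frame count of active trajectories.

    A trajectory is active at a frame iff it has a detection there (memory
    gaps do not count).  Every frame in a bin enters the mean, including
    frames with zero active trajectories.
    """
    counts = np.zeros(n_frames, dtype=np.int64)
    for t in trajectories:
        f = t.frames[(t.frames >= 0) & (t.frames < n_frames)]
        counts[f] += 1
    times = t0_s + np.arange(n_frames) * frame_interval_s
    bins = (times // _S_PER_H).astype(int)
    n = _n_bins((times[-1] + frame_interval_s) / _S_PER_H) if n_frames else 1
    values = np.full(n, np.nan)
    n_per = np.zeros(n, dtype=np.int64)
    for k in range(n):
        m = bins == k
        if m.any():
            values[k] = counts[m].mean()
            n_per[k] = m.sum()
    return HourlySeries(
        name="active_per_frame",
        bin_start_h=np.arange(n, dtype=float),
        values=values,
        n_per_bin=n_per,
    )


def _within_bin_accumulation(t: Trajectory, calib: Calibration, n_bins: int) -> dict[int, tuple[float, float]]:
    """Per-bin (path length µm, time s) of one trajectory.

    Each segment between consecutive detections is split at hour boundaries
    proportionally in time; the gap chord of a memory gap contributes over
    the full gap time.
    """
    acc: dict[int, list[float]] = {}
    xs, ys, ts = t.x_px, t.y_px, t.t_s
    for i in range(len(ts) - 1):
        t0, t1 = float(ts[i]), float(ts[i + 1])
        seg_len = float(np.hypot(xs[i + 1] - xs[i], ys[i + 1] - ys[i])) * calib.um_per_px
        seg_dt = t1 - t0
        if seg_dt <= 0:
            continue
        b0, b1 = int(t0 // _S_PER_H), int(np.ceil(t1 / _S_PER_H)) - 1
        b1 = max(b0, b1)
        for b in range(b0, b1 + 1):
            lo = max(t0, b * _S_PER_H)
            hi = min(t1, (b + 1) * _S_PER_H)
            frac = (hi - lo) / seg_dt
            if frac <= 0 or not (0 <= b < n_bins):
                continue
            cur = acc.setdefault(b, [0.0, 0.0])
            cur[0] += seg_len * frac
            cur[1] += hi - lo
    return {b: (v[0], v[1]) for b, v in acc.items()}


def per_bin_trajectory_stats(
    trajectories: list[Trajectory], calib: Calibration, record_duration_h: float
) -> dict[str, HourlySeries]:
    """Hourly distance, duration and mean-speed series.

    ``distance`` and ``duration`` average the whole-trajectory values over
    trajectories *initiated* in each bin.  ``speed`` averages, over every
    trajectory intersecting a bin, that trajectory's within-bin speed
    (within-bin path length / within-bin time); the mean is unweighted.
    Empty bins carry NaN.
    """
    n = _n_bins(record_duration_h)
    dist_acc: list[list[float]] = [[] for _ in range(n)]
    dur_acc: list[list[float]] = [[] for _ in range(n)]
    speed_acc: list[list[float]] = [[] for _ in range(n)]

    for t in trajectories:
        if t.n_points < 2:
            continue
        m = trajectory_metrics(t, calib)
        k = int(m.start_t_s // _S_PER_H)
        if 0 <= k < n:
            dist_acc[k].append(m.total_distance_um)
            dur_acc[k].append(m.duration_s)
        for b, (seg_len, seg_time) in _within_bin_accumulation(t, calib, n).items():
            if seg_time > 0:
                speed_acc[b].append(seg_len / seg_time)

    def series(name: str, acc: list[list[float]]) -> HourlySeries:
        values = np.array([np.mean(a) if a else np.nan for a in acc])
        n_per = np.array([len(a) for a in acc], dtype=np.int64)
        return HourlySeries(name=name, bin_start_h=np.arange(n, dtype=float), values=values, n_per_bin=n_per)

    return {
        "distance": series("distance_um", dist_acc),
        "duration": series("duration_s", dur_acc),
        "speed": series("speed_um_s", speed_acc),
    }
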