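"""Synthetic swimmers and dark-field frame rendering.

Simulates run-and-tumble-like ciliate swimmers in a shallow rectangular
observation chamber under a light-dark schedule, and renders the resulting
ground-truth trajectories as dark-field image sequences (bright Gaussian
spots on a dark, optionally cluttered background).  The simulation is 2-D:
the ~1 mm chamber depth is a projection axis for the camera and is ignored.

Behaviour is a three-state continuous-time Markov chain sampled at the frame
interval:

* ``SWIM`` — straight swimming with rotational diffusion of the heading;
* ``SPIRAL`` — swimming with an additional constant heading curvature;
* ``IMMOBILE`` — resting; the position is held.

Hitting a chamber wall triggers an avoidance reaction: the swimmer backs up
along its reversed heading for a fixed time, then reorients randomly.  The
light schedule enters multiplicatively: swimming speed is scaled by
``light_speed_gain(ZT)`` and the IMMOBILE→SWIM (trajectory initiation) rate
by ``initiation_rate_gain(ZT)``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import yaml

from .frames import FrameSequence
from .schedule import ConstantGain, LDSchedule, SquareWaveGain

__all__ = [
    "SWIM",
    "SPIRAL",
    "IMMOBILE",
    "STATE_NAMES",
    "Chamber",
    "StateRates",
    "SwimmerParams",
    "RenderParams",
    "GroundTruth",
    "simulate_swimmers",
    "render_frames",
    "make_clutter",
    "write_fixture",
]

SWIM, SPIRAL, IMMOBILE = 0, 1, 2
STATE_NAMES = ("SWIM", "SPIRAL", "IMMOBILE")


@dataclass(frozen=True)
class Chamber:
    """Rectangular observation chamber, dimensions in millimetres."""

    width_mm: float = 14.0
    height_mm: float = 10.0

    def __post_init__(self) -> None:
        if not (self.width_mm > 0 and self.height_mm > 0):
            raise ValueError("chamber dimensions must be strictly positive")

    @property
    def width_um(self) -> float:
        return self.width_mm * 1000.0

    @property
    def height_um(self) -> float:
        return self.height_mm * 1000.0


@dataclass(frozen=True)
class StateRates:
    """Transition rates (per second) of the three-state behaviour chain."""

    swim_to_spiral: float = 0.01
    swim_to_immobile: float = 0.005
    spiral_to_swim: float = 0.03
    spiral_to_immobile: float = 0.005
    immobile_to_swim: float = 0.01
    immobile_to_spiral: float = 0.0

    def __post_init__(self) -> None:
        for name, r in self.__dict__.items():
            if not (np.isfinite(r) and r >= 0):
                raise ValueError(f"state rate {name} must be finite and >= 0")

    def generator(self) -> np.ndarray:
        """3x3 CTMC generator matrix Q with rows summing to zero."""
        q = np.zeros((3, 3))
        q[SWIM, SPIRAL] = self.swim_to_spiral
        q[SWIM, IMMOBILE] = self.swim_to_immobile
        q[SPIRAL, SWIM] = self.spiral_to_swim
        q[SPIRAL, IMMOBILE] = self.spiral_to_immobile
        q[IMMOBILE, SWIM] = self.immobile_to_swim
        q[IMMOBILE, SPIRAL] = self.immobile_to_spiral
        np.fill_diagonal(q, -q.sum(axis=1))
        return q

    def stationary(self) -> np.ndarray:
        """Stationary distribution of the chain (pi @ Q = 0, sum(pi) = 1)."""
        q = self.generator()
        a = np.vstack([q.T, np.ones(3)])
        b = np.zeros(4)
        b[-1] = 1.0
        pi, *_ = np.linalg.lstsq(a, b, rcond=None)
        pi = np.clip(pi, 0, None)
        s = pi.sum()
        if s <= 0:
            raise ValueError("state rates admit no stationary distribution")
        return pi / s


@dataclass(frozen=True)
class SwimmerParams:
    """Kinematic and behavioural parameters of a simulated swimmer.

    Speeds are in µm/s.  The defaults are field-plausible for a ~100 µm
    ciliate (swimming at a few hundred µm/s, dwell times of tens of seconds
    to minutes per behavioural state); they are deliberately generic, not
    measurements.  The two gain profiles are strictly positive functions of
    zeitgeber time; the defaults are 12-h-period smoothed square waves locked
    to the transitions of a 12:12 LD cycle, i.e. the programmed response
    follows both lights-on and lights-off.
    """

    base_speed_um_s: float = 300.0
    rotational_diffusion_rad2_s: float = 0.05
    spiral_curvature_rad_s: float = 1.0
    state_rates: StateRates = field(default_factory=StateRates)
    avoidance_backup_s: float = 2.0
    avoidance_reorient_rad: float = 2.0
    light_speed_gain: object = field(
        default_factory=lambda: SquareWaveGain(high=1.4, low=1.0, period_h=12.0, duty_h=6.0, smoothing_h=1.0)
    )
    initiation_rate_gain: object = field(
        default_factory=lambda: SquareWaveGain(high=2.0, low=1.0, period_h=12.0, duty_h=3.0, smoothing_h=1.0)
    )

    def __post_init__(self) -> None:
        for name in ("base_speed_um_s", "rotational_diffusion_rad2_s", "avoidance_backup_s", "avoidance_reorient_rad"):
            v = getattr(self, name)
            if not (np.isfinite(v) and v >= 0):
                raise ValueError(f"{name} must be finite and >= 0")
        if not np.isfinite(self.spiral_curvature_rad_s):
            raise ValueError("spiral_curvature_rad_s must be finite")


@dataclass(frozen=True)
class RenderParams:
    """Dark-field rendering model: Gaussian spots + static clutter + noise."""

    image_width_px: int = 200
    image_height_px: int = 150
    um_per_px: float = 70.0
    spot_amplitude: float = 120.0
    spot_sigma_px: float = 2.0
    background_pattern: np.ndarray | None = None
    noise_sigma: float = 3.0
    frame_interval_s: float = 1.0

    def __post_init__(self) -> None:
        if self.spot_sigma_px <= 0:
            raise ValueError("spot_sigma_px must be > 0")
        if self.um_per_px <= 0:
            raise ValueError("um_per_px must be > 0")
        if self.frame_interval_s <= 0:
            raise ValueError("frame_interval_s must be > 0")
        if self.background_pattern is not None:
            bg = np.asarray(self.background_pattern)
            if bg.shape != (self.image_height_px, self.image_width_px):
                raise ValueError("background_pattern shape must be (image_height_px, image_width_px)")


@dataclass
class GroundTruth:
    """Per-swimmer truth: positions (µm), behavioural states and times.

    Arrays are shaped ``(n_swimmers, n_frames)``; times are strictly
    increasing at the simulation step ``dt_s`` starting from 0.
    """

    times_s: np.ndarray
    x_um: np.ndarray
    y_um: np.ndarray
    state: np.ndarray
    chamber: Chamber
    schedule: LDSchedule
    params: SwimmerParams
    dt_s: float
    rng_seed: int

    @property
    def n_swimmers(self) -> int:
        return self.x_um.shape[0]

    @property
    def n_frames(self) -> int:
        return self.x_um.shape[1]

    def to_dataframe(self) -> pd.DataFrame:
        s, f = self.x_um.shape
        return pd.DataFrame(
            {
                "swimmer_id": np.repeat(np.arange(s), f),
                "frame": np.tile(np.arange(f), s),
                "t_s": np.tile(self.times_s, s),
                "x_um": self.x_um.ravel(),
                "y_um": self.y_um.ravel(),
                "state": np.asarray(STATE_NAMES)[self.state.ravel()],
            }
        )


def _check_params(params: SwimmerParams) -> None:
    probe = params.light_speed_gain(np.array([0.0, 6.0, 12.0, 18.0]))
    probe2 = params.initiation_rate_gain(np.array([0.0, 6.0, 12.0, 18.0]))
    if not (np.all(np.isfinite(probe)) and np.all(probe > 0)):
        raise ValueError("light_speed_gain must be strictly positive and finite")
    if not (np.all(np.isfinite(probe2)) and np.all(probe2 > 0)):
        raise ValueError("initiation_rate_gain must be strictly positive and finite")


def simulate_swimmers(
    n_swimmers: int,
    duration_s: float,
    chamber: Chamber | None = None,
    params: SwimmerParams | None = None,
    schedule: LDSchedule | None = None,
    seed: int = 0,
    dt_s: float = 1.0,
    initial_state: int | None = None,
    initial_positions_um: np.ndarray | None = None,
) -> GroundTruth:
    """Simulate ``n_swimmers`` for ``duration_s`` seconds.

    The state machine and kinematics are Euler-stepped at ``dt_s`` (the frame
    interval).  Identical arguments (including ``seed``) give bit-identical
    output: all random draws are made for every swimmer at every step in a
    fixed order, regardless of which draws are consumed by the dynamics.

    Parameters
    ----------
    initial_state
        Force all swimmers to start in this state; by default initial states
        are sampled from the stationary distribution of the behaviour chain.
    initial_positions_um
        ``(n_swimmers, 2)`` starting positions; must lie inside the chamber.
        By default positions are drawn uniformly inside the chamber.
    """
    chamber = chamber or Chamber()
    params = params or SwimmerParams()
    schedule = schedule or LDSchedule()
    if duration_s <= 0:
        raise ValueError("duration_s must be > 0")
    if dt_s <= 0:
        raise ValueError("dt_s must be > 0")
    _check_params(params)

    rng = np.random.default_rng(seed)
    n_frames = int(round(duration_s / dt_s))
    times = np.arange(n_frames) * dt_s
    w, h = chamber.width_um, chamber.height_um

    x = np.empty((n_swimmers, n_frames))
    y = np.empty((n_swimmers, n_frames))
    st = np.empty((n_swimmers, n_frames), dtype=np.int8)

    if initial_positions_um is not None:
        p0 = np.asarray(initial_positions_um, dtype=float)
        if p0.shape != (n_swimmers, 2):
            raise ValueError("initial_positions_um must have shape (n_swimmers, 2)")
        if np.any(p0[:, 0] < 0) or np.any(p0[:, 0] > w) or np.any(p0[:, 1] < 0) or np.any(p0[:, 1] > h):
            raise ValueError("a swimmer was initialised outside the chamber")
        px, py = p0[:, 0].copy(), p0[:, 1].copy()
    else:
        margin = 0.02
        px = rng.uniform(margin * w, (1 - margin) * w, n_swimmers)
        py = rng.uniform(margin * h, (1 - margin) * h, n_swimmers)

    heading = rng.uniform(-np.pi, np.pi, n_swimmers)
    if initial_state is not None:
        state = np.full(n_swimmers, int(initial_state), dtype=np.int8)
    else:
        pi = params.state_rates.stationary()
        state = rng.choice(3, size=n_swimmers, p=pi).astype(np.int8)

    r = params.state_rates
    dr_sigma = np.sqrt(2.0 * params.rotational_diffusion_rad2_s * dt_s)
    avoid_timer = np.zeros(n_swimmers)

    x[:, 0], y[:, 0], st[:, 0] = px, py, state

    for i in range(1, n_frames):
        t = times[i - 1]
        zt = float(schedule.zt(t))
        speed = params.base_speed_um_s * float(params.light_speed_gain(zt))
        init_gain = float(params.initiation_rate_gain(zt))

        # fixed RNG consumption order: transitions, split, heading noise, reorientation
        u = rng.random(n_swimmers)
        v = rng.random(n_swimmers)
        z = rng.normal(size=n_swimmers)
        reorient = rng.normal(0.0, params.avoidance_reorient_rad or 1.0, n_swimmers)
        if params.avoidance_reorient_rad == 0.0:
            reorient = np.zeros(n_swimmers)

        # state transitions (rate of leaving each state, modulated initiation)
        r1 = np.choose(state, [r.swim_to_spiral, r.spiral_to_swim, r.immobile_to_swim * init_gain])
        r2 = np.choose(state, [r.swim_to_immobile, r.spiral_to_immobile, r.immobile_to_spiral])
        total = r1 + r2
        leave = u < -np.expm1(-total * dt_s)
        with np.errstate(invalid="ignore", divide="ignore"):
            first = v < np.where(total > 0, r1 / np.where(total > 0, total, 1.0), 0.0)
        dest1 = np.choose(state, [SPIRAL, SWIM, SWIM])
        dest2 = np.choose(state, [IMMOBILE, IMMOBILE, SPIRAL])
        new_state = np.where(leave, np.where(first, dest1, dest2), state).astype(np.int8)
        state = new_state

        avoiding = avoid_timer > 0
        # heading update: rotational diffusion while swimming; curvature while spiralling;
        # frozen during avoidance back-up
        dh = np.where(state == SWIM, dr_sigma * z, 0.0)
        dh = np.where(state == SPIRAL, params.spiral_curvature_rad_s * dt_s + dr_sigma * z, dh)
        heading = heading + np.where(avoiding, 0.0, dh)

        moving = (state != IMMOBILE) | avoiding
        step = speed * dt_s * moving
        px = px + step * np.cos(heading)
        py = py + step * np.sin(heading)

        # back-up countdown; on expiry, random reorientation
        avoid_timer = np.where(avoiding, avoid_timer - dt_s, avoid_timer)
        expired = avoiding & (avoid_timer <= 0)
        heading = np.where(expired, heading + np.pi + reorient, heading)
        avoid_timer = np.where(expired, 0.0, avoid_timer)

        # wall contact: clamp to the wall, reverse, start backing up
        hit = (px < 0) | (px > w) | (py < 0) | (py > h)
        px = np.clip(px, 0.0, w)
        py = np.clip(py, 0.0, h)
        fresh = hit & ~avoiding
        heading = np.where(fresh, heading + np.pi, heading)
        avoid_timer = np.where(fresh, params.avoidance_backup_s, avoid_timer)

        x[:, i], y[:, i], st[:, i] = px, py, state

    return GroundTruth(
        times_s=times,
        x_um=x,
        y_um=y,
        state=st,
        chamber=chamber,
        schedule=schedule,
        params=params,
        dt_s=dt_s,
        rng_seed=int(seed),
    )


def make_clutter(
    shape: tuple[int, int],
    n_blobs: int = 40,
    amplitude: float = 30.0,
    sigma_px: tuple[float, float] = (1.0, 6.0),
    seed: int = 0,
) -> np.ndarray:
    """Static dark-field clutter: fixed Gaussian blobs (debris, chamber edge)."""
    rng = np.random.default_rng(seed)
    hgt, wid = shape
    bg = np.zeros(shape, dtype=np.float64)
    yy, xx = np.mgrid[0:hgt, 0:wid]
    for _ in range(n_blobs):
        cx, cy = rng.uniform(0, wid), rng.uniform(0, hgt)
        a = rng.uniform(0.2, 1.0) * amplitude
        s = rng.uniform(*sigma_px)
        bg += a * np.exp(-((xx - cx) ** 2 + (yy - cy) ** 2) / (2 * s * s))
    # faint bright frame along the chamber edge
    edge = np.zeros(shape)
    edge[[0, -1], :] = 1.0
    edge[:, [0, -1]] = 1.0
    from scipy.ndimage import gaussian_filter

    bg += 0.5 * amplitude * gaussian_filter(edge, 2.0)
    return bg


def _add_spot(img: np.ndarray, cx: float, cy: float, amp: float, sigma: float) -> None:
    """Add one Gaussian spot in place, restricted to a ±4σ window (clipped at edges)."""
    hgt, wid = img.shape
    r = int(np.ceil(4 * sigma))
    x0, x1 = int(np.floor(cx)) - r, int(np.floor(cx)) + r + 1
    y0, y1 = int(np.floor(cy)) - r, int(np.floor(cy)) + r + 1
    x0c, x1c = max(x0, 0), min(x1, wid)
    y0c, y1c = max(y0, 0), min(y1, hgt)
    if x0c >= x1c or y0c >= y1c:
        return  # spot entirely outside the image: silently clipped
    xs = np.arange(x0c, x1c)
    ys = np.arange(y0c, y1c)
    gx = np.exp(-((xs - cx) ** 2) / (2 * sigma * sigma))
    gy = np.exp(-((ys - cy) ** 2) / (2 * sigma * sigma))
    img[y0c:y1c, x0c:x1c] += amp * np.outer(gy, gx)


def render_frames(truth: GroundTruth, render: RenderParams | None = None, seed: int | None = None) -> FrameSequence:
    """Render the ground truth as a dark-field frame sequence.

    Each frame is ``background + sum of Gaussian spots + N(0, noise_sigma)``
    clipped to [0, 255] and quantised to 8-bit.  Swimmers outside the image
    bounds are silently clipped.  ``seed`` defaults to a child of the truth's
    seed so rendering is reproducible without extra bookkeeping.
    """
    render = render or RenderParams()
    if seed is None:
        seed = int(np.random.SeedSequence(truth.rng_seed).spawn(1)[0].generate_state(1)[0] % (2**31))
    rng = np.random.default_rng(seed)

    shape = (render.image_height_px, render.image_width_px)
    bg = (
        np.zeros(shape, dtype=np.float64)
        if render.background_pattern is None
        else np.asarray(render.background_pattern, dtype=np.float64)
    )
    xs_px = truth.x_um / render.um_per_px
    ys_px = truth.y_um / render.um_per_px

    frames = np.empty((truth.n_frames, *shape), dtype=np.uint8)
    for i in range(truth.n_frames):
        img = bg.copy()
        for s in range(truth.n_swimmers):
            _add_spot(img, xs_px[s, i], ys_px[s, i], render.spot_amplitude, render.spot_sigma_px)
        if render.noise_sigma > 0:
            img += rng.normal(0.0, render.noise_sigma, shape)
        frames[i] = np.clip(img, 0, 255).round().astype(np.uint8)

    return FrameSequence.from_array(frames, frame_interval_s=render.frame_interval_s)


def write_fixture(
    truth: GroundTruth,
    frames: FrameSequence,
    out_dir: str | Path,
    overwrite: bool = False,
    image_format: str = "png",
    jpeg_quality: int = 75,
) -> dict:
    """Write a self-describing on-disk fixture.

    Produces numbered image files (``frame_%06d.<ext>``), the ground-truth
    CSV, a YAML snapshot of the generating configuration and a JSON manifest
    listing every path plus the RNG seed.  PNG (lossless) is the default;
    ``image_format="jpeg"`` emulates lossy acquisition for robustness tests.
    """
    out = Path(out_dir)
    manifest_path = out / "manifest.json"
    if manifest_path.exists() and not overwrite:
        raise FileExistsError(f"fixture already exists at {out} (pass overwrite=True)")
    out.mkdir(parents=True, exist_ok=True)

    ext = {"png": "png", "tiff": "tif", "jpeg": "jpg"}[image_format]
    frame_paths = []
    for i in range(len(frames)):
        p = out / f"frame_{i:06d}.{ext}"
        img = frames.raw(i)
        if image_format == "jpeg":
            iio.imwrite(p, img, quality=jpeg_quality)
        else:
            iio.imwrite(p, img)
        frame_paths.append(p.name)

    truth_csv = out / "ground_truth.csv"
    truth.to_dataframe().to_csv(truth_csv, index=False)

    config = {
        "seed": truth.rng_seed,
        "n_swimmers": truth.n_swimmers,
        "dt_s": truth.dt_s,
        "chamber": {"width_mm": truth.chamber.width_mm, "height_mm": truth.chamber.height_mm},
        "schedule": truth.schedule.to_dict(),
        "swimmer_params": {
            "base_speed_um_s": truth.params.base_speed_um_s,
            "rotational_diffusion_rad2_s": truth.params.rotational_diffusion_rad2_s,
            "spiral_curvature_rad_s": truth.params.spiral_curvature_rad_s,
            "avoidance_backup_s": truth.params.avoidance_backup_s,
            "avoidance_reorient_rad": truth.params.avoidance_reorient_rad,
            "state_rates": dict(truth.params.state_rates.__dict__),
            "light_speed_gain": truth.params.light_speed_gain.to_dict(),
            "initiation_rate_gain": truth.params.initiation_rate_gain.to_dict(),
        },
        "frame_interval_s": frames.frame_interval_s,
        "image_format": image_format,
    }
    config_path = out / "config.yaml"
    config_path.write_text(yaml.safe_dump(config, sort_keys=False))

    manifest = {
        "seed": truth.rng_seed,
        "n_frames": len(frames),
        "frame_files": frame_paths,
        "ground_truth_csv": truth_csv.name,
        "config": config_path.name,
        "image_format": image_format,
    }
    manifest_path.write_text(json.dumps(manifest, indent=2))
    return manifest
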