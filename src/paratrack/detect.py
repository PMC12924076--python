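"""Bright-spot detection with blockwise background subtraction.

Dark-field frames show swimmers as bright spots on a dark background with
static clutter (debris, chamber edges).  The background is estimated as the
pixel-wise mean over consecutive, non-overlapping blocks of frames (default
100); subtracting it removes everything stationary — including swimmers
immobile for a whole block, which is deliberate and mirrors the fact that
this approach cannot track a continuously immobile cell.

Spot localisation is Crocker–Grier style: Gaussian smoothing, local-maximum
candidates with a minimum separation, then sub-pixel refinement by iterated
intensity-weighted centroids within a disk, and finally an integrated-mass
cut.  Coordinates are pixels, origin at the top-left, x rightward, y
downward, frame indices 0-based.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.feature import peak_local_max

from .frames import FrameSequence

__all__ = [
    "DetectParams",
    "Detection",
    "BackgroundModel",
    "build_background",
    "subtract_background",
    "detect_spots",
    "detect_sequence",
    "detections_to_dataframe",
]


@dataclass(frozen=True)
class DetectParams:
    """Spot-detection parameters.

    ``diameter_px`` is the odd feature size; mass is integrated over a disk
    of radius ``diameter_px / 2``.  ``threshold`` rejects smoothed-image
    maxima below an absolute height before the (more expensive) centroid
    refinement; ``minmass`` is the final integrated-brightness cut.
    """

    diameter_px: int = 9
    minmass: float = 500.0
    separation_px: float | None = None
    smoothing_sigma_px: float = 1.0
    threshold: float = 10.0

    def __post_init__(self) -> None:
        if self.diameter_px < 3 or self.diameter_px % 2 == 0:
            raise ValueError("diameter_px must be odd and >= 3")
        if self.minmass < 0:
            raise ValueError("minmass must be >= 0")
        if self.smoothing_sigma_px < 0:
            raise ValueError("smoothing_sigma_px must be >= 0")

    @property
    def separation(self) -> float:
        return self.separation_px if self.separation_px is not None else float(self.diameter_px)


@dataclass(frozen=True)
class Detection:
    """One sub-pixel bright-spot localisation."""

    frame: int
    t_s: float
    x_px: float
    y_px: float
    mass: float
    size_px: float


class BackgroundModel:
    """Blockwise mean background: frame ``i`` maps to block ``i // window``."""

    def __init__(self, means: list[np.ndarray], window_size: int, n_frames: int) -> None:
        self.means = means
        self.window_size = int(window_size)
        self.n_frames = int(n_frames)

    def block_of(self, frame_index: int) -> int:
        if not (0 <= frame_index < self.n_frames):
            raise IndexError(f"frame index {frame_index} outside modelled range [0, {self.n_frames})")
        return frame_index // self.window_size

    def mean_for(self, frame_index: int) -> np.ndarray:
        return self.means[self.block_of(frame_index)]

    @property
    def n_blocks(self) -> int:
        return len(self.means)


def build_background(frames: FrameSequence, window_size: int = 100) -> BackgroundModel:
    """Pixel-wise mean over consecutive non-overlapping blocks of frames.

    The final block may be shorter than ``window_size``.  Streaming: only a
    running sum per block is held in memory.
    """
    if window_size < 1:
        raise ValueError("window_size must be >= 1")
    n = len(frames)
    if n == 0:
        raise ValueError("empty frame sequence")
    means: list[np.ndarray] = []
    acc = None
    count = 0
    for i in range(n):
        f = frames.get(i)
        if acc is None:
            acc = np.zeros_like(f, dtype=np.float64)
        elif f.shape != acc.shape:
            raise ValueError(f"frame {i} shape {f.shape} differs from {acc.shape}")
        acc += f
        count += 1
        if count == window_size:
            means.append(acc / count)
            acc = None
            count = 0
    if count > 0:
        means.append(acc / count)
    return BackgroundModel(means, window_size, n)


def subtract_background(frame: np.ndarray, model: BackgroundModel, frame_index: int) -> np.ndarray:
    """Positive part of (frame − block mean): bright residual, float64."""
    mean = model.mean_for(frame_index)
    frame = np.asarray(frame, dtype=np.float64)
    if frame.shape != mean.shape:
        raise ValueError(f"frame shape {frame.shape} does not match background {mean.shape}")
    return np.maximum(frame - mean, 0.0)


def _disk_offsets(radius: float) -> tuple[np.ndarray, np.ndarray]:
    r = int(np.floor(radius))
    dy, dx = np.mgrid[-r : r + 1, -r : r + 1]
    mask = dx * dx + dy * dy <= radius * radius
    return dy[mask], dx[mask]


def _refine_centroid(
    smoothed: np.ndarray, y0: int, x0: int, radius: float, max_iter: int = 10, tol: float = 0.005
) -> tuple[float, float]:
    """Iterated intensity-weighted centroid within a disk around (y0, x0)."""
    hgt, wid = smoothed.shape
    dy, dx = _disk_offsets(radius)
    cy, cx = float(y0), float(x0)
    for _ in range(max_iter):
        iy = np.clip(np.round(cy).astype(int) + dy, 0, hgt - 1)
        ix = np.clip(np.round(cx).astype(int) + dx, 0, wid - 1)
        w = smoothed[iy, ix]
        tot = w.sum()
        if tot <= 0:
            break
        ny = float(np.sum(w * iy) / tot)
        nx = float(np.sum(w * ix) / tot)
        shift = max(abs(ny - cy), abs(nx - cx))
        cy, cx = ny, nx
        if shift < tol:
            break
    return cy, cx


def detect_spots(
    residual: np.ndarray, params: DetectParams | None = None, frame: int = 0, t_s: float = 0.0
) -> list[Detection]:
    """Locate bright spots in a non-negative residual image.

    Returns detections sorted by (y, x); an empty list is a valid result.
    """
    params = params or DetectParams()
    residual = np.asarray(residual, dtype=np.float64)
    if residual.size == 0:
        return []
    if params.smoothing_sigma_px > 0:
        smoothed = ndimage.gaussian_filter(residual, params.smoothing_sigma_px)
    else:
        smoothed = residual

    min_dist = max(1, int(np.ceil(params.separation)))
    coords = peak_local_max(
        smoothed,
        min_distance=min_dist,
        threshold_abs=max(params.threshold, 1e-12),
        exclude_border=False,
    )
    if coords.size == 0:
        return []

    radius = params.diameter_px / 2.0
    dy, dx = _disk_offsets(radius)
    hgt, wid = residual.shape
    out: list[Detection] = []
    for y0, x0 in coords:
        cy, cx = _refine_centroid(smoothed, int(y0), int(x0), radius)
        iy = np.round(cy).astype(int) + dy
        ix = np.round(cx).astype(int) + dx
        keep = (iy >= 0) & (iy < hgt) & (ix >= 0) & (ix < wid)
        iy, ix = iy[keep], ix[keep]
        w = residual[iy, ix]
        mass = float(w.sum())
        if mass < params.minmass or mass <= 0:
            continue
        rg2 = float(np.sum(w * ((iy - cy) ** 2 + (ix - cx) ** 2)) / mass)
        out.append(
            Detection(
                frame=frame,
                t_s=t_s,
                x_px=float(np.clip(cx, 0, wid - 1)),
                y_px=float(np.clip(cy, 0, hgt - 1)),
                mass=mass,
                size_px=float(np.sqrt(max(rg2, 0.0))),
            )
        )
    out.sort(key=lambda d: (d.y_px, d.x_px))
    return out


def detect_sequence(
    frames: FrameSequence, window_size: int = 100, params: DetectParams | None = None
) -> list[Detection]:
    """Detect spots in every frame after blockwise background subtraction.

    Equivalent to per-frame ``detect_spots`` over ``subtract_background``;
    memory stays bounded by the background model (block means), not the
    whole sequence.
    """
    params = params or DetectParams()
    model = build_background(frames, window_size)
    detections: list[Detection] = []
    for i in range(len(frames)):
        residual = subtract_background(frames.get(i), model, i)
        detections.extend(detect_spots(residual, params, frame=i, t_s=frames.time_of(i)))
    return detections


def detections_to_dataframe(detections: list[Detection]) -> pd.DataFrame:
    """Detections as a tidy table (frame, t_s, x_px, y_px, mass, size_px)."""
    return pd.DataFrame(
        {
            "frame": [d.frame for d in detections],
            "t_s": [d.t_s for d in detections],
            "x_px": [d.x_px for d in detections],
            "y_px": [d.y_px for d in detections],
            "mass": [d.mass for d in detections],
            "size_px": [d.size_px for d in detections],
        }
    )
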