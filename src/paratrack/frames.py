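"""Ordered grayscale frame sequences, in memory or lazily from disk.

A :class:`FrameSequence` abstracts over an in-memory image stack and a
directory of numbered image files so the detection stage can stream either.
Frames are returned as 2-D float64 arrays; colour images are averaged to
grayscale on read.  An optional downscale factor (e.g. 0.3, as used to tame
4000x3000-pixel acquisitions) is applied on access; the pixel calibration of
downstream stages must then be divided by the same factor, which
:meth:`effective_um_per_px` does in one place to avoid double correction.
"""

from __future__ import annotations

import re
from pathlib import Path

import imageio.v3 as iio
import numpy as np
from skimage.transform import rescale

__all__ = ["FrameSequence", "natural_sort_key"]

_NUM_RE = re.compile(r"(\d+)")


def natural_sort_key(name: str):
    """Sort key treating digit runs numerically (frame_2 < frame_10)."""
    return [int(tok) if tok.isdigit() else tok for tok in _NUM_RE.split(str(name))]


class FrameSequence:
    """Ordered grayscale frames with uniform timestamps.

    Frame *i* is taken at ``t0_s + i * frame_interval_s`` seconds.
    """

    def __init__(
        self,
        stack: np.ndarray | None = None,
        paths: list[Path] | None = None,
        frame_interval_s: float = 1.0,
        t0_s: float = 0.0,
        downscale_factor: float | None = None,
    ) -> None:
        if (stack is None) == (paths is None):
            raise ValueError("provide exactly one of stack or paths")
        if frame_interval_s <= 0:
            raise ValueError("frame_interval_s must be > 0")
        if downscale_factor is not None and not (0 < downscale_factor <= 1):
            raise ValueError("downscale_factor must lie in (0, 1]")
        self._stack = stack
        self._paths = paths
        self.frame_interval_s = float(frame_interval_s)
        self.t0_s = float(t0_s)
        self.downscale_factor = downscale_factor
        self._shape: tuple[int, int] | None = None

    # -- constructors -----------------------------------------------------
    @classmethod
    def from_array(
        cls,
        stack: np.ndarray,
        frame_interval_s: float = 1.0,
        t0_s: float = 0.0,
        downscale_factor: float | None = None,
    ) -> "FrameSequence":
        stack = np.asarray(stack)
        if stack.ndim != 3:
            raise ValueError("stack must be (n_frames, height, width)")
        return cls(stack=stack, frame_interval_s=frame_interval_s, t0_s=t0_s, downscale_factor=downscale_factor)

    @classmethod
    def from_directory(
        cls,
        directory: str | Path,
        pattern: str = "*",
        frame_interval_s: float = 1.0,
        t0_s: float = 0.0,
        downscale_factor: float | None = None,
    ) -> "FrameSequence":
        """Collect image files matching ``pattern`` in natural sort order."""
        directory = Path(directory)
        exts = {".png", ".jpg", ".jpeg", ".tif", ".tiff"}
        paths = sorted(
            (p for p in directory.glob(pattern) if p.suffix.lower() in exts),
            key=lambda p: natural_sort_key(p.name),
        )
        if not paths:
            raise FileNotFoundError(f"no image files matching {pattern!r} in {directory}")
        return cls(paths=paths, frame_interval_s=frame_interval_s, t0_s=t0_s, downscale_factor=downscale_factor)

    # -- access -----------------------------------------------------------
    def __len__(self) -> int:
        return len(self._stack) if self._stack is not None else len(self._paths)

    @property
    def n_frames(self) -> int:
        return len(self)

    def raw(self, i: int) -> np.ndarray:
        """Frame ``i`` as stored (no grayscale conversion or downscaling)."""
        if self._stack is not None:
            return self._stack[i]
        p = self._paths[i]
        try:
            return iio.imread(p)
        except Exception as exc:  # noqa: BLE001 - re-raise naming the frame
            raise OSError(f"failed to read frame {i} ({p})") from exc

    def get(self, i: int) -> np.ndarray:
        """Frame ``i`` as a 2-D float64 grayscale image (downscaled if set)."""
        img = np.asarray(self.raw(i), dtype=np.float64)
        if img.ndim == 3:
            img = img.mean(axis=2)
        if self.downscale_factor is not None and self.downscale_factor != 1.0:
            img = rescale(img, self.downscale_factor, anti_aliasing=True, preserve_range=True)
        return img

    def __getitem__(self, i: int) -> np.ndarray:
        return self.get(i)

    def __iter__(self):
        for i in range(len(self)):
            yield self.get(i)

    @property
    def shape(self) -> tuple[int, int]:
        """(height, width) of the frames as returned by :meth:`get`."""
        if self._shape is None:
            self._shape = self.get(0).shape
        return self._shape

    @property
    def times_s(self) -> np.ndarray:
        return self.t0_s + np.arange(len(self)) * self.frame_interval_s

    def time_of(self, i: int) -> float:
        return self.t0_s + i * self.frame_interval_s

    def effective_um_per_px(self, um_per_px: float) -> float:
        """Pixel calibration after downscaling (µm per output pixel)."""
        if self.downscale_factor in (None, 1.0):
            return um_per_px
        return um_per_px / self.downscale_factor
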