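"""Light-dark (LD) schedules and zeitgeber-time gain profiles.

Zeitgeber time (ZT) counts hours since lights-on in an entraining LD cycle:
ZT0 is lights-on and, in the standard 12:12 schedule used here, ZT12 is
lights-off.  All behavioural modulation in the simulator is expressed as a
strictly positive multiplicative gain evaluated at ZT, so the schedule and
the gain profile together define the programmed diel behaviour.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "LDSchedule",
    "ConstantGain",
    "SquareWaveGain",
    "gain_from_dict",
]


@dataclass(frozen=True)
class LDSchedule:
    """A periodic light-dark schedule.

    Parameters
    ----------
    period_h
        Full cycle length in hours (24 for a diel cycle).
    light_on_zt, light_off_zt
        ZT of lights-on and lights-off.  By convention ZT0 = lights-on, so
        ``light_on_zt`` is 0 in an entrained recording.
    zt_at_record_start
        ZT of frame 0 of the recording; lets hourly bins (which are aligned
        to the recording start) be labelled in ZT.
    """

    period_h: float = 24.0
    light_on_zt: float = 0.0
    light_off_zt: float = 12.0
    zt_at_record_start: float = 0.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.light_on_zt < self.light_off_zt <= self.period_h):
            raise ValueError(
                "require 0 <= light_on_zt < light_off_zt <= period_h, got "
                f"on={self.light_on_zt}, off={self.light_off_zt}, period={self.period_h}"
            )
        if not (0.0 <= self.zt_at_record_start < self.period_h):
            raise ValueError("zt_at_record_start must lie in [0, period_h)")

    def zt(self, t_s):
        """Zeitgeber time (hours) at recording time ``t_s`` seconds."""
        return (self.zt_at_record_start + np.asarray(t_s) / 3600.0) % self.period_h

    def is_light(self, t_s):
        """Boolean light-phase indicator at recording time ``t_s`` seconds."""
        zt = self.zt(t_s)
        return (zt >= self.light_on_zt) & (zt < self.light_off_zt)

    def to_dict(self) -> dict:
        return {
            "period_h": self.period_h,
            "light_on_zt": self.light_on_zt,
            "light_off_zt": self.light_off_zt,
            "zt_at_record_start": self.zt_at_record_start,
        }


@dataclass(frozen=True)
class ConstantGain:
    """ZT-independent gain (value must be strictly positive)."""

    value: float = 1.0

    def __post_init__(self) -> None:
        if not (self.value > 0 and np.isfinite(self.value)):
            raise ValueError("gain must be strictly positive and finite")

    def __call__(self, zt):
        return np.broadcast_to(np.float64(self.value), np.shape(zt)).copy() if np.ndim(zt) else float(self.value)

    def to_dict(self) -> dict:
        return {"kind": "constant", "value": self.value}


@dataclass(frozen=True)
class SquareWaveGain:
    """Periodic square-wave gain with optional raised-cosine edge smoothing.

    The gain is ``high`` for ``duty_h`` hours starting at ``phase_h`` (modulo
    ``period_h``) and ``low`` otherwise.  ``smoothing_h`` > 0 replaces the
    instantaneous edges by half-cosine ramps of that width, centred on the
    nominal edge, which keeps the profile strictly positive and periodic.

    With ``period_h=12`` and ``phase_h=0`` under a 12:12 LD schedule the high
    phase starts at every light transition (both lights-on and lights-off), so
    the programmed modulation has a 12-hour period.
    """

    high: float = 1.5
    low: float = 1.0
    period_h: float = 12.0
    phase_h: float = 0.0
    duty_h: float | None = None
    smoothing_h: float = 0.0

    def __post_init__(self) -> None:
        if not (self.high > 0 and self.low > 0):
            raise ValueError("square-wave gain levels must be strictly positive")
        if self.period_h <= 0:
            raise ValueError("period_h must be positive")
        duty = self.duty_h if self.duty_h is not None else self.period_h / 2.0
        if not (0 < duty < self.period_h):
            raise ValueError("duty_h must lie in (0, period_h)")
        if self.smoothing_h < 0 or self.smoothing_h > min(duty, self.period_h - duty):
            raise ValueError("smoothing_h must lie in [0, min(duty_h, period_h - duty_h)]")

    @property
    def _duty(self) -> float:
        return self.duty_h if self.duty_h is not None else self.period_h / 2.0

    def __call__(self, zt):
        x = (np.asarray(zt, dtype=float) - self.phase_h) % self.period_h
        duty, w = self._duty, self.smoothing_h
        s = (x < duty).astype(float)
        if w > 0.0:
            # half-sine ramps of width w centred on both edges
            d0 = x - np.round(x / self.period_h) * self.period_h  # signed distance to the 0-edge
            d1 = x - duty
            s = np.where(np.abs(d0) <= w / 2, 0.5 * (1 + np.sin(np.pi * d0 / w)), s)
            s = np.where(np.abs(d1) <= w / 2, 0.5 * (1 - np.sin(np.pi * d1 / w)), s)
        out = self.low + (self.high - self.low) * s
        return float(out) if np.ndim(zt) == 0 else out

    def to_dict(self) -> dict:
        return {
            "kind": "square",
            "high": self.high,
            "low": self.low,
            "period_h": self.period_h,
            "phase_h": self.phase_h,
            "duty_h": self._duty,
            "smoothing_h": self.smoothing_h,
        }


def gain_from_dict(d: dict):
    """Rebuild a gain profile from its ``to_dict`` form (config round-trips)."""
    kind = d.get("kind")
    rest = {k: v for k, v in d.items() if k != "kind"}
    if kind == "constant":
        return ConstantGain(**rest)
    if kind == "square":
        return SquareWaveGain(**rest)
    raise ValueError(f"unknown gain kind: {kind!r}")
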