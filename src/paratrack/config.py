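"""Pipeline configuration: a single structured YAML file, validated.

One file carries everything needed to reproduce a run: input location,
calibration, detection/linking parameters, the trajectory-length filter,
the LD schedule, periodicity settings and the top-level seed.  Validation
reports every violation with its key path and rejects unknown keys with a
closest-match suggestion; omitted keys take the documented defaults, and a
validated config serialises back to YAML losslessly.
"""

from __future__ import annotations

import difflib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .detect import DetectParams
from .link import LinkParams
from .metrics import Calibration
from .schedule import LDSchedule

__all__ = ["PipelineConfig", "PeriodicityParams", "ConfigError", "validate_config", "load_config", "dump_config"]


class ConfigError(ValueError):
    """Configuration rejected; ``errors`` lists 'key.path: problem' strings."""

    def __init__(self, errors: list[str]) -> None:
        self.errors = errors
        super().__init__("invalid configuration:\n  " + "\n  ".join(errors))


@dataclass(frozen=True)
class PeriodicityParams:
    min_period_h: float = 2.0
    max_period_h: float | None = None  # None: record length
    step_h: float = 0.25
    n_permutations: int = 1000
    quantile: float = 0.99

    def grid(self, record_length_h: float) -> np.ndarray:
        hi = self.max_period_h if self.max_period_h is not None else record_length_h
        n = int(np.floor((hi - self.min_period_h) / self.step_h + 1e-9))
        if n < 1:
            raise ValueError("period grid is empty; check min/max/step")
        return self.min_period_h + self.step_h * np.arange(n + 1)


@dataclass
class PipelineConfig:
    input_dir: str | None = None
    input_glob: str = "*"
    output_dir: str = "paratrack_out"
    calibration: Calibration = field(default_factory=lambda: Calibration(um_per_px=70.0, frame_interval_s=1.0))
    detect: DetectParams = field(default_factory=DetectParams)
    link: LinkParams = field(default_factory=LinkParams)
    min_length_mm: float = 10.0
    background_window: int = 100
    schedule: LDSchedule = field(default_factory=LDSchedule)
    periodicity: PeriodicityParams = field(default_factory=PeriodicityParams)
    downscale_factor: float | None = None
    seed: int = 0

    def to_dict(self) -> dict:
        return {
            "input_dir": self.input_dir,
            "input_glob": self.input_glob,
            "output_dir": self.output_dir,
            "calibration": asdict(self.calibration),
            "detect": asdict(self.detect),
            "link": asdict(self.link),
            "min_length_mm": self.min_length_mm,
            "background_window": self.background_window,
            "schedule": self.schedule.to_dict(),
            "periodicity": asdict(self.periodicity),
            "downscale_factor": self.downscale_factor,
            "seed": self.seed,
        }


_SECTIONS = {
    "calibration": Calibration,
    "detect": DetectParams,
    "link": LinkParams,
    "schedule": LDSchedule,
    "periodicity": PeriodicityParams,
}
_SCALARS = {
    "input_dir",
    "input_glob",
    "output_dir",
    "min_length_mm",
    "background_window",
    "downscale_factor",
    "seed",
}


def _suggest(key: str, known) -> str:
    close = difflib.get_close_matches(key, list(known), n=1)
    return f" (did you mean {close[0]!r}?)" if close else ""


def validate_config(raw: str | dict) -> PipelineConfig:
    """Parse and validate a config mapping or YAML text.

    Raises :class:`ConfigError` carrying every violation found, each
    prefixed with its key path; fills defaults for omitted keys.
    """
    if isinstance(raw, str):
        try:
            raw = yaml.safe_load(raw) or {}
        except yaml.YAMLError as exc:
            raise ConfigError([f"<root>: unparseable YAML ({exc})"]) from exc
    if not isinstance(raw, dict):
        raise ConfigError(["<root>: config must be a mapping"])

    errors: list[str] = []
    known_top = _SCALARS | set(_SECTIONS)
    for key in raw:
        if key not in known_top:
            errors.append(f"{key}: unknown key{_suggest(key, known_top)}")

    kwargs: dict = {}
    for name, cls in _SECTIONS.items():
        section = raw.get(name)
        if not section:
            continue  # omitted section: the documented default applies
        if not isinstance(section, dict):
            errors.append(f"{name}: must be a mapping")
            continue
        fields = set(cls.__dataclass_fields__)
        for key in section:
            if key not in fields:
                errors.append(f"{name}.{key}: unknown key{_suggest(key, fields)}")
        clean = {k: v for k, v in section.items() if k in fields}
        try:
            kwargs[name] = cls(**clean)
        except (TypeError, ValueError) as exc:
            errors.append(f"{name}: {exc}")

    for key in _SCALARS:
        if key in raw:
            kwargs[key] = raw[key]

    if errors:
        raise ConfigError(errors)
    cfg = PipelineConfig(**kwargs)
    extra: list[str] = []
    if cfg.min_length_mm < 0:
        extra.append("min_length_mm: must be >= 0")
    if cfg.background_window < 1:
        extra.append("background_window: must be >= 1")
    if cfg.downscale_factor is not None and not (0 < cfg.downscale_factor <= 1):
        extra.append("downscale_factor: must lie in (0, 1]")
    if extra:
        raise ConfigError(extra)
    return cfg


def load_config(path: str | Path) -> PipelineConfig:
    return validate_config(Path(path).read_text())


def dump_config(config: PipelineConfig, path: str | Path | None = None) -> str:
    text = yaml.safe_dump(config.to_dict(), sort_keys=False)
    if path is not None:
        Path(path).write_text(text)
    return text
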