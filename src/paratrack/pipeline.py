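"""End-to-end pipeline: detection → linking → filtering → metrics → periodicity.

``run_pipeline`` executes every analysis stage on a frame directory (or an
in-memory sequence), writes each stage's CSV plus a JSON summary and a log
of per-stage counts, and returns a :class:`RunReport`.  A stage failure
aborts the run, names the failing stage and leaves a ``FAILED`` marker next
to whatever partial outputs were written.  All randomness derives from the
single configured seed, split deterministically per stage.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .config import PipelineConfig, dump_config
from .detect import detect_sequence, detections_to_dataframe
from .frames import FrameSequence
from .link import link, trajectories_to_dataframe
from .metrics import (
    Calibration,
    active_per_frame_hourly,
    filter_trajectories,
    initiation_counts,
    metrics_table,
    per_bin_trajectory_stats,
)
from .periodogram import periodogram

__all__ = ["RunReport", "StageError", "run_pipeline", "stage_seeds"]

log = logging.getLogger("paratrack")


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: BaseException) -> None:
        self.stage = stage
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")


def stage_seeds(seed: int, n: int = 4) -> list[int]:
    """Deterministically split one seed into per-stage child seeds (< 2**31)."""
    children = np.random.SeedSequence(seed).spawn(n)
    return [int(c.generate_state(1)[0] % (2**31)) for c in children]


@dataclass
class RunReport:
    output_dir: str
    n_frames: int = 0
    n_detections: int = 0
    n_trajectories: int = 0
    n_filtered: int = 0
    hourly_bins: int = 0
    significant_peaks: dict = field(default_factory=dict)
    outputs: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "output_dir": self.output_dir,
            "n_frames": self.n_frames,
            "n_detections": self.n_detections,
            "n_trajectories": self.n_trajectories,
            "n_filtered": self.n_filtered,
            "hourly_bins": self.hourly_bins,
            "significant_peaks": self.significant_peaks,
            "outputs": self.outputs,
        }


def run_pipeline(
    config: PipelineConfig,
    frames: FrameSequence | None = None,
    out_dir: str | Path | None = None,
) -> RunReport:
    """Run every stage on ``frames`` (or ``config.input_dir``) and write outputs."""
    out = Path(out_dir if out_dir is not None else config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    report = RunReport(output_dir=str(out))
    dump_config(config, out / "config_snapshot.yaml")
    stage = "load"
    try:
        if frames is None:
            if config.input_dir is None:
                raise ValueError("no frames given and config.input_dir is unset")
            frames = FrameSequence.from_directory(
                config.input_dir,
                pattern=config.input_glob,
                frame_interval_s=config.calibration.frame_interval_s,
                downscale_factor=config.downscale_factor,
            )
        report.n_frames = len(frames)
        um_per_px = frames.effective_um_per_px(config.calibration.um_per_px)
        calib = Calibration(um_per_px=um_per_px, frame_interval_s=frames.frame_interval_s)
        record_h = len(frames) * frames.frame_interval_s / 3600.0
        log.info("loaded %d frames (%.2f h of recording)", len(frames), record_h)

        stage = "detect"
        detections = detect_sequence(frames, config.background_window, config.detect)
        report.n_detections = len(detections)
        det_df = detections_to_dataframe(detections)
        det_df.to_csv(out / "detections.csv", index=False)
        report.outputs["detections"] = "detections.csv"
        log.info("detected %d spots", len(detections))

        stage = "link"
        trajectories = link(detections, config.link)
        report.n_trajectories = len(trajectories)
        trajectories_to_dataframe(trajectories).to_csv(out / "trajectories.csv", index=False)
        report.outputs["trajectories"] = "trajectories.csv"
        log.info("linked %d trajectories", len(trajectories))

        stage = "metrics"
        kept = filter_trajectories(trajectories, calib, config.min_length_mm)
        report.n_filtered = len(kept)
        log.info("%d trajectories pass the %.1f mm filter", len(kept), config.min_length_mm)
        metrics_table(kept, calib).to_csv(out / "trajectory_metrics.csv", index=False)
        report.outputs["trajectory_metrics"] = "trajectory_metrics.csv"

        hourly: dict = {}
        if kept and record_h >= 1.0:
            init = initiation_counts(kept, record_h)
            active = active_per_frame_hourly(kept, len(frames), frames.frame_interval_s)
            stats = per_bin_trajectory_stats(kept, calib, record_h)
            hourly = {"initiations": init, "active_per_frame": active, **stats}
            pd.concat([s.to_dataframe(config.schedule) for s in hourly.values()], ignore_index=True).to_csv(
                out / "hourly_series.csv", index=False
            )
            report.outputs["hourly_series"] = "hourly_series.csv"
            report.hourly_bins = init.n_bins
            log.info("hourly initiation counts: %s", init.values.astype(int).tolist())
            log.info("hourly active/frame means: %s", np.round(active.values, 2).tolist())

        stage = "periodogram"
        seeds = stage_seeds(config.seed)
        summaries = {}
        grid = None
        if hourly:
            try:
                grid = config.periodicity.grid(record_h)
            except ValueError:
                log.info("record too short for the configured period grid; skipping periodograms")
        if grid is not None:
            frames_csv = []
            for i, (name, series) in enumerate(hourly.items()):
                finite = np.isfinite(series.values).sum()
                if finite < 4:
                    log.info("skipping periodogram of %s: only %d finite bins", name, finite)
                    continue
                res = periodogram(
                    series,
                    grid,
                    n_permutations=config.periodicity.n_permutations,
                    quantile=config.periodicity.quantile,
                    seed=seeds[-1] + i,
                )
                summaries[name] = res.summary()
                df = res.to_dataframe()
                df.insert(0, "statistic", name)
                frames_csv.append(df)
                log.info(
                    "periodogram %s: %d significant peaks%s",
                    name,
                    len(res.significant_peaks),
                    f", top at {res.top_peak_period_h} h" if res.significant_peaks else "",
                )
            if frames_csv:
                pd.concat(frames_csv, ignore_index=True).to_csv(out / "periodogram.csv", index=False)
                report.outputs["periodogram"] = "periodogram.csv"
        report.significant_peaks = summaries

        summary = report.to_dict()
        (out / "summary.json").write_text(json.dumps(summary, indent=2))
        report.outputs["summary"] = "summary.json"
        return report
    except Exception as exc:
        (out / "FAILED").write_text(f"stage: {stage}\nerror: {exc}\n")
        raise StageError(stage, exc) from exc
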