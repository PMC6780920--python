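"""Batch processing: one configuration, many runs, isolated failures.

A :class:`RunConfig` (YAML-serializable) drives the full pipeline per
input file — demultiplex, MS1 annotation, AIF annotation per collision
energy, scoring — writing one report CSV per run plus a concatenated
summary with a run-id column.  A failing input is logged and marked failed
without aborting the batch.
"""

from __future__ import annotations

import logging
import traceback
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd
import yaml

from .dia import AnnotationConstraint, annotate_aif, dia_report, score_dia
from .library import (LibraryEntry, MSMSLibraryEntry, load_ms1_library,
                      load_msms_library)
from .ms1 import annotate_ms1, group_ms1, ms1_report, score_ms1
from .msio import read_run, split_by_energy
from .scoring import PPC_CUTOFF, PPS_BAND

__all__ = ["RunConfig", "run_batch", "process_run",
           "EXIT_OK", "EXIT_FAILED", "EXIT_PARTIAL"]

log = logging.getLogger("metadia.batch")

EXIT_OK = 0
EXIT_FAILED = 1
EXIT_PARTIAL = 2


@dataclass
class RunConfig:
    inputs: list[str] = field(default_factory=list)
    format: str | None = None            # inferred from extension when None
    ms1_library: str | None = None       # CSV paths
    msms_library: str | None = None
    polarity: str | None = None          # filter before CE split
    energy_cycle: list[float] | None = None  # fallback for missing metadata
    ppm_tol: float = 5.0
    mz_window: float = 0.005
    rt_tol: float = 0.08
    min_fragments: int | str = 1
    min_scans: int = 3
    min_intensity: float = 0.0
    ppc_cutoff: float = PPC_CUTOFF
    pps_band: tuple[float, float] = PPS_BAND
    smoother: str = "smoothing-spline"
    output_dir: str = "."
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.ppm_tol <= 0 or self.rt_tol <= 0 or self.mz_window <= 0:
            raise ValueError("tolerances must be positive")
        if isinstance(self.pps_band, list):
            self.pps_band = tuple(self.pps_band)

    def validate_paths(self) -> None:
        for p in self.inputs:
            if not Path(p).exists():
                raise FileNotFoundError(p)
        for p in (self.ms1_library, self.msms_library):
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(p)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        data = asdict(self)
        data["pps_band"] = list(self.pps_band)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)

    def constraint(self) -> AnnotationConstraint:
        return AnnotationConstraint(
            min_fragments=self.min_fragments, ppm_tol=self.ppm_tol,
            mz_window=self.mz_window, rt_tol=self.rt_tol,
            min_scans=self.min_scans, min_intensity=self.min_intensity)


def process_run(path: str | Path, config: RunConfig,
                ms1_lib: list[LibraryEntry] | None,
                msms_lib: list[MSMSLibraryEntry] | None) -> pd.DataFrame:
    """Run the full pipeline on one file; returns the combined report."""
    scans = read_run(path, config.format, energy_cycle=config.energy_cycle)
    channels = split_by_energy(scans, polarity=config.polarity)
    ms1_channels = [c for c in channels.values() if c.is_ms1]
    frames: list[pd.DataFrame] = []
    if ms1_lib and ms1_channels:
        anns = annotate_ms1(ms1_channels[0], ms1_lib,
                            ppm_tol=config.ppm_tol,
                            mz_window=config.mz_window,
                            min_scans=config.min_scans,
                            min_intensity=config.min_intensity)
        scores = [score_ms1(g, config.smoother, config.ppc_cutoff,
                            config.pps_band) for g in group_ms1(anns)]
        rep = ms1_report(anns, scores)
        if len(rep):
            rep.insert(0, "level", "MS1")
            frames.append(rep)
    if msms_lib and ms1_channels:
        constraint = config.constraint()
        scored = []
        for label, ch in sorted(channels.items()):
            if ch.is_ms1:
                continue
            groups = annotate_aif(ms1_channels[0], ch, msms_lib, constraint)
            scored.extend(score_dia(g, config.ppc_cutoff, config.pps_band,
                                    config.smoother) for g in groups)
        rep = dia_report(scored)
        if len(rep):
            rep.insert(0, "level", "DIA")
            frames.append(rep)
    if not frames:
        return pd.DataFrame()
    return pd.concat(frames, ignore_index=True)


def run_batch(config: RunConfig) -> int:
    """Process every input independently; returns a process exit code
    (0 = all succeeded, 1 = all failed, 2 = partial failure)."""
    logging.basicConfig(level=config.log_level)
    config.validate_paths()
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    ms1_lib = (load_ms1_library(config.ms1_library)
               if config.ms1_library else None)
    msms_lib = (load_msms_library(config.msms_library)
                if config.msms_library else None)
    summary_frames: list[pd.DataFrame] = []
    statuses: list[dict] = []
    for path in config.inputs:
        run_id = Path(path).stem
        try:
            report = process_run(path, config, ms1_lib, msms_lib)
            report_path = out_dir / f"{run_id}_report.csv"
            report.to_csv(report_path, index=False)
            if len(report):
                tagged = report.copy()
                tagged.insert(0, "run_id", run_id)
                summary_frames.append(tagged)
            statuses.append({"run_id": run_id, "status": "ok",
                             "n_rows": len(report)})
            log.info("processed %s: %d report rows", path, len(report))
        except Exception as exc:  # failure isolation per run
            log.error("run %s failed: %s", path, exc)
            log.debug("%s", traceback.format_exc())
            statuses.append({"run_id": run_id, "status": "failed",
                             "n_rows": 0, "error": str(exc)})
    summary = (pd.concat(summary_frames, ignore_index=True)
               if summary_frames else pd.DataFrame())
    summary.to_csv(out_dir / "summary.csv", index=False)
    pd.DataFrame(statuses).to_csv(out_dir / "batch_status.csv", index=False)
    n_failed = sum(s["status"] == "failed" for s in statuses)
    if n_failed == 0:
        return EXIT_OK
    if n_failed == len(statuses):
        return EXIT_FAILED
    return EXIT_PARTIAL
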