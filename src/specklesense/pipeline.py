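"""End-to-end orchestration of the sensing configurations.

A *configuration* is one cell of the study design: covered or uncovered
fiber, AC magnetic drive on or off, and (with the drive on) lock-in
filtering applied or not.  ``run_configuration`` executes the full chain

    simulate -> track -> (band-filter | normalize) -> segment -> cross-validate

for one configuration on synthetic data and returns the cross-validated
classification report; ``run_all`` assembles the per-configuration
reports into a comparative table.  Only the uncovered fiber with the
drive on carries glucose information, and only the lock-in-filtered path
recovers it cleanly — the comparison reproduces that qualitative
structure, not any particular human-data accuracy.

Default problem sizes are chosen so a five-configuration comparison runs
on a laptop CPU in minutes: 64x64-pixel frames, 1.5 s recordings at
1 kHz, 96 modes, 14 glucose levels x 5 recordings.  A ``"quick"`` scale
(48x48, 0.35 s, 24 modes) supports multi-seed ordering checks.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field, replace, asdict
from pathlib import Path

import numpy as np

from . import classify, lockin, tracking
from .classify import EvalReport, FeatureMatrix
from .exceptions import ValidationError
from .lockin import BandSelection
from .synthetic_data import (AcquisitionConfig, FiberSpec,
                             GLUCOSE_LEVELS_MG_DL, generate_dataset)
from .tracking import SubImageGrid

__all__ = [
    "CONFIGURATION_IDS",
    "RunConfig",
    "ComparativeReport",
    "study_config",
    "run_configuration",
    "run_all",
    "render_report",
]

#: The experimental cells compared in the study design.
CONFIGURATION_IDS: tuple[str, ...] = (
    "covered/no-field",
    "covered/field+lockin",
    "uncovered/no-field",
    "uncovered/field-no-filter",
    "uncovered/field+lockin",
)


def _parse_configuration(configuration: str) -> tuple[bool, bool, bool]:
    """-> (covered, field_on, use_filter)."""
    if configuration not in CONFIGURATION_IDS:
        raise ValidationError(
            f"unknown configuration {configuration!r}; "
            f"expected one of {CONFIGURATION_IDS}")
    fiber_part, drive_part = configuration.split("/")
    covered = fiber_part == "covered"
    field_on = drive_part != "no-field"
    use_filter = drive_part.endswith("+lockin")
    return covered, field_on, use_filter


@dataclass(frozen=True)
class RunConfig:
    """Everything one end-to-end run needs, plus its master seed."""

    configuration: str = "uncovered/field+lockin"
    levels: tuple = GLUCOSE_LEVELS_MG_DL
    recordings_per_level: int = 5
    fiber: FiberSpec = field(default_factory=FiberSpec)
    acquisition: AcquisitionConfig = field(
        default_factory=lambda: AcquisitionConfig(
            duration_s=1.5, frame_shape=(64, 64)))
    n_modes: int = 96
    grid: SubImageGrid = field(default_factory=lambda: SubImageGrid(
        subimage_rows=24, subimage_cols=24, stride=24, search_radius=6))
    # ~2/3 Hz: one to two FFT bins of a 1.5 s adjacent-frame trace
    band: BandSelection = field(default_factory=lambda: BandSelection(
        center_freq_hz=140.0, half_bandwidth_hz=2.0 / 3.0))
    # hop deliberately not a multiple of the drive period (7.14 samples at
    # the defaults): successive windows then sample different drive phases,
    # so per-feature training densities cover the tone's full swing
    window: int = 50
    hop: int = 36
    feature_transform: str = "none"
    h_grid: tuple | None = None
    n_folds: int = 5
    # a recording is one physical measurement; windows are repeated looks
    aggregate: str = "recording"
    seed: int = 0
    out_dir: str | None = None
    write_recordings: bool = False

    def __post_init__(self) -> None:
        _parse_configuration(self.configuration)

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def study_config(configuration: str = "uncovered/field+lockin",
                 seed: int = 0, scale: str = "default",
                 **overrides) -> RunConfig:
    """A ready-made RunConfig at one of the supported problem scales.

    ``scale="default"`` is the standard study size; ``scale="quick"``
    shrinks frames, duration and mode count for multi-seed medians.
    """
    if scale == "default":
        kwargs: dict = {}
    elif scale == "quick":
        kwargs = dict(
            acquisition=AcquisitionConfig(duration_s=0.35,
                                          frame_shape=(48, 48)),
            n_modes=24,
            grid=SubImageGrid(subimage_rows=20, subimage_cols=20,
                              stride=20, search_radius=5),
            band=BandSelection(center_freq_hz=140.0, half_bandwidth_hz=3.0),
            window=50, hop=36)
    else:
        raise ValidationError(f"unknown scale {scale!r}")
    kwargs.update(overrides)
    return RunConfig(configuration=configuration, seed=seed, **kwargs)


@dataclass
class ComparativeReport:
    """Per-configuration evaluation reports plus provenance."""

    reports: dict                       # configuration id -> EvalReport
    failed: dict                        # configuration id -> error message
    master_seed: int
    config_hashes: dict                 # configuration id -> hash

    @property
    def accuracy_table(self) -> dict:
        """Overall accuracy in percent per configuration."""
        return {cid: 100.0 * rep.overall_accuracy
                for cid, rep in self.reports.items()}

    def to_json(self) -> str:
        return json.dumps({
            "master_seed": self.master_seed,
            "config_hashes": self.config_hashes,
            "failed": self.failed,
            "reports": {cid: json.loads(rep.to_json())
                        for cid, rep in self.reports.items()},
        }, sort_keys=True, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "ComparativeReport":
        d = json.loads(text)
        return cls(
            reports={cid: EvalReport.from_json(json.dumps(rep))
                     for cid, rep in d["reports"].items()},
            failed=d.get("failed", {}),
            master_seed=d["master_seed"],
            config_hashes=d.get("config_hashes", {}),
        )


# --------------------------------------------------------------------------
# stage runners
# --------------------------------------------------------------------------

def _log(handle, stage: str, **fields) -> None:
    if handle is not None:
        entry = {"stage": stage, "wall_s": round(time.perf_counter(), 3)}
        entry.update(fields)
        handle.write(json.dumps(entry, sort_keys=True, default=str) + "\n")


def extract_features(config: RunConfig) -> FeatureMatrix:
    """Simulate, track, filter and segment one configuration's dataset."""
    covered, field_on, use_filter = _parse_configuration(config.configuration)
    fiber = replace(config.fiber, covered=covered)
    acquisition = replace(config.acquisition, field_on=field_on)

    out = Path(config.out_dir) if config.out_dir else None
    log_handle = None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
        for sub in ("recordings", "traces", "features", "reports"):
            (out / sub).mkdir(exist_ok=True)
        log_handle = (out / "run.log").open("a")

    dataset = generate_dataset(
        levels=config.levels,
        recordings_per_level=config.recordings_per_level,
        fiber=fiber, acquisition=acquisition, n_modes=config.n_modes,
        seed=config.seed)
    if out is not None:
        (out / "recordings" / "manifest.json").write_text(
            dataset.manifest_json())

    fs = acquisition.frame_rate_hz
    parts = []
    try:
        for entry, recording in zip(dataset.manifest,
                                    dataset.iter_recordings()):
            rec_id = entry["recording_id"]
            _log(log_handle, "simulate", recording_id=rec_id,
                 seed=entry["seed"])
            if out is not None and config.write_recordings:
                from .synthetic_data import write_recording_tiff
                write_recording_tiff(recording,
                                     out / "recordings" / entry["file"])
            trace = tracking.track_sequence(recording, config.grid,
                                            mode="adjacent")
            _log(log_handle, "track", recording_id=rec_id)
            if out is not None:
                tracking.write_trace_csv(trace,
                                         out / "traces" / f"{rec_id}.csv",
                                         grid=config.grid)
            series = trace.peak_height
            if use_filter:
                series = lockin.band_filter(series, fs, config.band)
            else:
                series = lockin.normalize(series)
            _log(log_handle, "filter", recording_id=rec_id,
                 filtered=use_filter)
            parts.append(classify.segment_features(
                series, config.window, config.hop,
                label=entry["glucose_mg_dl"], recording_id=rec_id,
                transform=config.feature_transform))
    finally:
        if log_handle is not None:
            log_handle.close()

    features = classify.concat_features(parts)
    if out is not None:
        features.to_frame().to_csv(out / "features" / "features.csv",
                                   index=False)
    return features


def run_configuration(config: RunConfig) -> EvalReport:
    """Run one configuration end to end; returns the CV report."""
    features = extract_features(config)
    h_grid = None if config.h_grid is None else np.asarray(config.h_grid)
    report, _ = classify.cross_validate(features, k=config.n_folds,
                                        h_grid=h_grid, seed=config.seed,
                                        aggregate=config.aggregate)
    if config.out_dir:
        out = Path(config.out_dir)
        name = config.configuration.replace("/", "_")
        (out / "reports" / f"{name}.json").write_text(report.to_json())
        report.confusion_frame().to_csv(
            out / "reports" / f"{name}_confusion.csv")
    return report


def run_all(configurations=CONFIGURATION_IDS,
            base: RunConfig | None = None) -> ComparativeReport:
    """Run several configurations on the same master seed family.

    Each configuration reuses the base RunConfig with only the
    configuration id swapped, so datasets differ solely through the
    channel gating (covered fibers and field-off runs share the
    underlying noise streams with their counterparts).  A failing
    configuration is recorded rather than aborting the comparison.
    """
    if len(configurations) == 0:
        raise ValidationError("at least one configuration required")
    base = base if base is not None else RunConfig()
    reports, failed, hashes = {}, {}, {}
    for cid in configurations:
        cfg = replace(base, configuration=cid)
        hashes[cid] = cfg.config_hash()
        try:
            reports[cid] = run_configuration(cfg)
        except Exception as exc:  # noqa: BLE001 - report, don't abort
            failed[cid] = f"{type(exc).__name__}: {exc}"
    return ComparativeReport(reports=reports, failed=failed,
                             master_seed=base.seed, config_hashes=hashes)


def render_report(report: ComparativeReport) -> str:
    """Human-readable comparison: accuracy table, per-class F1, confusions.

    Accuracies are printed in percent to one decimal.  Configurations
    that failed get an empty per-class section and a note.
    """
    lines = ["# Configuration comparison", ""]
    lines.append("| configuration | overall accuracy (%) |")
    lines.append("|---|---|")
    for cid in sorted(set(list(report.reports) + list(report.failed))):
        if cid in report.reports:
            lines.append(f"| {cid} | "
                         f"{100.0 * report.reports[cid].overall_accuracy:.1f} |")
        else:
            lines.append(f"| {cid} | failed |")
    for cid, rep in sorted(report.reports.items()):
        lines.append("")
        lines.append(f"## {cid}")
        lines.append("")
        classes = [f"{c:g}" for c in np.asarray(rep.classes, dtype=float)]
        lines.append("per-class F1: " + ", ".join(
            f"{c}: {f:.2f}" for c, f in zip(classes, rep.per_class["f1"])))
        lines.append("")
        lines.append("confusion matrix (rows = true, cols = predicted):")
        for row in rep.confusion:
            lines.append("    " + " ".join(f"{v:4d}" for v in row))
    for cid, msg in sorted(report.failed.items()):
        lines.append("")
        lines.append(f"## {cid}")
        lines.append("")
        lines.append(f"FAILED: {msg}")
    return "\n".join(lines) + "\n"
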