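"""Configured multi-stage runs with provenance and an output manifest.

A :class:`RunConfig` names the stages to execute and their parameters;
:func:`run_pipeline` runs them in order inside an output directory,
writing every table with the package's own writers, echoing the fully
resolved configuration (package version, config hash, timestamp, seed)
and finishing with a manifest listing each artifact's SHA-256 checksum.
Deterministic stages re-run bit-for-bit from the emitted config and seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .classify import train_phase_classifier, training_set_from_movie
from .errors import MitoscreenError, ValidationError
from .events import extract_mitotic_events
from .geometry import angle_group_summary
from .kinetics import bootstrap_dual_pulse
from . import io as msio
from .screen import normalize_plate, zscore_mimics
from .synthetic import (
    CellScript,
    MovieSpec,
    division_schedule,
    gen_anaphase_annotations,
    gen_dual_pulse_counts,
    gen_screen_plates,
    gen_timelapse_movie,
)

__all__ = ["RunConfig", "run_pipeline", "PipelineError"]

log = logging.getLogger("mitoscreen")

KNOWN_STAGES = (
    "simulate-movie",
    "simulate-annotations",
    "simulate-screen",
    "simulate-kinetics",
    "timing",
    "angles",
    "kinetics",
    "screen",
)


class PipelineError(MitoscreenError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    """Resolved parameters of one pipeline run."""

    out_dir: str
    stages: list[str]
    seed: int = 0
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        unknown = [s for s in self.stages if s not in KNOWN_STAGES]
        if unknown:
            raise ValidationError(f"unknown stages: {unknown}; known: {KNOWN_STAGES}")

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        path = Path(path)
        with open(path, "r", encoding="utf-8") as fh:
            raw = (
                json.load(fh) if path.suffix == ".json" else yaml.safe_load(fh)
            )
        return cls(**raw)

    def resolved(self) -> dict:
        blob = dataclasses.asdict(self)
        digest = hashlib.sha256(
            json.dumps(blob, sort_keys=True, default=str).encode()
        ).hexdigest()
        return {
            "config": blob,
            "package_version": __version__,
            "config_sha256": digest,
            "timestamp": datetime.now(timezone.utc).isoformat(),
        }


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _stage_simulate_movie(cfg: RunConfig, out: Path) -> list[Path]:
    p = cfg.params.get("simulate-movie", {})
    frame_count = int(p.get("frame_count", 30))
    interval = float(p.get("frame_interval_min", 3.0))
    n_cells = int(p.get("cell_count", 3))
    sched = division_schedule(
        int(p.get("nebd_frame", 8)), int(p.get("anaphase_frame", 16)), frame_count
    )
    spec = MovieSpec(
        frame_count=frame_count,
        frame_interval_min=interval,
        cells=[CellScript(phase_schedule=list(sched)) for _ in range(n_cells)],
        image_size=tuple(p.get("image_size", (160, 160))),
        noise_sd=float(p.get("noise_sd", 0.0)),
        seed=cfg.seed,
    )
    stack, truth = gen_timelapse_movie(spec)
    movie = out / "movie.tif"
    msio.write_image_stack(movie, stack, {"frame_interval_min": interval})
    truth_csv = out / "movie_truth.csv"
    msio.write_table(truth.to_frame(), truth_csv, "movie-truth")
    sidecar = out / "movie_params.json"
    msio.write_params_json(
        {"spec": {k: v for k, v in dataclasses.asdict(spec).items() if k != "cells"},
         "cell_count": spec.cell_count},
        sidecar,
    )
    return [movie, truth_csv, sidecar]


def _stage_simulate_annotations(cfg: RunConfig, out: Path) -> list[Path]:
    p = cfg.params.get("simulate-annotations", {})
    groups = p.get("groups", {"het": {"angle_mean_deg": 25.0}, "ko": {"angle_mean_deg": 15.0}})
    all_annotations = []
    for gi, (name, gp) in enumerate(sorted(groups.items())):
        anns, _ = gen_anaphase_annotations(
            n=int(gp.get("n", 20)),
            angle_mean_deg=float(gp.get("angle_mean_deg", 15.0)),
            angle_sd_deg=float(gp.get("angle_sd_deg", 12.0)),
            centrosome_noise_sd_um=float(gp.get("centrosome_noise_sd_um", 0.2)),
            group=name,
            seed=cfg.seed + gi,
        )
        for a in anns:
            a.cell_id = f"{name}_{a.cell_id}"
        all_annotations.extend(anns)
    path = out / "annotations.csv"
    msio.write_annotations(all_annotations, path)
    return [path]


def _stage_simulate_screen(cfg: RunConfig, out: Path) -> list[Path]:
    p = dict(cfg.params.get("simulate-screen", {}))
    p.setdefault("seed", cfg.seed)
    ds = gen_screen_plates(**p)
    path = out / "screen.csv"
    msio.write_screen(ds, path)
    return [path]


def _stage_simulate_kinetics(cfg: RunConfig, out: Path) -> list[Path]:
    p = cfg.params.get("simulate-kinetics", {})
    n_specimens = int(p.get("n_specimens", 3))
    counts = {
        f"specimen_{i + 1}": gen_dual_pulse_counts(
            tc_hours=float(p.get("tc_hours", 24.0)),
            ts_hours=float(p.get("ts_hours", 6.0)),
            ti_hours=float(p.get("ti_hours", 2.5)),
            n_cells=int(p.get("n_cells", 1000)),
            seed=cfg.seed + i,
        )
        for i in range(n_specimens)
    }
    path = out / "dual_pulse_counts.csv"
    msio.write_dual_pulse_counts(counts, path)
    return [path]


def _stage_timing(cfg: RunConfig, out: Path) -> list[Path]:
    p = cfg.params.get("timing", {})
    movie_path = Path(p.get("movie", out / "movie.tif"))
    if not movie_path.exists():
        raise ValidationError(f"timing: input movie {movie_path} does not exist")
    stack, meta = msio.read_image_stack(movie_path)
    interval = float(p.get("frame_interval_min", meta.get("frame_interval_min", 3.0)))
    truth_path = Path(p.get("truth", out / "movie_truth.csv"))
    # Train on a dedicated movie so classification never sees its target.
    train_spec = MovieSpec(
        frame_count=stack.shape[0],
        frame_interval_min=interval,
        cells=[
            CellScript(
                phase_schedule=division_schedule(
                    int(p.get("nebd_frame", 8)),
                    int(p.get("anaphase_frame", 16)),
                    stack.shape[0],
                )
            )
            for _ in range(3)
        ],
        image_size=(160, 160),
        noise_sd=float(p.get("train_noise_sd", 0.0)),
        seed=cfg.seed + 1000,
    )
    train_stack, train_truth = gen_timelapse_movie(train_spec)
    feats, labels = training_set_from_movie(train_stack, train_truth)
    clf = train_phase_classifier(feats, labels, seed=cfg.seed)
    tracks, events = extract_mitotic_events(stack, clf, interval)
    track_rows = [
        {
            "track_id": t.track_id,
            "frame": pt.frame_index,
            "label": pt.label,
            "row": pt.centroid[0],
            "col": pt.centroid[1],
            "phase": pt.phase,
            "ibb_ratio": pt.ibb_ratio,
            "parent_id": t.parent_id,
            "merged": t.merged,
        }
        for t in tracks
        for pt in t.points
    ]
    tracks_csv = out / "tracks.csv"
    msio.write_table(pd.DataFrame(track_rows), tracks_csv, "tracks")
    event_rows = [dataclasses.asdict(e) for e in events]
    events_csv = out / "events.csv"
    msio.write_table(
        pd.DataFrame(
            event_rows,
            columns=[
                "track_id",
                "nebd_frame",
                "anaphase_onset_frame",
                "duration_pm_ana_min",
                "reassembly_frame",
                "ratio_at_segregation",
            ],
        ),
        events_csv,
        "mitotic-events",
    )
    del truth_path  # truth is not consumed here; kept for external checks
    return [tracks_csv, events_csv]


def _stage_angles(cfg: RunConfig, out: Path) -> list[Path]:
    p = cfg.params.get("angles", {})
    ann_path = Path(p.get("annotations", out / "annotations.csv"))
    if not ann_path.exists():
        raise ValidationError(f"angles: annotation file {ann_path} does not exist")
    annotations = msio.read_annotations(ann_path)
    summary = angle_group_summary(annotations, alpha=float(p.get("alpha", 0.05)))
    angles_csv = out / "angles.csv"
    msio.write_table(summary.table, angles_csv, "spindle-angles")
    report = out / "angle_comparisons.txt"
    with open(report, "w", encoding="utf-8") as fh:
        for rep in summary.comparisons:
            fh.write(rep.to_text() + "\n\n")
        if not summary.comparisons:
            fh.write("single group: summary only, no comparison\n")
    return [angles_csv, report]


def _stage_kinetics(cfg: RunConfig, out: Path) -> list[Path]:
    p = cfg.params.get("kinetics", {})
    counts_path = Path(p.get("counts", out / "dual_pulse_counts.csv"))
    if not counts_path.exists():
        raise ValidationError(f"kinetics: counts file {counts_path} does not exist")
    counts = msio.read_dual_pulse_counts(counts_path)
    rows = []
    for name, c in sorted(counts.items()):
        res = bootstrap_dual_pulse(
            c, n_boot=int(p.get("bootstrap", 1000)), seed=cfg.seed
        )
        rows.append(
            {
                "specimen": name,
                "ts_hours": res["ts_hours"],
                "ts_ci_lo": res["ts_ci"][0],
                "ts_ci_hi": res["ts_ci"][1],
                "tc_hours": res["tc_hours"],
                "tc_ci_lo": res["tc_ci"][0],
                "tc_ci_hi": res["tc_ci"][1],
            }
        )
    path = out / "kinetics.csv"
    msio.write_table(pd.DataFrame(rows), path, "kinetics")
    return [path]


def _stage_screen(cfg: RunConfig, out: Path) -> list[Path]:
    p = cfg.params.get("screen", {})
    screen_path = Path(p.get("screen", out / "screen.csv"))
    if not screen_path.exists():
        raise ValidationError(f"screen: input file {screen_path} does not exist")
    ds = msio.read_screen(screen_path)
    ds = normalize_plate(ds, method=p.get("normalize", "median-scale"))
    table = zscore_mimics(ds, per_cell=bool(p.get("per_cell", False)))
    path = out / "zscores.csv"
    msio.write_table(table.reset_index(), path, "zscores")
    return [path]


_STAGE_FNS = {
    "simulate-movie": _stage_simulate_movie,
    "simulate-annotations": _stage_simulate_annotations,
    "simulate-screen": _stage_simulate_screen,
    "simulate-kinetics": _stage_simulate_kinetics,
    "timing": _stage_timing,
    "angles": _stage_angles,
    "kinetics": _stage_kinetics,
    "screen": _stage_screen,
}


def run_pipeline(config: RunConfig) -> Path:
    """Execute the configured stages; returns the run directory.

    Writes ``resolved_config.json`` first and ``manifest.json`` (paths and
    SHA-256 checksums of every artifact) last.  A stage failure aborts the
    run with the stage name; artifacts of completed stages are preserved.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    resolved = config.resolved()
    with open(out / "resolved_config.json", "w", encoding="utf-8") as fh:
        json.dump(resolved, fh, indent=2, sort_keys=True)
    log.info(
        "run start: seed=%s version=%s config=%s",
        config.seed,
        __version__,
        resolved["config_sha256"],
    )
    np.random.seed(config.seed % (2**31))  # defensive; stages seed explicitly
    manifest: dict[str, list[dict]] = {}
    for stage in config.stages:
        log.info("stage %s", stage)
        try:
            artifacts = _STAGE_FNS[stage](config, out)
        except Exception as exc:
            raise PipelineError(stage, exc) from exc
        manifest[stage] = [
            {"path": str(a.relative_to(out)), "sha256": _sha256(a)} for a in artifacts
        ]
    with open(out / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(
            {"resolved_config": resolved, "artifacts": manifest}, fh, indent=2,
            sort_keys=True,
        )
    log.info("run complete: %d stages", len(config.stages))
    return out
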