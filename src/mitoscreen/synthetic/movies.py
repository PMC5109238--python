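"""Synthetic two-channel live-cell movies with scripted mitoses.

The generator emulates the statistical structure of a chromatin-marker /
nuclear-import-reporter imaging assay, not its optics.  Channel 0 renders
chromatin as Gaussian blobs whose size, brightness and eccentricity change
with mitotic phase (large dim interphase nuclei condense into small bright
prometaphase masses, elongate into a metaphase plate, and split into two
daughter blobs at anaphase onset).  Channel 1 renders a nuclear-import
reporter as a flat cytoplasmic disk plus a nuclear disk whose intensity is
the cytoplasmic level times the phase's scripted nuclear/cytoplasmic
ratio: the ratio collapses at nuclear envelope breakdown and recovers
above the reassembly threshold in telophase.

Cells are static (no migration) and divisions place two daughters at a
fixed offset along a per-cell random axis.  Pixel noise is i.i.d.
Gaussian.  Ground truth records every event frame, lineage link and
centroid, so downstream recovery can be checked exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ..errors import GenerationError
from ..phases import PHASES, validate_phase

__all__ = [
    "DEFAULT_IBB_PROFILE",
    "MovieSpec",
    "CellScript",
    "CellTruth",
    "GroundTruth",
    "division_schedule",
    "gen_timelapse_movie",
    "gen_phase_clusters",
]

#: Nuclear/cytoplasmic reporter ratio per phase.  Interphase enrichment
#: collapses at nuclear envelope breakdown (prometaphase) and recovers in
#: telophase, crossing the 1.5x-of-segregation reassembly threshold.
DEFAULT_IBB_PROFILE: dict[str, float] = {
    "interphase": 3.0,
    "prophase": 2.6,
    "prometaphase": 0.8,
    "metaphase": 0.8,
    "anaphase": 0.9,
    "telophase": 2.2,
}

# Chromatin rendering per phase: ((sigma_major, sigma_minor) px, amplitude).
_PHASE_RENDER: dict[str, tuple[tuple[float, float], float]] = {
    "interphase": ((5.0, 5.0), 90.0),
    "prophase": ((3.8, 3.8), 130.0),
    "prometaphase": ((2.6, 2.6), 180.0),
    "metaphase": ((4.4, 1.6), 180.0),
    "anaphase": ((3.2, 1.8), 150.0),
    "telophase": ((3.0, 3.0), 110.0),
}

_CHROMATIN_BG = 10.0
_REPORTER_BG = 5.0
_CYTO_INTENSITY = 60.0
# The reporter's nuclear compartment is the chromatin blob's ellipse scaled
# by this factor (in sigma units), so it always sits inside the segmented
# chromatin mask and the cytoplasmic ring samples pure cytoplasm.
_NUCLEUS_SIGMA_SCALE = 1.25
_CYTO_RADIUS_PX = 15.0
_MIN_SEPARATION_PX = 34.0
_BORDER_MARGIN_PX = 20.0

REASSEMBLY_FACTOR = 1.5


@dataclass
class CellScript:
    """Scripted behaviour of one seeded cell.

    ``phase_schedule`` is a contiguous, non-overlapping list of
    ``(phase, start_frame, end_frame)`` half-open segments covering the
    cell's lifetime from frame 0.  If ``divides`` and the schedule contains
    anaphase, the cell is replaced by two daughters at the first anaphase
    frame; the daughters inherit the rest of the schedule.
    """

    phase_schedule: list[tuple[str, int, int]]
    position: tuple[float, float] | None = None  # (row, col); None -> auto-place
    divides: bool = True


@dataclass
class MovieSpec:
    frame_count: int
    frame_interval_min: float
    cells: list[CellScript]
    image_size: tuple[int, int] = (128, 128)
    noise_sd: float = 0.0
    ibb_ratio_profile: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_IBB_PROFILE)
    )
    seed: int = 0
    division_offset_px: float = 9.0

    @property
    def cell_count(self) -> int:
        return len(self.cells)

    def validate(self) -> None:
        if self.frame_count < 1:
            raise ValueError("frame_count must be >= 1")
        if self.frame_interval_min <= 0:
            raise ValueError("frame_interval_min must be positive")
        prof = self.ibb_ratio_profile
        missing = [p for p in PHASES if p not in prof]
        if missing:
            raise ValueError(f"ibb_ratio_profile missing phases: {missing}")
        if prof["interphase"] <= prof["prometaphase"]:
            raise ValueError(
                "interphase ratio must exceed prometaphase ratio "
                "(the reporter disperses at nuclear envelope breakdown)"
            )
        for cell in self.cells:
            prev_end = 0
            for phase, start, end in cell.phase_schedule:
                validate_phase(phase)
                if start != prev_end or end <= start:
                    raise ValueError(
                        "phase schedule must be contiguous, non-overlapping "
                        f"half-open segments; got ({phase}, {start}, {end})"
                    )
                prev_end = end
            if prev_end != self.frame_count:
                raise ValueError("phase schedule must cover every frame")


def division_schedule(
    nebd_frame: int,
    anaphase_frame: int,
    frame_count: int,
    prophase_frames: int = 2,
    anaphase_frames: int = 2,
    telophase_frames: int = 3,
) -> list[tuple[str, int, int]]:
    """Build a standard one-division schedule.

    Interphase runs up to ``nebd_frame - prophase_frames``; nuclear
    envelope breakdown (first prometaphase frame) is at ``nebd_frame`` and
    anaphase onset at ``anaphase_frame``, with the prometaphase/metaphase
    boundary placed halfway between.
    """
    if not 0 < nebd_frame - prophase_frames:
        raise ValueError("need at least one interphase frame before prophase")
    if not nebd_frame < anaphase_frame < frame_count:
        raise ValueError("need nebd_frame < anaphase_frame < frame_count")
    pm_end = nebd_frame + max(1, (anaphase_frame - nebd_frame) // 2)
    ana_end = min(anaphase_frame + anaphase_frames, frame_count)
    telo_end = min(ana_end + telophase_frames, frame_count)
    sched = [
        ("interphase", 0, nebd_frame - prophase_frames),
        ("prophase", nebd_frame - prophase_frames, nebd_frame),
        ("prometaphase", nebd_frame, pm_end),
        ("metaphase", pm_end, anaphase_frame),
        ("anaphase", anaphase_frame, ana_end),
    ]
    if telo_end > ana_end:
        sched.append(("telophase", ana_end, telo_end))
    if telo_end < frame_count:
        sched.append(("interphase", telo_end, frame_count))
    return sched


@dataclass
class CellTruth:
    cell_id: int
    parent_id: int | None
    phases: dict[int, str]
    centroids: dict[int, tuple[float, float]]
    nebd_frame: int | None = None
    anaphase_onset_frame: int | None = None
    reassembly_frame: int | None = None
    daughter_ids: tuple[int, ...] = ()


@dataclass
class GroundTruth:
    """Truth channel of a generated movie (for testing, not analysis)."""

    frame_interval_min: float
    cells: dict[int, CellTruth]

    def mitotic_durations_min(self) -> dict[int, float]:
        """Scripted prometaphase-to-anaphase-onset duration per mother cell."""
        out = {}
        for cid, cell in self.cells.items():
            if cell.nebd_frame is not None and cell.anaphase_onset_frame is not None:
                out[cid] = (
                    cell.anaphase_onset_frame - cell.nebd_frame
                ) * self.frame_interval_min
        return out

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for cid, c in sorted(self.cells.items()):
            for f in sorted(c.phases):
                r, col = c.centroids[f]
                rows.append((cid, c.parent_id, f, c.phases[f], r, col))
        return pd.DataFrame(
            rows, columns=["cell_id", "parent_id", "frame", "phase", "row", "col"]
        )


def _place_positions(spec: MovieSpec, rng: np.random.Generator) -> list[np.ndarray]:
    h, w = spec.image_size
    lo_r, hi_r = _BORDER_MARGIN_PX, h - _BORDER_MARGIN_PX
    lo_c, hi_c = _BORDER_MARGIN_PX, w - _BORDER_MARGIN_PX
    if hi_r <= lo_r or hi_c <= lo_c:
        raise GenerationError("image too small for the border margin")
    placed: list[np.ndarray] = []
    for cell in spec.cells:
        if cell.position is not None:
            placed.append(np.asarray(cell.position, dtype=float))
            continue
        for _ in range(2000):
            cand = np.array([rng.uniform(lo_r, hi_r), rng.uniform(lo_c, hi_c)])
            if all(np.linalg.norm(cand - p) >= _MIN_SEPARATION_PX for p in placed):
                placed.append(cand)
                break
        else:
            raise GenerationError(
                f"could not place {spec.cell_count} non-overlapping cells "
                f"in a {h}x{w} image"
            )
    return placed


def _schedule_to_phases(schedule: list[tuple[str, int, int]]) -> dict[int, str]:
    return {f: phase for phase, start, end in schedule for f in range(start, end)}


def _reassembly_from_profile(
    phases: dict[int, str], onset: int, profile: dict[str, float]
) -> int | None:
    r0 = profile[phases[onset]]
    for f in sorted(k for k in phases if k > onset):
        if profile[phases[f]] > REASSEMBLY_FACTOR * r0:
            return f
    return None


def _add_gaussian(canvas: np.ndarray, pos, sigma, amp, theta) -> None:
    s1, s2 = sigma
    half = int(math.ceil(4 * max(s1, s2)))
    h, w = canvas.shape
    r0, c0 = pos
    rlo, rhi = max(0, int(r0) - half), min(h, int(r0) + half + 1)
    clo, chi = max(0, int(c0) - half), min(w, int(c0) + half + 1)
    rr, cc = np.mgrid[rlo:rhi, clo:chi]
    dr, dc = rr - r0, cc - c0
    u = dr * math.cos(theta) + dc * math.sin(theta)
    v = -dr * math.sin(theta) + dc * math.cos(theta)
    blob = amp * np.exp(-0.5 * ((u / s1) ** 2 + (v / s2) ** 2))
    np.maximum(canvas[rlo:rhi, clo:chi], _CHROMATIN_BG + blob, out=canvas[rlo:rhi, clo:chi])


def _disk_mask(shape, pos, radius) -> tuple[slice, slice, np.ndarray]:
    h, w = shape
    r0, c0 = pos
    half = int(math.ceil(radius)) + 1
    rlo, rhi = max(0, int(r0) - half), min(h, int(r0) + half + 1)
    clo, chi = max(0, int(c0) - half), min(w, int(c0) + half + 1)
    rr, cc = np.mgrid[rlo:rhi, clo:chi]
    mask = (rr - r0) ** 2 + (cc - c0) ** 2 <= radius**2
    return slice(rlo, rhi), slice(clo, chi), mask


def _ellipse_mask(shape, pos, sigma, theta, scale) -> tuple[slice, slice, np.ndarray]:
    h, w = shape
    r0, c0 = pos
    s1, s2 = sigma
    half = int(math.ceil(scale * max(s1, s2))) + 1
    rlo, rhi = max(0, int(r0) - half), min(h, int(r0) + half + 1)
    clo, chi = max(0, int(c0) - half), min(w, int(c0) + half + 1)
    rr, cc = np.mgrid[rlo:rhi, clo:chi]
    dr, dc = rr - r0, cc - c0
    u = dr * math.cos(theta) + dc * math.sin(theta)
    v = -dr * math.sin(theta) + dc * math.cos(theta)
    mask = (u / s1) ** 2 + (v / s2) ** 2 <= scale**2
    return slice(rlo, rhi), slice(clo, chi), mask


@dataclass
class _Entity:
    cell_id: int
    parent_id: int | None
    position: np.ndarray
    theta: float
    phases: dict[int, str]


def gen_timelapse_movie(spec: MovieSpec) -> tuple[np.ndarray, GroundTruth]:
    """Render a movie and its ground truth.

    Returns
    -------
    stack : float32 ndarray, shape (frames, 2, height, width)
        Channel 0 chromatin, channel 1 nuclear-import reporter.
    truth : GroundTruth
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    positions = _place_positions(spec, rng)
    entities: list[_Entity] = []
    truth_cells: dict[int, CellTruth] = {}
    next_id = spec.cell_count + 1

    for i, cell in enumerate(spec.cells):
        cid = i + 1
        theta = rng.uniform(0, math.pi)
        phases = _schedule_to_phases(cell.phase_schedule)
        mitotic_frames = sorted(f for f, p in phases.items() if p == "prometaphase")
        nebd = mitotic_frames[0] if mitotic_frames else None
        ana_frames = sorted(f for f, p in phases.items() if p == "anaphase")
        onset = ana_frames[0] if ana_frames else None
        pos = positions[i]
        if cell.divides and onset is not None:
            parent_phases = {f: p for f, p in phases.items() if f < onset}
            child_phases = {f: p for f, p in phases.items() if f >= onset}
            offset = spec.division_offset_px * np.array(
                [math.cos(theta), math.sin(theta)]
            )
            d_ids = (next_id, next_id + 1)
            next_id += 2
            entities.append(_Entity(cid, None, pos, theta, parent_phases))
            truth_cells[cid] = CellTruth(
                cell_id=cid,
                parent_id=None,
                phases=dict(parent_phases),
                centroids={f: tuple(pos) for f in parent_phases},
                nebd_frame=nebd,
                anaphase_onset_frame=onset,
                daughter_ids=d_ids,
            )
            for did, sign in zip(d_ids, (+1.0, -1.0)):
                dpos = pos + sign * offset
                entities.append(_Entity(did, cid, dpos, theta, dict(child_phases)))
                truth_cells[did] = CellTruth(
                    cell_id=did,
                    parent_id=cid,
                    phases=dict(child_phases),
                    centroids={f: tuple(dpos) for f in child_phases},
                    reassembly_frame=_reassembly_from_profile(
                        phases, onset, spec.ibb_ratio_profile
                    ),
                )
        else:
            entities.append(_Entity(cid, None, pos, theta, phases))
            truth_cells[cid] = CellTruth(
                cell_id=cid,
                parent_id=None,
                phases=dict(phases),
                centroids={f: tuple(pos) for f in phases},
                nebd_frame=nebd,
                anaphase_onset_frame=onset,
                reassembly_frame=(
                    _reassembly_from_profile(phases, onset, spec.ibb_ratio_profile)
                    if onset is not None
                    else None
                ),
            )

    h, w = spec.image_size
    stack = np.empty((spec.frame_count, 2, h, w), dtype=np.float32)
    for f in range(spec.frame_count):
        chrom = np.full((h, w), _CHROMATIN_BG, dtype=float)
        rep = np.full((h, w), _REPORTER_BG, dtype=float)
        alive = [e for e in entities if f in e.phases]
        for e in alive:  # cytoplasm first, then nuclei overwrite
            rs, cs, m = _disk_mask((h, w), e.position, _CYTO_RADIUS_PX)
            patch = rep[rs, cs]
            patch[m] = np.maximum(patch[m], _CYTO_INTENSITY)
        for e in alive:
            ratio = spec.ibb_ratio_profile[e.phases[f]]
            sigma, amp = _PHASE_RENDER[e.phases[f]]
            # metaphase plates elongate perpendicular to the division axis
            th = e.theta + math.pi / 2 if e.phases[f] == "metaphase" else e.theta
            rs, cs, m = _ellipse_mask(
                (h, w), e.position, sigma, th, _NUCLEUS_SIGMA_SCALE
            )
            rep[rs, cs][m] = _CYTO_INTENSITY * ratio
            _add_gaussian(chrom, e.position, sigma, amp, th)
        if spec.noise_sd > 0:
            chrom = chrom + rng.normal(0.0, spec.noise_sd, size=chrom.shape)
            rep = rep + rng.normal(0.0, spec.noise_sd, size=rep.shape)
        stack[f, 0] = np.clip(chrom, 0, None)
        stack[f, 1] = np.clip(rep, 0, None)

    return stack, GroundTruth(frame_interval_min=spec.frame_interval_min, cells=truth_cells)


def gen_phase_clusters(
    n_per_class: int = 40,
    separation_sigma: float = 4.0,
    n_features: int = 8,
    seed: int = 0,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Gaussian feature-space clusters, one per mitotic phase.

    Class centres sit ``separation_sigma`` standard deviations apart along
    orthogonal feature axes — a controlled testbed for the phase
    classifier, independent of image rendering.
    """
    if n_features < len(PHASES):
        raise ValueError("need at least one feature axis per phase")
    rng = np.random.default_rng(seed)
    xs, ys = [], []
    for k, phase in enumerate(PHASES):
        centre = np.zeros(n_features)
        centre[k] = separation_sigma
        xs.append(rng.normal(0.0, 1.0, size=(n_per_class, n_features)) + centre)
        ys.extend([phase] * n_per_class)
    x = pd.DataFrame(
        np.vstack(xs), columns=[f"f{j}" for j in range(n_features)]
    )
    return x, np.asarray(ys)
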