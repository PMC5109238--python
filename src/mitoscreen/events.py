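"""Mitotic-event detection, nuclear-reassembly detection and timing curves.

The measured interval is nuclear envelope breakdown (NEBD, the first
prometaphase frame of the prophase-to-prometaphase transition) to anaphase
onset (the first anaphase-labelled frame, or the track's split frame if
the cell divides before anaphase is scored).  Nuclear envelope reassembly
is the first post-segregation frame whose nuclear/cytoplasmic reporter
ratio exceeds 1.5 times the ratio at chromosome segregation — a rule that
is invariant to any common positive rescaling of both channels.

Because the per-frame classifier can flicker at phase boundaries, labels
are smoothed by a 3-frame majority vote before event detection (disable
with ``smooth=False``).
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass

import numpy as np

from .classify import PhaseClassifier, extract_features
from .segmentation import grow_cytoplasm, segment_frame
from .tracking import CellTrack, track_cells

__all__ = [
    "MitoticEvent",
    "REASSEMBLY_FACTOR",
    "smooth_phase_labels",
    "detect_mitotic_event",
    "detect_reassembly",
    "duration_histogram",
    "extract_mitotic_events",
]

REASSEMBLY_FACTOR = 1.5


@dataclass
class MitoticEvent:
    """One detected mitosis on a cell track."""

    track_id: int
    nebd_frame: int
    anaphase_onset_frame: int
    duration_pm_ana_min: float
    reassembly_frame: int | None = None
    ratio_at_segregation: float = float("nan")


def smooth_phase_labels(phases: list[str], window: int = 3) -> list[str]:
    """Sliding majority vote over phase labels; ties keep the centre label."""
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be odd and >= 1")
    half = window // 2
    out = []
    for i in range(len(phases)):
        votes = Counter(phases[max(0, i - half) : i + half + 1])
        top = votes.most_common()
        if len(top) > 1 and top[0][1] == top[1][1]:
            out.append(phases[i])
        else:
            out.append(top[0][0])
    return out


def detect_mitotic_event(
    track: CellTrack,
    frame_interval_min: float,
    smooth: bool = True,
    split_frame: int | None = None,
) -> MitoticEvent | None:
    """Detect one mitosis on a fully phase-labelled track.

    NEBD is the first frame of the first prophase-to-prometaphase
    transition; anaphase onset is the first anaphase-labelled frame after
    NEBD, or ``split_frame`` (the first daughter frame, when the track
    splits) if that comes first.  Returns ``None`` when the track shows no
    such transition or never reaches anaphase.  A track whose anaphase
    precedes any prometaphase is reported as inconsistent and skipped.
    """
    phases = track.phases
    if any(p is None for p in phases):
        raise ValueError("every frame of the track needs a phase label")
    if smooth and len(phases) >= 3:
        phases = smooth_phase_labels(phases, window=3)
    frames = track.frames

    nebd_i = next(
        (
            i
            for i in range(1, len(phases))
            if phases[i] == "prometaphase" and phases[i - 1] == "prophase"
        ),
        None,
    )
    first_ana_i = next((i for i, p in enumerate(phases) if p == "anaphase"), None)
    if nebd_i is None:
        return None
    if first_ana_i is not None and first_ana_i < nebd_i:
        warnings.warn(
            f"track {track.track_id}: anaphase precedes prometaphase; skipped",
            stacklevel=2,
        )
        return None

    onset = frames[first_ana_i] if first_ana_i is not None else None
    if track.daughter_ids:
        split = split_frame if split_frame is not None else frames[-1] + 1
        onset = split if onset is None else min(onset, split)
    if onset is None:
        return None

    nebd = frames[nebd_i]
    ratio_at_seg = float("nan")
    if onset in frames:
        ratio_at_seg = float(track.ratios[frames.index(onset)])
    return MitoticEvent(
        track_id=track.track_id,
        nebd_frame=nebd,
        anaphase_onset_frame=onset,
        duration_pm_ana_min=(onset - nebd) * frame_interval_min,
        ratio_at_segregation=ratio_at_seg,
    )


def detect_reassembly(
    track: CellTrack,
    segregation_frame: int,
    factor: float = REASSEMBLY_FACTOR,
) -> int | None:
    """First frame after segregation whose ratio exceeds ``factor`` times
    the ratio at segregation; ``None`` if the threshold is never reached."""
    frames = track.frames
    if segregation_frame not in frames:
        raise ValueError("segregation_frame must lie on the track")
    ratios = track.ratios
    r0 = ratios[frames.index(segregation_frame)]
    if not np.isfinite(r0):
        raise ValueError("ratio undefined at the segregation frame")
    for f, r in zip(frames, ratios):
        if f > segregation_frame and np.isfinite(r) and r > factor * r0:
            return f
    return None


def duration_histogram(durations_min) -> tuple[np.ndarray, np.ndarray]:
    """Cumulative fraction of cells having reached anaphase vs. time.

    Accepts durations (minutes) or :class:`MitoticEvent` objects; returns
    ``(times, cumulative_fraction)`` — the empirical CDF, a nondecreasing
    step function reaching 1.0 at the longest completed mitosis.
    """
    vals = [
        d.duration_pm_ana_min if isinstance(d, MitoticEvent) else float(d)
        for d in durations_min
    ]
    if not vals:
        raise ValueError("need at least one completed mitotic event")
    times = np.sort(np.asarray(vals, dtype=float))
    frac = np.arange(1, len(times) + 1) / len(times)
    return times, frac


def extract_mitotic_events(
    stack: np.ndarray,
    classifier: PhaseClassifier,
    frame_interval_min: float,
    window: int = 33,
    offset: float = -20.0,
    min_area: int = 20,
    ring_width: int = 3,
    max_link_distance: float = 15.0,
    smooth: bool = True,
    restrict_splits: bool = False,
) -> tuple[list[CellTrack], list[MitoticEvent]]:
    """Full timing pipeline on a two-channel movie.

    Segments every frame, grows cytoplasmic rings, classifies objects,
    tracks cells, and detects one mitotic event per non-merged root track.
    Reassembly is scored on the first daughter track (the segregation
    frame is the daughter's first frame) or, for non-splitting tracks, on
    the track itself after its anaphase onset.
    """
    frames = []
    by_id = {}
    for f in range(stack.shape[0]):
        lf = segment_frame(
            stack[f], frame_index=f, window=window, offset=offset, min_area=min_area
        )
        lf = grow_cytoplasm(lf, ring_width=ring_width)
        if lf.objects:
            feats = extract_features(lf)
            pred = classifier.predict(feats)
            for lab, phase in zip(feats.index, pred):
                lf.objects[lab].phase = str(phase)
        frames.append(lf)
    tracks = track_cells(
        frames, max_link_distance=max_link_distance, restrict_splits=restrict_splits
    )
    by_id = {t.track_id: t for t in tracks}

    events = []
    for track in tracks:
        if track.parent_id is not None or track.merged:
            continue
        split_frame = (
            by_id[track.daughter_ids[0]].frames[0] if track.daughter_ids else None
        )
        event = detect_mitotic_event(
            track, frame_interval_min, smooth=smooth, split_frame=split_frame
        )
        if event is None:
            continue
        carrier = by_id[track.daughter_ids[0]] if track.daughter_ids else track
        try:
            seg_frame = event.anaphase_onset_frame
            if seg_frame in carrier.frames:
                ratios = carrier.ratios
                event.ratio_at_segregation = float(
                    ratios[carrier.frames.index(seg_frame)]
                )
                event.reassembly_frame = detect_reassembly(carrier, seg_frame)
        except ValueError:
            pass
        events.append(event)
    return tracks, events
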