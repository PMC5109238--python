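"""Constrained nearest-neighbour cell tracking with splits and merges.

Objects of consecutive frames are linked by the assignment minimising the
total centroid distance among all maximum-cardinality matchings whose
individual links stay within ``max_link_distance`` (solved with the
Hungarian algorithm on a padded cost matrix; leaving an object unlinked
costs ``max_link_distance``, so any feasible link is always preferred and
ties reduce to minimal total distance).  An unlinked new object next to an
already-linked predecessor records a one-to-two *split* — the mitosis
signature: the parent track ends and two daughter tracks begin.  An
unlinked old object next to an already-linked successor records a
two-to-one *merge*; merged tracks are flagged and excluded from event
statistics by downstream consumers.  All tie-breaks favour the lowest
object label, so tracking is deterministic given the input ordering.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment

from .segmentation import LabeledFrame

__all__ = ["TrackPoint", "CellTrack", "track_cells"]

_BIG = 1e9


@dataclass
class TrackPoint:
    frame_index: int
    label: int
    centroid: tuple[float, float]
    phase: str | None = None
    ibb_ratio: float = float("nan")


@dataclass
class CellTrack:
    track_id: int
    points: list[TrackPoint] = field(default_factory=list)
    parent_id: int | None = None
    daughter_ids: tuple[int, ...] = ()
    merged: bool = False
    merged_into: int | None = None

    @property
    def frames(self) -> list[int]:
        return [p.frame_index for p in self.points]

    @property
    def phases(self) -> list[str | None]:
        return [p.phase for p in self.points]

    @property
    def ratios(self) -> np.ndarray:
        return np.array([p.ibb_ratio for p in self.points])

    def __len__(self) -> int:
        return len(self.points)


def _point(frame: LabeledFrame, label: int) -> TrackPoint:
    obj = frame.objects[label]
    return TrackPoint(
        frame_index=frame.frame_index,
        label=label,
        centroid=obj.centroid,
        phase=obj.phase,
        ibb_ratio=obj.ibb_ratio,
    )


def _pair_assignment(
    a_pos: np.ndarray, b_pos: np.ndarray, max_dist: float
) -> list[tuple[int, int]]:
    """Max-cardinality feasible matching with minimal total distance.

    Returns (row, col) index pairs into ``a_pos`` / ``b_pos``.
    """
    na, nb = len(a_pos), len(b_pos)
    if na == 0 or nb == 0:
        return []
    d = np.linalg.norm(a_pos[:, None, :] - b_pos[None, :, :], axis=2)
    cost = np.where(d <= max_dist, d, _BIG)
    size = na + nb
    padded = np.full((size, size), _BIG)
    padded[:na, :nb] = cost
    padded[na:, nb:] = 0.0
    for i in range(na):
        padded[i, nb + i] = max_dist  # leave a_i unmatched
    for j in range(nb):
        padded[na + j, j] = max_dist  # leave b_j unmatched
    rows, cols = linear_sum_assignment(padded)
    return [
        (int(r), int(c))
        for r, c in zip(rows, cols)
        if r < na and c < nb and d[r, c] <= max_dist
    ]


def _recently_mitotic(track: CellTrack, lookback: int = 3) -> bool:
    tail = [p.phase for p in track.points[-lookback:]]
    return any(p in ("metaphase", "anaphase") for p in tail if p is not None)


def track_cells(
    frames: list[LabeledFrame],
    max_link_distance: float = 15.0,
    restrict_splits: bool = False,
) -> list[CellTrack]:
    """Link segmented frames into cell tracks.

    Parameters
    ----------
    frames : list of LabeledFrame
        Consecutive frames (``frame_index`` strictly increasing by 1).
    max_link_distance : float
        Gating radius in pixels for any frame-to-frame link.
    restrict_splits : bool
        When phase labels are present, only allow a split if the parent
        track was labelled metaphase or anaphase within its last 3 frames
        (restricts one-to-two links to plausible mitoses).
    """
    idx = [f.frame_index for f in frames]
    if any(b - a != 1 for a, b in zip(idx, idx[1:])):
        raise ValueError("frames must be consecutive")

    tracks: list[CellTrack] = []

    def new_track(point: TrackPoint, parent_id: int | None = None) -> CellTrack:
        t = CellTrack(track_id=len(tracks) + 1, parent_id=parent_id)
        t.points.append(point)
        tracks.append(t)
        return t

    if not frames:
        return tracks

    active: dict[int, CellTrack] = {}
    for lab in sorted(frames[0].objects):
        active[lab] = new_track(_point(frames[0], lab))

    for prev, cur in zip(frames, frames[1:]):
        a_labels = sorted(active)
        b_labels = sorted(cur.objects)
        a_pos = np.array([prev.objects[l].centroid for l in a_labels], dtype=float)
        b_pos = np.array([cur.objects[l].centroid for l in b_labels], dtype=float)
        pairs = _pair_assignment(
            a_pos.reshape(-1, 2) if len(a_labels) else np.empty((0, 2)),
            b_pos.reshape(-1, 2) if len(b_labels) else np.empty((0, 2)),
            max_link_distance,
        )
        link_of_a = {a_labels[r]: b_labels[c] for r, c in pairs}
        link_of_b = {b_labels[c]: a_labels[r] for r, c in pairs}

        def dist(al: int, bl: int) -> float:
            return float(
                np.linalg.norm(
                    np.asarray(prev.objects[al].centroid)
                    - np.asarray(cur.objects[bl].centroid)
                )
            )

        # -- splits: unmatched new object adopted by a matched neighbour
        splits: dict[int, int] = {}  # parent a-label -> extra b-label
        spawned_new: list[int] = []
        for bl in b_labels:
            if bl in link_of_b:
                continue
            candidates = [
                al
                for al in a_labels
                if al in link_of_a
                and al not in splits
                and dist(al, bl) <= max_link_distance
            ]
            if restrict_splits:
                candidates = [al for al in candidates if _recently_mitotic(active[al])]
            if candidates:
                parent = min(candidates, key=lambda al: (dist(al, bl), al))
                splits[parent] = bl
            else:
                spawned_new.append(bl)

        next_active: dict[int, CellTrack] = {}
        for al in a_labels:
            track = active[al]
            if al in splits:
                b1, b2 = sorted([link_of_a[al], splits[al]])
                d1 = new_track(_point(cur, b1), parent_id=track.track_id)
                d2 = new_track(_point(cur, b2), parent_id=track.track_id)
                track.daughter_ids = (d1.track_id, d2.track_id)
                next_active[b1] = d1
                next_active[b2] = d2
            elif al in link_of_a:
                bl = link_of_a[al]
                track.points.append(_point(cur, bl))
                next_active[bl] = track
            else:
                # -- merge: unmatched old object absorbed by a linked successor
                near = [
                    bl
                    for bl in b_labels
                    if bl in link_of_b and dist(al, bl) <= max_link_distance
                ]
                if near:
                    target = min(near, key=lambda bl: (dist(al, bl), bl))
                    track.merged = True
                    track.merged_into = active[link_of_b[target]].track_id
                # track ends either way
        for bl in spawned_new:
            next_active[bl] = new_track(_point(cur, bl))
        active = next_active

    return tracks
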