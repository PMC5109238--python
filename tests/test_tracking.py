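"""Tracking against an exhaustive minimal-total-distance assignment oracle."""

from itertools import combinations, permutations

import numpy as np
import pytest

from mitoscreen.segmentation import LabeledFrame, SegmentedObject
from mitoscreen.tracking import track_cells


def frames_from_points(points_per_frame, phases_per_frame=None):
    """Build minimal LabeledFrames from per-frame centroid lists."""
    frames = []
    for f, pts in enumerate(points_per_frame):
        objs = {}
        for i, p in enumerate(pts):
            obj = SegmentedObject(
                label=i + 1,
                centroid=(float(p[0]), float(p[1])),
                area=1,
                mean_chromatin=0.0,
                mean_reporter_nuclear=0.0,
            )
            if phases_per_frame is not None:
                obj.phase = phases_per_frame[f][i]
            objs[i + 1] = obj
        frames.append(
            LabeledFrame(
                frame_index=f,
                image=np.zeros((2, 1, 1)),
                labels=np.zeros((1, 1), int),
                ring_labels=np.zeros((1, 1), int),
                objects=objs,
            )
        )
    return frames


def oracle_matching(a_pos, b_pos, max_dist):
    """Exhaustive search: maximum-cardinality feasible matching with
    minimal total distance, as (a_index, b_index) pairs (0-based)."""
    na, nb = len(a_pos), len(b_pos)
    d = np.linalg.norm(
        np.asarray(a_pos)[:, None, :] - np.asarray(b_pos)[None, :, :], axis=2
    )
    for k in range(min(na, nb), 0, -1):
        best = None
        for rows in combinations(range(na), k):
            for cols in permutations(range(nb), k):
                if all(d[r, c] <= max_dist for r, c in zip(rows, cols)):
                    tot = sum(d[r, c] for r, c in zip(rows, cols))
                    if best is None or tot < best[0] - 1e-12:
                        best = (tot, set(zip(rows, cols)))
        if best is not None:
            return best[1]
    return set()


def one_to_one_links(tracks, frame):
    """Links (label_t, label_t+1) realised by the tracker, excluding the
    extra daughter link of a split (splits add a second link)."""
    links = set()
    extra = set()
    by_id = {t.track_id: t for t in tracks}
    for t in tracks:
        for p, q in zip(t.points, t.points[1:]):
            if p.frame_index == frame:
                links.add((p.label, q.label))
        if t.daughter_ids and t.points[-1].frame_index == frame:
            d1, d2 = (by_id[d].points[0] for d in t.daughter_ids)
            pair = sorted(
                [d1, d2],
                key=lambda pt: np.linalg.norm(
                    np.array(pt.centroid) - np.array(t.points[-1].centroid)
                ),
            )
            links.add((t.points[-1].label, pair[0].label))
            extra.add((t.points[-1].label, pair[1].label))
    return links, extra


def test_single_stationary_object_single_track():
    frames = frames_from_points([[(50.0, 50.0)]] * 10)
    tracks = track_cells(frames)
    assert len(tracks) == 1 and len(tracks[0]) == 10


def test_split_creates_two_daughter_tracks():
    pts = [[(50.0, 50.0)]] * 3 + [[(46.0, 50.0), (54.0, 50.0)]] * 3
    tracks = track_cells(frames_from_points(pts))
    parent = next(t for t in tracks if t.daughter_ids)
    assert len(parent) == 3
    daughters = [t for t in tracks if t.parent_id == parent.track_id]
    assert len(daughters) == 2 and all(len(d) == 3 for d in daughters)


def test_merge_flagged_and_track_ends():
    pts = [[(40.0, 50.0), (60.0, 50.0)]] * 3 + [[(50.0, 50.0)]] * 2
    tracks = track_cells(frames_from_points(pts), max_link_distance=15.0)
    merged = [t for t in tracks if t.merged]
    assert len(merged) == 1 and merged[0].merged_into is not None


def test_crossing_trajectories_match_oracle():
    # two objects swap sides over 5 frames; straight-line interpolation
    a = np.linspace([10.0, 10.0], [10.0, 50.0], 5)
    b = np.linspace([10.0, 50.0], [10.0, 10.0], 5)
    pts = [[tuple(a[f]), tuple(b[f])] for f in range(5)]
    frames = frames_from_points(pts)
    tracks = track_cells(frames, max_link_distance=15.0)
    for f in range(4):
        links, extra = one_to_one_links(tracks, f)
        assert not extra
        oracle = {
            (r + 1, c + 1) for r, c in oracle_matching(pts[f], pts[f + 1], 15.0)
        }
        assert links == oracle


def test_random_instances_match_oracle():
    rng = np.random.default_rng(0)
    for trial in range(25):
        n_obj = int(rng.integers(2, 7))
        n_frames = int(rng.integers(2, 7))
        pos = rng.uniform(10, 90, size=(n_obj, 2))
        pts = []
        for _ in range(n_frames):
            pts.append([tuple(p) for p in pos])
            pos = pos + rng.normal(0, 3.0, size=pos.shape)
        frames = frames_from_points(pts)
        tracks = track_cells(frames, max_link_distance=15.0)
        for f in range(n_frames - 1):
            links, extra = one_to_one_links(tracks, f)
            oracle = {
                (r + 1, c + 1) for r, c in oracle_matching(pts[f], pts[f + 1], 15.0)
            }
            assert not extra  # constant object count: pure one-to-one
            assert links == oracle


def test_split_links_contain_oracle_assignment():
    pts = [
        [(50.0, 50.0), (20.0, 20.0)],
        [(50.0, 50.0), (20.0, 22.0)],
        [(46.0, 50.0), (54.0, 50.0), (20.0, 24.0)],
    ]
    frames = frames_from_points(pts)
    tracks = track_cells(frames, max_link_distance=15.0)
    links, extra = one_to_one_links(tracks, 1)
    oracle = {(r + 1, c + 1) for r, c in oracle_matching(pts[1], pts[2], 15.0)}
    assert oracle <= links | extra
    assert len(extra) == 1  # exactly one adopted daughter


def test_restricted_splits_require_recent_mitotic_phase():
    pts = [[(50.0, 50.0)]] * 3 + [[(46.0, 50.0), (54.0, 50.0)]]
    interphase = [["interphase"]] * 3 + [["interphase", "interphase"]]
    mitotic = [["prometaphase"], ["metaphase"], ["anaphase"]] + [
        ["anaphase", "anaphase"]
    ]
    t_blocked = track_cells(
        frames_from_points(pts, interphase), restrict_splits=True
    )
    assert not any(t.daughter_ids for t in t_blocked)
    t_allowed = track_cells(frames_from_points(pts, mitotic), restrict_splits=True)
    assert any(t.daughter_ids for t in t_allowed)


def test_distant_object_starts_new_track():
    pts = [[(20.0, 20.0)], [(20.0, 20.0), (90.0, 90.0)]]
    tracks = track_cells(frames_from_points(pts), max_link_distance=10.0)
    assert len(tracks) == 2
    assert all(t.parent_id is None for t in tracks)


def test_non_consecutive_frames_rejected():
    frames = frames_from_points([[(1.0, 1.0)], [(1.0, 1.0)]])
    frames[1].frame_index = 5
    with pytest.raises(ValueError):
        track_cells(frames)
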