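"""Frame-to-frame trajectory linking and per-track motility metrics.

Linking solves, per consecutive frame pair and lineage, a minimum-cost
one-to-one assignment with cost equal to centroid Euclidean distance;
links above ``max_link_distance_um`` are forbidden.  The objective is
equivalent to: maximise the number of admissible links, and among those
matchings minimise the total linked distance (leaving an object unlinked
costs ``max_link_distance_um``).  Track ends may afterwards be closed
across up to ``max_gap_frames`` missing frames, cheapest pair first,
under the same distance cap.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import linear_sum_assignment

from .config import Calibration
from .detection import Detection

_BIG = 1e12


@dataclass
class Track:
    """An ordered trajectory of detections for one cell."""

    track_id: int
    lineage: str
    items: list[tuple[int, Detection]] = field(default_factory=list)
    #: (last frame before gap, number of missing frames) per closed gap
    gaps: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        frames = [f for f, _ in self.items]
        if any(b <= a for a, b in zip(frames, frames[1:])):
            raise ValueError("track frames must be strictly increasing")

    @property
    def frames(self) -> list[int]:
        return [f for f, _ in self.items]

    @property
    def n_detections(self) -> int:
        return len(self.items)

    def centroids_um(self) -> np.ndarray:
        """(n, 2) array of (x, y) centroids in μm."""
        return np.array([d.centroid_um for _, d in self.items], dtype=float)


@dataclass(frozen=True)
class TrackMetrics:
    """Motility summary of one track; requires >= 2 detections."""

    mean_speed_um_min: float
    directionality_ratio: float | None
    path_length_um: float
    net_displacement_um: float
    duration_min: float


def _pair_assignment(prev_xy: np.ndarray, curr_xy: np.ndarray,
                     max_dist: float) -> list[tuple[int, int]]:
    """Optimal one-to-one links between two frames; no link above max_dist.

    Uses the standard augmented LAP: linking i->j costs d(i, j); leaving
    any object unlinked costs max_dist.  Since d <= max_dist < 2*max_dist,
    the solver maximises links and then minimises total distance.
    """
    n, m = len(prev_xy), len(curr_xy)
    if n == 0 or m == 0:
        return []
    d = np.linalg.norm(prev_xy[:, None, :] - curr_xy[None, :, :], axis=2)
    size = n + m
    cost = np.full((size, size), _BIG)
    cost[:n, :m] = np.where(d <= max_dist, d, _BIG)
    cost[np.arange(n), m + np.arange(n)] = max_dist      # prev i stays unlinked
    cost[n + np.arange(m), np.arange(m)] = max_dist      # curr j starts a track
    cost[n:, m:] = 0.0
    rows, cols = linear_sum_assignment(cost)
    return [(int(i), int(j)) for i, j in zip(rows, cols)
            if i < n and j < m and d[i, j] <= max_dist]


def link_tracks(detections: Sequence[Detection], max_link_distance_um: float,
                max_gap_frames: int = 0) -> list[Track]:
    """Link detections into tracks; every detection ends up in exactly one track."""
    if max_link_distance_um < 0:
        raise ValueError("max_link_distance_um must be non-negative")
    if max_gap_frames < 0:
        raise ValueError("max_gap_frames must be non-negative")

    tracks: list[Track] = []
    for lineage in sorted({d.lineage for d in detections}):
        dets = [d for d in detections if d.lineage == lineage]
        tracks.extend(_link_lineage(dets, max_link_distance_um, max_gap_frames))
    for i, t in enumerate(tracks):
        t.track_id = i
    return tracks


def _link_lineage(dets: Sequence[Detection], max_dist: float, max_gap: int) -> list[Track]:
    by_frame: dict[int, list[Detection]] = {}
    for d in dets:
        by_frame.setdefault(d.frame_index, []).append(d)
    for frame_dets in by_frame.values():
        frame_dets.sort(key=lambda d: d.object_id)  # deterministic tie order
    frames = sorted(by_frame)
    if not frames:
        return []

    lineage = dets[0].lineage
    tracks: list[Track] = [Track(track_id=-1, lineage=lineage, items=[(frames[0], d)])
                           for d in by_frame[frames[0]]]
    open_by_det: dict[int, Track] = {id(d): t for t, d in
                                     zip(tracks, by_frame[frames[0]])}

    prev_frame = frames[0]
    for frame in frames[1:]:
        curr = by_frame[frame]
        prev = by_frame.get(prev_frame, [])
        links = []
        if frame == prev_frame + 1 and prev:
            prev_xy = np.array([d.centroid_um for d in prev])
            curr_xy = np.array([d.centroid_um for d in curr])
            links = _pair_assignment(prev_xy, curr_xy, max_dist)
        linked_curr = set()
        for i, j in links:
            track = open_by_det.pop(id(prev[i]))
            track.items.append((frame, curr[j]))
            open_by_det[id(curr[j])] = track
            linked_curr.add(j)
        for j, d in enumerate(curr):
            if j not in linked_curr:
                t = Track(track_id=-1, lineage=lineage, items=[(frame, d)])
                tracks.append(t)
                open_by_det[id(d)] = t
        prev_frame = frame

    if max_gap > 0:
        tracks = _close_gaps(tracks, max_dist, max_gap)
    return tracks


def _close_gaps(tracks: list[Track], max_dist: float, max_gap: int) -> list[Track]:
    """Greedy cheapest-first joining of track ends to later track starts."""
    candidates = []
    for ei, end_track in enumerate(tracks):
        end_frame, end_det = end_track.items[-1]
        for si, start_track in enumerate(tracks):
            if si == ei:
                continue
            start_frame, start_det = start_track.items[0]
            n_missing = start_frame - end_frame - 1
            if not 1 <= n_missing <= max_gap:
                continue
            dist = float(np.linalg.norm(np.asarray(end_det.centroid_um)
                                        - np.asarray(start_det.centroid_um)))
            if dist <= max_dist:
                candidates.append((dist, end_det.object_id, start_det.object_id, ei, si))
    candidates.sort()

    merged_into = list(range(len(tracks)))
    used_end, used_start = set(), set()

    def root(i: int) -> int:
        while merged_into[i] != i:
            i = merged_into[i]
        return i

    for _dist, _eid, _sid, ei, si in candidates:
        ei, si = root(ei), root(si)
        if ei in used_end or si in used_start or ei == si:
            continue
        end_track, start_track = tracks[ei], tracks[si]
        if start_track.items[0][0] - end_track.items[-1][0] - 1 < 1:
            continue
        end_track.gaps.append((end_track.items[-1][0],
                               start_track.items[0][0] - end_track.items[-1][0] - 1))
        end_track.gaps.extend(start_track.gaps)
        end_track.items.extend(start_track.items)
        used_end.add(ei)
        used_start.add(si)
        merged_into[si] = ei

    return [t for i, t in enumerate(tracks) if root(i) == i]


def compute_metrics(track: Track, calibration: Calibration) -> TrackMetrics:
    """Path length, net displacement, duration, mean speed, directionality ratio.

    Mean speed is path length over elapsed time; gap segments contribute
    their straight-line distance.  The directionality ratio is net
    displacement / path length, undefined (None) for a zero-length path.
    """
    if track.n_detections < 2:
        raise ValueError("metrics require a track with at least 2 detections")
    xy = track.centroids_um()
    steps = np.linalg.norm(np.diff(xy, axis=0), axis=1)
    path_length = float(steps.sum())
    net = float(np.linalg.norm(xy[-1] - xy[0]))
    frames = track.frames
    duration = (frames[-1] - frames[0]) * calibration.frame_interval
    mean_speed = path_length / duration
    ratio = net / path_length if path_length > 0 else None
    return TrackMetrics(
        mean_speed_um_min=mean_speed,
        directionality_ratio=ratio,
        path_length_um=path_length,
        net_displacement_um=net,
        duration_min=duration,
    )
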