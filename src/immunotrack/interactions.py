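"""Cell-lesion surface distances, interaction events and summaries.

The per-frame distance of a tracked cell to a lesion is the minimum, over
the detection's boundary pixels, of the lesion's signed distance field,
clamped below at zero; a non-positive minimum sets the overlap flag.  For
neutrophils the measured surface is the cytoplasmic margin; for
macrophages it is the nuclear margin, which is why the close-proximity
threshold differs per lineage: < 20 μm for the neutrophil margin and
< 50 μm for macrophage nuclei (allowing for a ~30 μm average macrophage
radius).  Comparisons are strict.

An interaction event is a maximal run of consecutive frames-with-
detections whose distance is below the lineage threshold; runs are broken
by frames at or above the threshold and by track gaps.  An event is a
*contact* if any frame in the run has the overlap flag, otherwise *close*.
An n-frame run lasts ``n * frame_interval`` minutes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .lesion import LesionSeries
from .tracking import Track

#: Lineage-specific close-proximity thresholds (μm), strict comparison.
DEFAULT_THRESHOLDS_UM: dict[str, float] = {"neutrophil": 20.0, "macrophage": 50.0}


@dataclass
class DistanceSeries:
    """Surface distance of one track to one lesion, on frames with detections."""

    track_id: int
    lesion_id: str
    lineage: str
    frames: np.ndarray
    distance_um: np.ndarray
    overlap: np.ndarray

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=int)
        self.distance_um = np.asarray(self.distance_um, dtype=float)
        self.overlap = np.asarray(self.overlap, dtype=bool)
        if not (len(self.frames) == len(self.distance_um) == len(self.overlap)):
            raise ValueError("frames, distances and overlap flags must align")
        if np.any(self.distance_um[self.overlap] != 0.0):
            raise ValueError("overlap flag requires clamped distance 0")


@dataclass(frozen=True)
class InteractionEvent:
    """One maximal sub-threshold run; ``end_frame`` is inclusive."""

    track_id: int
    lesion_id: str
    lineage: str
    start_frame: int
    end_frame: int
    event_class: str  # "contact" | "close"
    min_distance_um: float
    duration_min: float

    def __post_init__(self) -> None:
        if self.end_frame < self.start_frame:
            raise ValueError("end_frame before start_frame")
        if self.event_class not in ("contact", "close"):
            raise ValueError(f"unknown event class {self.event_class!r}")


@dataclass
class InteractionSummary:
    """Per-lineage interaction counts and durations for one movie/fish."""

    lineage: str
    n_events: int
    n_contact: int
    n_close: int
    durations_min: list[float]
    total_duration_min: float
    n_tracks_interacting: int
    events_per_lesion: dict[str, int] = field(default_factory=dict)


def measure_distances(tracks: Sequence[Track], lesion_series: Sequence[LesionSeries],
                      ) -> list[DistanceSeries]:
    """Signed-field surface distances for every (track, lesion) pair.

    Requires a lesion mask on every frame where a track has a detection.
    """
    out = []
    for track in tracks:
        for lesion in lesion_series:
            frames, dists, overlaps = [], [], []
            for frame, det in track.items:
                fld = lesion.distance_field(frame)  # raises if no mask governs frame
                b = det.boundary_pixels()
                m_boundary = float(fld[b[:, 0], b[:, 1]].min())
                # Overlap is judged on the full pixel set: an object can cover
                # lesion pixels without any of its boundary pixels doing so.
                m_all = min(m_boundary,
                            float(fld[det.pixels[:, 0], det.pixels[:, 1]].min()))
                frames.append(frame)
                dists.append(0.0 if m_all <= 0.0 else m_boundary)
                overlaps.append(m_all <= 0.0)
            out.append(DistanceSeries(
                track_id=track.track_id, lesion_id=lesion.lesion_id,
                lineage=track.lineage, frames=np.array(frames, dtype=int),
                distance_um=np.array(dists), overlap=np.array(overlaps, dtype=bool),
            ))
    return out


def extract_runs(frames: np.ndarray, distance_um: np.ndarray, overlap: np.ndarray,
                 threshold_um: float) -> list[tuple[int, int, bool, float]]:
    """Maximal runs of consecutive frames with distance strictly below threshold.

    Returns (start_frame, end_frame, any_overlap, min_distance) tuples.
    Runs break at frames >= threshold and wherever consecutive
    frames-with-detections are not adjacent (track gaps).
    """
    if threshold_um <= 0:
        raise ValueError("threshold must be positive")
    runs = []
    start = None
    prev_frame = None
    any_overlap = False
    min_dist = np.inf
    for f, d, o in zip(frames, distance_um, overlap):
        below = d < threshold_um
        gap_break = prev_frame is not None and f != prev_frame + 1
        if start is not None and (not below or gap_break):
            runs.append((start, prev_frame, any_overlap, min_dist))
            start = None
        if below and start is None:
            start, any_overlap, min_dist = int(f), bool(o), float(d)
        elif below:
            any_overlap = any_overlap or bool(o)
            min_dist = min(min_dist, float(d))
        prev_frame = int(f)
    if start is not None:
        runs.append((start, prev_frame, any_overlap, min_dist))
    return runs


def classify_and_extract_events(distance_series: Iterable[DistanceSeries],
                                frame_interval: float,
                                thresholds_um: Mapping[str, float] | None = None,
                                ) -> list[InteractionEvent]:
    """Extract contact / close interaction events from distance series."""
    thresholds = dict(DEFAULT_THRESHOLDS_UM)
    if thresholds_um:
        thresholds.update(thresholds_um)
    events = []
    for ds in distance_series:
        thr = thresholds[ds.lineage]
        for start, end, any_overlap, min_dist in extract_runs(
                ds.frames, ds.distance_um, ds.overlap, thr):
            n = end - start + 1
            events.append(InteractionEvent(
                track_id=ds.track_id, lesion_id=ds.lesion_id, lineage=ds.lineage,
                start_frame=start, end_frame=end,
                event_class="contact" if any_overlap else "close",
                min_distance_um=min_dist,
                duration_min=n * frame_interval,
            ))
    return events


def summarise_interactions(events: Sequence[InteractionEvent], tracks: Sequence[Track],
                           frame_interval: float) -> dict[str, InteractionSummary]:
    """Per-lineage event counts, individual and total durations, per one movie."""
    lineages = sorted({t.lineage for t in tracks} | {e.lineage for e in events})
    out = {}
    for lineage in lineages:
        evs = [e for e in events if e.lineage == lineage]
        durations = [e.duration_min for e in evs]
        per_lesion: dict[str, int] = {}
        for e in evs:
            per_lesion[e.lesion_id] = per_lesion.get(e.lesion_id, 0) + 1
        out[lineage] = InteractionSummary(
            lineage=lineage,
            n_events=len(evs),
            n_contact=sum(e.event_class == "contact" for e in evs),
            n_close=sum(e.event_class == "close" for e in evs),
            durations_min=durations,
            total_duration_min=float(sum(durations)),
            n_tracks_interacting=len({e.track_id for e in evs}),
            events_per_lesion=per_lesion,
        )
    return out


def count_in_fov(objects, fov_rect_um: tuple[float, float, float, float]) -> int:
    """Count objects whose centroid lies in the half-open rectangle
    ``[x0, x1) x [y0, y1)`` (μm).

    ``objects`` is an iterable of detections/tracked objects exposing
    ``centroid_um`` or of (x, y) pairs.  The reference field of view is
    660 μm x 310 μm.
    """
    x0, y0, x1, y1 = fov_rect_um
    if not (x1 > x0 and y1 > y0):
        raise ValueError("degenerate field-of-view rectangle")
    count = 0
    for obj in objects:
        x, y = obj.centroid_um if hasattr(obj, "centroid_um") else obj
        if x0 <= x < x1 and y0 <= y < y1:
            count += 1
    return count
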