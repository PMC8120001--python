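"""End-to-end analysis pipeline: movie + annotations -> tables.

Glues the stages together with one parameter object so the CLI, the test
suite and batch scripts run the identical chain: segmentation of both
lineages, track linking, lesion rasterisation, distance measurement,
event extraction, motility metrics and per-movie summaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .config import Calibration, ChannelRole
from .detection import (Detection, PixelClassifier, apply_corrections,
                        segment_cytoplasmic, segment_nuclei, train_pixel_classifier)
from .interactions import (DEFAULT_THRESHOLDS_UM, classify_and_extract_events,
                           measure_distances, summarise_interactions)
from .lesion import rasterise_annotations
from .movie_io import AnnotationFile, MovieStack
from .tracking import Track, compute_metrics, link_tracks


@dataclass
class AnalysisParams:
    """Tunable parameters of the analysis chain (defaults are engineering
    choices; the close-proximity thresholds are the lineage defaults)."""

    neutrophil_threshold: float | str = "otsu"
    smoothing_sigma: float = 1.0
    neutrophil_min_area_um2: float = 30.0
    neutrophil_max_area_um2: float = 800.0
    macrophage_min_area_um2: float = 10.0
    macrophage_max_area_um2: float = 300.0
    prob_threshold: float = 0.5
    classifier_seed: int = 0
    max_link_distance_um: float = 30.0
    max_gap_frames: int = 2
    thresholds_um: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_THRESHOLDS_UM))

    @classmethod
    def from_config(cls, cfg: Mapping) -> "AnalysisParams":
        params = cls()
        seg = cfg.get("segmentation", {})
        for key in ("neutrophil_threshold", "smoothing_sigma", "prob_threshold",
                    "classifier_seed", "neutrophil_min_area_um2", "neutrophil_max_area_um2",
                    "macrophage_min_area_um2", "macrophage_max_area_um2"):
            if key in seg:
                setattr(params, key, seg[key])
        trk = cfg.get("tracking", {})
        if "max_link_distance_um" in trk:
            params.max_link_distance_um = float(trk["max_link_distance_um"])
        if "max_gap_frames" in trk:
            params.max_gap_frames = int(trk["max_gap_frames"])
        inter = cfg.get("interactions", {})
        if "thresholds_um" in inter:
            params.thresholds_um.update(
                {str(k): float(v) for k, v in inter["thresholds_um"].items()})
        return params


def auto_train_classifier(stack: MovieStack, params: AnalysisParams) -> PixelClassifier:
    """Bootstrap a nucleus pixel classifier from the movie itself.

    High-confidence sparse labels are harvested from the first frame of
    the macrophage channel: eroded Otsu foreground as nucleus pixels,
    eroded Otsu background as background pixels.  Deterministic given the
    classifier seed.
    """
    from skimage.filters import threshold_otsu

    img = stack.channel(ChannelRole.MACROPHAGE)[0].astype(float)
    smoothed = ndimage.gaussian_filter(img, 1.0)
    t = threshold_otsu(smoothed)
    # Symmetric 1-px margins keep the learned 0.5 contour on the Otsu contour.
    fg = ndimage.binary_erosion(smoothed >= t, iterations=1)
    bg = ndimage.binary_erosion(smoothed < t, iterations=1)
    labels = np.zeros(img.shape, dtype=np.uint8)
    labels[bg] = 1
    labels[fg] = 2
    if not fg.any() or not bg.any():
        raise ValueError("could not harvest training labels; supply a trained classifier")
    return train_pixel_classifier([img], [labels], seed=params.classifier_seed)


def segment_movie(stack: MovieStack, params: AnalysisParams,
                  classifier: PixelClassifier | None = None,
                  corrections: Sequence[Mapping] | None = None) -> list[Detection]:
    """Segment both lineages on every frame of a movie."""
    px = stack.calibration.pixel_size
    detections: list[Detection] = []
    neut = stack.channel(ChannelRole.NEUTROPHIL)
    for f in range(stack.n_frames):
        detections.extend(segment_cytoplasmic(
            neut[f], params.neutrophil_threshold,
            params.neutrophil_min_area_um2, params.neutrophil_max_area_um2,
            px, frame_index=f, smoothing_sigma=params.smoothing_sigma))
    try:
        mac = stack.channel(ChannelRole.MACROPHAGE)
    except KeyError:
        mac = None
    if mac is not None:
        if classifier is None:
            classifier = auto_train_classifier(stack, params)
        for f in range(stack.n_frames):
            detections.extend(segment_nuclei(
                mac[f], classifier, params.prob_threshold,
                params.macrophage_min_area_um2, params.macrophage_max_area_um2,
                px, frame_index=f))
    if corrections:
        detections = apply_corrections(detections, corrections,
                                       image_shape=(stack.height, stack.width))
    return detections


@dataclass
class PipelineResult:
    """All intermediate and final products of one movie's analysis."""

    fish: str
    calibration: Calibration
    detections: list[Detection]
    tracks: list[Track]
    distance_series: list
    events: list
    summaries: dict

    def tables(self) -> dict[str, pd.DataFrame]:
        """Result tables matching the documented CSV schemas."""
        det_rows = [{
            "fish": self.fish, "frame": d.frame_index, "channel_role": d.lineage,
            "object_id": d.object_id, "centroid_x_um": d.centroid_um[0],
            "centroid_y_um": d.centroid_um[1], "area_um2": d.area_um2,
        } for d in self.detections]

        track_rows = [{
            "fish": self.fish, "track_id": t.track_id, "lineage": t.lineage,
            "frame": f, "object_id": d.object_id,
            "centroid_x_um": d.centroid_um[0], "centroid_y_um": d.centroid_um[1],
        } for t in self.tracks for f, d in t.items]

        dist_rows = [{
            "fish": self.fish, "track_id": ds.track_id, "lesion_id": ds.lesion_id,
            "frame": int(f), "distance_um": float(d), "overlap": bool(o),
        } for ds in self.distance_series
            for f, d, o in zip(ds.frames, ds.distance_um, ds.overlap)]

        event_rows = [{
            "fish": self.fish, "track_id": e.track_id, "lesion_id": e.lesion_id,
            "lineage": e.lineage, "start_frame": e.start_frame, "end_frame": e.end_frame,
            "class": e.event_class, "min_distance_um": e.min_distance_um,
            "duration_min": e.duration_min,
        } for e in self.events]

        metric_rows = []
        for t in self.tracks:
            if t.n_detections < 2:
                continue
            m = compute_metrics(t, self.calibration)
            metric_rows.append({
                "fish": self.fish, "track_id": t.track_id, "lineage": t.lineage,
                "mean_speed_um_min": m.mean_speed_um_min,
                "directionality_ratio": m.directionality_ratio,
                "path_length_um": m.path_length_um,
                "net_displacement_um": m.net_displacement_um,
                "duration_min": m.duration_min,
            })

        summary_rows = [{
            "fish": self.fish, "lineage": lineage, "n_events": s.n_events,
            "n_contact": s.n_contact, "n_close": s.n_close,
            "total_duration_min": s.total_duration_min,
            "n_tracks_interacting": s.n_tracks_interacting,
        } for lineage, s in self.summaries.items()]

        return {
            "detections": pd.DataFrame(det_rows),
            "tracks": pd.DataFrame(track_rows),
            "distances": pd.DataFrame(dist_rows),
            "events": pd.DataFrame(event_rows),
            "metrics": pd.DataFrame(metric_rows),
            "summary": pd.DataFrame(summary_rows),
        }


def analyse_movie(stack: MovieStack, annotations: Sequence[AnnotationFile],
                  params: AnalysisParams | None = None,
                  classifier: PixelClassifier | None = None,
                  corrections: Sequence[Mapping] | None = None,
                  fish: str = "fish0") -> PipelineResult:
    """Run the full chain on one movie."""
    params = params or AnalysisParams()
    detections = segment_movie(stack, params, classifier, corrections)
    tracks = link_tracks(detections, params.max_link_distance_um, params.max_gap_frames)
    lesion_series = rasterise_annotations(
        annotations, (stack.height, stack.width), stack.n_frames,
        stack.calibration.pixel_size)
    distance_series = measure_distances(tracks, lesion_series)
    events = classify_and_extract_events(
        distance_series, stack.calibration.frame_interval, params.thresholds_um)
    summaries = summarise_interactions(events, tracks, stack.calibration.frame_interval)
    return PipelineResult(fish=fish, calibration=stack.calibration,
                          detections=detections, tracks=tracks,
                          distance_series=distance_series, events=events,
                          summaries=summaries)
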