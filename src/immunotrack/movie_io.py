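"""Reading and writing calibrated movies, lesion annotations and tables.

Coordinate conventions used throughout the package:

* pixel indices are 0-based with origin at the top-left, y increasing
  downward; physical coordinates are ``index * pixel_size`` (μm);
* polygon annotation coordinates follow the raster-corner convention of
  common annotation tools: integer coordinate ``x`` is the left edge of
  pixel column ``x``, so pixel ``(row i, col j)`` has its centre at
  ``(j + 0.5, i + 0.5)`` in annotation space;
* Z-stacks are reduced by maximum-intensity projection before analysis.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import tifffile

from . import ijroi
from .config import Calibration

logger = logging.getLogger(__name__)


@dataclass
class MovieStack:
    """A calibrated multi-channel time-lapse stack.

    ``pixels`` is indexed ``(frame, channel, y, x)`` and holds finite,
    non-negative intensities.
    """

    pixels: np.ndarray
    calibration: Calibration

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 4:
            raise ValueError(f"pixels must be 4-D (frame, channel, y, x), got {self.pixels.ndim}-D")
        if self.pixels.shape[0] < 1:
            raise ValueError("movie must contain at least one frame")
        if np.issubdtype(self.pixels.dtype, np.floating):
            if not np.all(np.isfinite(self.pixels)):
                raise ValueError("pixel intensities must be finite")
        if self.pixels.size and self.pixels.min() < 0:
            raise ValueError("pixel intensities must be non-negative")
        for idx in self.calibration.channel_roles:
            if idx >= self.n_channels:
                raise ValueError(
                    f"channel_roles references channel {idx} but movie has {self.n_channels} channels"
                )

    @property
    def n_frames(self) -> int:
        return self.pixels.shape[0]

    @property
    def n_channels(self) -> int:
        return self.pixels.shape[1]

    @property
    def height(self) -> int:
        return self.pixels.shape[2]

    @property
    def width(self) -> int:
        return self.pixels.shape[3]

    def channel(self, role) -> np.ndarray:
        """All frames of the channel carrying the given role, shape (T, Y, X)."""
        return self.pixels[:, self.calibration.channel_for(role)]


@dataclass
class AnnotationFile:
    """Time-keyed polygon outlines for one lesion.

    ``keyframes`` maps strictly increasing 0-based frame indices to polygon
    vertex lists ``[(x, y), ...]`` in pixel (annotation-corner) coordinates.
    """

    lesion_id: str
    keyframes: list[tuple[int, np.ndarray]] = field(default_factory=list)

    def __post_init__(self) -> None:
        cleaned = []
        last_frame = -1
        for frame, verts in self.keyframes:
            frame = int(frame)
            verts = np.asarray(verts, dtype=float)
            if frame <= last_frame:
                raise ValueError(f"keyframe frames must be strictly increasing (lesion {self.lesion_id})")
            if verts.ndim != 2 or verts.shape[1] != 2 or verts.shape[0] < 3:
                raise ValueError(f"polygon must have >= 3 (x, y) vertices (lesion {self.lesion_id}, frame {frame})")
            if _polygon_self_intersects(verts):
                raise ValueError(f"polygon is self-intersecting (lesion {self.lesion_id}, frame {frame})")
            cleaned.append((frame, verts))
            last_frame = frame
        self.keyframes = cleaned

    def validate_bounds(self, height: int, width: int) -> None:
        for frame, verts in self.keyframes:
            if (verts[:, 0].min() < 0 or verts[:, 1].min() < 0
                    or verts[:, 0].max() > width or verts[:, 1].max() > height):
                raise ValueError(
                    f"lesion {self.lesion_id} frame {frame}: vertex outside image bounds "
                    f"({width}x{height})"
                )


def _polygon_self_intersects(verts: np.ndarray) -> bool:
    from shapely.geometry import Polygon

    return not Polygon(verts).is_simple


_AXIS_CHARS = set("TCZYX")


def read_movie(path: str | Path, calibration: Calibration, axes: str | None = None) -> MovieStack:
    """Read a TIFF/OME-TIFF stack and normalise axes to (frame, channel, y, x).

    Calibration comes from ``calibration`` (user config); embedded pixel-size
    metadata, if present and different, only triggers a warning.  ``axes``
    overrides the axis layout recorded in the file (a string over T, C, Z,
    Y, X, e.g. ``"TCYX"``); it is required when the file does not
    unambiguously declare its layout.
    """
    path = Path(path)
    with tifffile.TiffFile(path) as tf:
        series = tf.series[0]
        data = series.asarray()
        file_axes = series.axes.upper()
        _warn_on_metadata_mismatch(tf, calibration)

    layout = axes.upper() if axes else file_axes
    if len(layout) != data.ndim:
        raise ValueError(f"axis layout {layout!r} does not match array with {data.ndim} dimensions")
    if not set(layout) <= _AXIS_CHARS:
        unknown = set(layout) - _AXIS_CHARS
        raise ValueError(
            f"ambiguous axis layout {layout!r} (unknown axes {sorted(unknown)}); "
            "pass an explicit axes flag such as 'TCYX'"
        )
    if "Y" not in layout or "X" not in layout:
        raise ValueError(f"axis layout {layout!r} lacks Y/X image axes")

    # Insert missing T/C/Z as singleton axes, then order as T, C, Z, Y, X.
    for ax in "TCZ":
        if ax not in layout:
            data = data[np.newaxis]
            layout = ax + layout
    order = [layout.index(ax) for ax in "TCZYX"]
    data = np.transpose(data, order)
    if data.shape[2] > 1:
        data = data.max(axis=2)  # max-intensity projection over Z
    else:
        data = data[:, :, 0]
    return MovieStack(pixels=data, calibration=calibration)


def _warn_on_metadata_mismatch(tf: "tifffile.TiffFile", calibration: Calibration) -> None:
    try:
        page = tf.pages[0]
        res = page.tags.get("XResolution")
        if res is None:
            return
        num, den = res.value
        if num == 0:
            return
        meta_pixel_size = den / num  # resolution is pixels per unit
        if not np.isclose(meta_pixel_size, calibration.pixel_size, rtol=0.01):
            logger.warning(
                "embedded pixel size %.4g differs from configured %.4g μm/px; using configuration",
                meta_pixel_size, calibration.pixel_size,
            )
    except Exception:  # metadata is best-effort only
        pass


def write_movie(stack: MovieStack, path: str | Path) -> None:
    """Write a MovieStack as a TIFF with TCYX axes metadata."""
    tifffile.imwrite(
        Path(path),
        stack.pixels,
        photometric="minisblack",
        metadata={"axes": "TCYX"},
        resolution=(1.0 / stack.calibration.pixel_size, 1.0 / stack.calibration.pixel_size),
    )


# ---------------------------------------------------------------------------
# Annotations


def read_annotations(path: str | Path, dialect: str | None = None,
                     image_shape: tuple[int, int] | None = None) -> list[AnnotationFile]:
    """Read lesion annotations from the JSON dialect or ImageJ ``.roi``/``.zip``.

    ``dialect`` is ``"json"`` or ``"imagej"``; inferred from the file suffix
    when omitted.  ImageJ frame positions are 1-based in the format and are
    converted to 0-based here (an unset position maps to frame 0).  If
    ``image_shape`` (height, width) is given, vertices are bounds-checked.
    """
    path = Path(path)
    if dialect is None:
        dialect = "json" if path.suffix.lower() == ".json" else "imagej"
    if dialect == "json":
        annos = _read_annotations_json(path)
    elif dialect == "imagej":
        annos = _read_annotations_imagej(path)
    else:
        raise ValueError(f"unknown annotation dialect {dialect!r}")
    if image_shape is not None:
        h, w = image_shape
        for anno in annos:
            anno.validate_bounds(h, w)
    return annos


def _read_annotations_json(path: Path) -> list[AnnotationFile]:
    with open(path) as fh:
        payload = json.load(fh)
    entries = payload if isinstance(payload, list) else [payload]
    annos = []
    for entry in entries:
        seen = set()
        keyframes = []
        for kf in entry["keyframes"]:
            frame = int(kf["frame"])
            if frame in seen:
                raise ValueError(f"duplicate keyframe at frame {frame} for lesion {entry['lesion_id']}")
            seen.add(frame)
            keyframes.append((frame, np.asarray(kf["vertices"], dtype=float)))
        keyframes.sort(key=lambda kv: kv[0])
        annos.append(AnnotationFile(lesion_id=str(entry["lesion_id"]), keyframes=keyframes))
    return annos


def _read_annotations_imagej(path: Path) -> list[AnnotationFile]:
    rois = ijroi.read_roi_file(path)
    by_lesion: dict[str, dict[int, np.ndarray]] = {}
    for roi in rois:
        # "lesionid-suffix" names group ROIs; unnamed ROIs share one lesion.
        lesion_id = roi.name.split("-")[0] if roi.name else "lesion"
        frame = max(roi.t_position, 1) - 1  # 1-based in the format
        frames = by_lesion.setdefault(lesion_id, {})
        if frame in frames:
            raise ValueError(f"duplicate keyframe at frame {frame} for lesion {lesion_id}")
        frames[frame] = np.asarray(roi.vertices, dtype=float)
    return [
        AnnotationFile(lesion_id=lid, keyframes=sorted(frames.items()))
        for lid, frames in sorted(by_lesion.items())
    ]


def write_annotations_json(annotations: Sequence[AnnotationFile], path: str | Path) -> None:
    """Write annotations in the package's JSON dialect (exact round-trip)."""
    payload = [
        {
            "lesion_id": anno.lesion_id,
            "keyframes": [
                {"frame": frame, "vertices": np.asarray(verts, dtype=float).tolist()}
                for frame, verts in anno.keyframes
            ],
        }
        for anno in annotations
    ]
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)


# ---------------------------------------------------------------------------
# Tabular output

#: Column schemas for the CSV outputs, in written order.
TABLE_SCHEMAS: dict[str, list[str]] = {
    "detections": ["fish", "frame", "channel_role", "object_id",
                   "centroid_x_um", "centroid_y_um", "area_um2"],
    "tracks": ["fish", "track_id", "lineage", "frame", "object_id",
               "centroid_x_um", "centroid_y_um"],
    "distances": ["fish", "track_id", "lesion_id", "frame", "distance_um", "overlap"],
    "events": ["fish", "track_id", "lesion_id", "lineage", "start_frame", "end_frame",
               "class", "min_distance_um", "duration_min"],
    "metrics": ["fish", "track_id", "lineage", "mean_speed_um_min", "directionality_ratio",
                "path_length_um", "net_displacement_um", "duration_min"],
    "summary": ["fish", "lineage", "n_events", "n_contact", "n_close",
                "total_duration_min", "n_tracks_interacting"],
}

_SORT_KEYS = ["fish", "lineage", "channel_role", "track_id", "lesion_id",
              "object_id", "frame", "start_frame"]


def write_tables(results: Mapping[str, pd.DataFrame], out_dir: str | Path) -> dict[str, Path]:
    """Write result tables as CSVs with documented schemas.

    Rows are sorted deterministically (fish, then track/object, then frame).
    Unknown table names are written as-is.  Returns name -> written path.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = {}
    for name, df in results.items():
        df = pd.DataFrame(df)
        schema = TABLE_SCHEMAS.get(name)
        if schema is not None:
            missing = [c for c in schema if c not in df.columns]
            if missing and len(df):
                raise ValueError(f"table {name!r} missing columns {missing}")
            if not len(df):
                df = pd.DataFrame(columns=schema)
            df = df[schema + [c for c in df.columns if c not in schema]]
        keys = [k for k in _SORT_KEYS if k in df.columns]
        if keys and len(df):
            df = df.sort_values(keys, kind="mergesort").reset_index(drop=True)
        dest = out_dir / f"{name}.csv"
        df.to_csv(dest, index=False)
        written[name] = dest
    return written
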