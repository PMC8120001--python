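"""Per-frame segmentation of cytoplasmic and nuclear signals.

Neutrophils carry a cytoplasmic marker and are segmented by binarisation
(fixed or automatic threshold) followed by connected-components labelling.
Macrophage nuclei are segmented via trainable pixel classification to a
probability map, binarised at a fixed probability, then labelled the same
way.  Both routes apply area filters to remove noise, and manual
correction directives (delete / merge / split / add) can patch individual
frames.

Components are 8-connected; labels are assigned in raster-scan order of
each component's first (topmost, then leftmost) pixel.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import ndimage
from skimage.draw import line as draw_line
from skimage.filters import threshold_otsu
from sklearn.linear_model import LogisticRegression
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler

from .lesion import boundary_mask, rasterise_polygon

_STRUCT8 = ndimage.generate_binary_structure(2, 2)

LINEAGES = ("neutrophil", "macrophage")


@dataclass
class Detection:
    """One segmented object in one frame.

    ``pixels`` is an (n, 2) array of (row, col) indices; the pixel set must
    be non-empty and 8-connected.  Physical quantities use
    ``coordinate = index * pixel_size``.
    """

    frame_index: int
    object_id: int
    lineage: str
    pixels: np.ndarray
    pixel_size: float

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.intp).reshape(-1, 2)
        if self.lineage not in LINEAGES:
            raise ValueError(f"unknown lineage {self.lineage!r}")
        if len(self.pixels) == 0:
            raise ValueError("detection pixel set is empty")
        if not _is_connected(self.pixels):
            raise ValueError("detection pixel set is not 8-connected")

    @property
    def area_um2(self) -> float:
        return len(self.pixels) * self.pixel_size ** 2

    @property
    def centroid_um(self) -> tuple[float, float]:
        """(x, y) centroid in μm."""
        cy, cx = self.pixels.mean(axis=0)
        return (float(cx) * self.pixel_size, float(cy) * self.pixel_size)

    @property
    def centroid_xy(self) -> np.ndarray:
        return np.asarray(self.centroid_um)

    def boundary_pixels(self) -> np.ndarray:
        """(n, 2) array of (row, col) object pixels with a 4-neighbour outside."""
        rmin, cmin = self.pixels.min(axis=0)
        rmax, cmax = self.pixels.max(axis=0)
        local = np.zeros((rmax - rmin + 3, cmax - cmin + 3), dtype=bool)
        local[self.pixels[:, 0] - rmin + 1, self.pixels[:, 1] - cmin + 1] = True
        b = boundary_mask(local)
        rows, cols = np.nonzero(b)
        return np.column_stack([rows + rmin - 1, cols + cmin - 1])


def _is_connected(pixels: np.ndarray) -> bool:
    if len(pixels) == 1:
        return True
    rmin, cmin = pixels.min(axis=0)
    rmax, cmax = pixels.max(axis=0)
    local = np.zeros((rmax - rmin + 1, cmax - cmin + 1), dtype=bool)
    local[pixels[:, 0] - rmin, pixels[:, 1] - cmin] = True
    _, n = ndimage.label(local, structure=_STRUCT8)
    return n == 1


def label_components(mask: np.ndarray) -> tuple[np.ndarray, int]:
    """8-connected component labelling; labels follow raster order of first pixels."""
    return ndimage.label(np.asarray(mask, dtype=bool), structure=_STRUCT8)


def _components_to_detections(mask: np.ndarray, frame_index: int, lineage: str,
                              pixel_size: float, min_area_um2: float,
                              max_area_um2: float) -> list[Detection]:
    if max_area_um2 < min_area_um2:
        raise ValueError("max_area_um2 < min_area_um2")
    labels, n = label_components(mask)
    detections = []
    object_id = 0
    for lab in range(1, n + 1):
        rows, cols = np.nonzero(labels == lab)
        area = len(rows) * pixel_size ** 2
        if not (min_area_um2 <= area <= max_area_um2):
            continue
        detections.append(Detection(
            frame_index=frame_index,
            object_id=object_id,
            lineage=lineage,
            pixels=np.column_stack([rows, cols]),
            pixel_size=pixel_size,
        ))
        object_id += 1
    return detections


def segment_cytoplasmic(frame_image: np.ndarray, threshold_spec, min_area_um2: float,
                        max_area_um2: float, pixel_size: float, *,
                        frame_index: int = 0, lineage: str = "neutrophil",
                        smoothing_sigma: float = 0.0) -> list[Detection]:
    """Segment a cytoplasmic-marker channel by threshold + labelling.

    ``threshold_spec`` is a fixed intensity (pixels >= threshold are
    foreground) or the automatic method name ``"otsu"``.  Components with
    area outside ``[min_area_um2, max_area_um2]`` are discarded.  A blank
    frame yields an empty list.
    """
    img = np.asarray(frame_image, dtype=float)
    if img.ndim != 2:
        raise ValueError("frame_image must be 2-D")
    if smoothing_sigma > 0:
        img = ndimage.gaussian_filter(img, smoothing_sigma)
    if isinstance(threshold_spec, str):
        if threshold_spec.lower() != "otsu":
            raise ValueError(f"unknown automatic threshold method {threshold_spec!r}")
        if img.max() == img.min():
            return []
        threshold = threshold_otsu(img)
    else:
        threshold = float(threshold_spec)
    mask = img >= threshold
    return _components_to_detections(mask, frame_index, lineage, pixel_size,
                                     min_area_um2, max_area_um2)


# ---------------------------------------------------------------------------
# Trainable pixel classification (nuclear channel)

DEFAULT_SMOOTH_SIGMAS = (1.0, 2.0, 4.0)
DEFAULT_DERIV_SIGMAS = (1.0, 2.0)


def feature_stack(image: np.ndarray,
                  smooth_sigmas: Sequence[float] = DEFAULT_SMOOTH_SIGMAS,
                  deriv_sigmas: Sequence[float] = DEFAULT_DERIV_SIGMAS) -> np.ndarray:
    """Multi-scale feature bank: raw intensity, Gaussian smoothings,
    gradient magnitude and Laplacian at several scales.  Shape (y, x, f)."""
    img = np.asarray(image, dtype=float)
    feats = [img]
    for s in smooth_sigmas:
        feats.append(ndimage.gaussian_filter(img, s))
    for s in deriv_sigmas:
        feats.append(ndimage.gaussian_gradient_magnitude(img, s))
    for s in deriv_sigmas:
        feats.append(ndimage.gaussian_laplace(img, s))
    return np.stack(feats, axis=-1)


@dataclass
class PixelClassifier:
    """Probabilistic per-pixel nucleus classifier over a fixed feature bank."""

    smooth_sigmas: tuple[float, ...] = DEFAULT_SMOOTH_SIGMAS
    deriv_sigmas: tuple[float, ...] = DEFAULT_DERIV_SIGMAS
    model: Pipeline | None = None
    n_labelled: dict[str, int] = field(default_factory=dict)
    seed: int | None = None

    @property
    def trained(self) -> bool:
        return self.model is not None

    def predict_proba_map(self, image: np.ndarray) -> np.ndarray:
        """P(nucleus) per pixel, shape equal to ``image``; values in [0, 1]."""
        if not self.trained:
            raise ValueError("classifier has not been trained")
        feats = feature_stack(image, self.smooth_sigmas, self.deriv_sigmas)
        flat = feats.reshape(-1, feats.shape[-1])
        proba = self.model.predict_proba(flat)[:, 1]
        return proba.reshape(image.shape)


def train_pixel_classifier(images: Sequence[np.ndarray], sparse_labels: Sequence[np.ndarray],
                           seed: int, *,
                           smooth_sigmas: Sequence[float] = DEFAULT_SMOOTH_SIGMAS,
                           deriv_sigmas: Sequence[float] = DEFAULT_DERIV_SIGMAS,
                           max_samples: int = 200_000) -> PixelClassifier:
    """Train a pixel classifier from sparse labels.

    ``sparse_labels[i]`` matches ``images[i]`` in shape with values
    0 = unlabelled, 1 = background, 2 = nucleus.  Both classes need at
    least one labelled pixel.  Training is deterministic given ``seed``
    (used to subsample when more than ``max_samples`` pixels are labelled).
    """
    if len(images) != len(sparse_labels) or not images:
        raise ValueError("need matching, non-empty image and label sequences")
    X_parts, y_parts = [], []
    for img, lab in zip(images, sparse_labels):
        img = np.asarray(img)
        lab = np.asarray(lab)
        if img.shape != lab.shape:
            raise ValueError("label array shape must match image shape")
        sel = lab > 0
        if sel.any():
            feats = feature_stack(img, smooth_sigmas, deriv_sigmas)
            X_parts.append(feats[sel])
            y_parts.append((lab[sel] == 2).astype(int))
    if not X_parts:
        raise ValueError("no labelled pixels supplied")
    X = np.concatenate(X_parts)
    y = np.concatenate(y_parts)
    n_bg, n_fg = int((y == 0).sum()), int((y == 1).sum())
    if n_bg == 0 or n_fg == 0:
        raise ValueError(f"both classes need labelled pixels (background={n_bg}, nucleus={n_fg})")
    rng = np.random.default_rng(seed)
    if len(y) > max_samples:
        keep = rng.choice(len(y), size=max_samples, replace=False)
        keep.sort()
        X, y = X[keep], y[keep]
    model = Pipeline([
        ("scale", StandardScaler()),
        ("clf", LogisticRegression(max_iter=2000, C=10.0)),
    ])
    model.fit(X, y)
    return PixelClassifier(
        smooth_sigmas=tuple(smooth_sigmas),
        deriv_sigmas=tuple(deriv_sigmas),
        model=model,
        n_labelled={"background": n_bg, "nucleus": n_fg},
        seed=seed,
    )


def segment_nuclei(frame_image: np.ndarray, classifier: PixelClassifier,
                   prob_threshold: float, min_area_um2: float, max_area_um2: float,
                   pixel_size: float, *, frame_index: int = 0,
                   lineage: str = "macrophage") -> list[Detection]:
    """Segment nuclei: probability map >= ``prob_threshold`` -> components -> size filter."""
    if not 0 < prob_threshold < 1:
        raise ValueError(f"prob_threshold must be in (0, 1), got {prob_threshold}")
    if not classifier.trained:
        raise ValueError("classifier has not been trained")
    proba = classifier.predict_proba_map(np.asarray(frame_image, dtype=float))
    mask = proba >= prob_threshold
    return _components_to_detections(mask, frame_index, lineage, pixel_size,
                                     min_area_um2, max_area_um2)


# ---------------------------------------------------------------------------
# Manual corrections

_CORRECTION_OPS = ("delete", "merge", "split", "add")


def apply_corrections(detections: Sequence[Detection], corrections: Iterable[Mapping],
                      image_shape: tuple[int, int] | None = None) -> list[Detection]:
    """Apply manual correction directives, in listed order.

    Directive dictionaries (JSON-friendly)::

        {"op": "delete", "frame": f, "lineage": l, "object_id": i}
        {"op": "merge",  "frame": f, "lineage": l, "object_ids": [i, j, ...]}
        {"op": "split",  "frame": f, "lineage": l, "object_id": i,
         "polyline": [[x, y], ...]}        # pixel-index coordinates
        {"op": "add",    "frame": f, "lineage": l, "polygon": [[x, y], ...],
         "pixel_size": s}                  # polygon in annotation coordinates

    Directives reference objects by their ids at the time of application;
    objects created mid-stream receive fresh provisional ids.  After all
    directives, ids are reassigned deterministically per (frame, lineage)
    in raster-scan order of each object's topmost-leftmost pixel.
    """
    pool: list[Detection] = list(detections)

    for corr in corrections:
        op = corr.get("op")
        if op not in _CORRECTION_OPS:
            raise ValueError(f"unknown correction op {op!r}")
        frame = int(corr["frame"])
        lineage = corr.get("lineage")
        if op == "delete":
            target = _find(pool, frame, lineage, int(corr["object_id"]))
            pool.remove(target)
        elif op == "merge":
            ids = [int(i) for i in corr["object_ids"]]
            if len(ids) < 2:
                raise ValueError("merge needs at least two object ids")
            targets = [_find(pool, frame, lineage, i) for i in ids]
            merged_pixels = np.unique(np.concatenate([t.pixels for t in targets]), axis=0)
            merged = Detection(
                frame_index=frame, object_id=_next_id(pool, frame, targets[0].lineage),
                lineage=targets[0].lineage, pixels=merged_pixels,
                pixel_size=targets[0].pixel_size,
            )  # Detection validates 8-connectivity of the union
            for t in targets:
                pool.remove(t)
            pool.append(merged)
        elif op == "split":
            target = _find(pool, frame, lineage, int(corr["object_id"]))
            parts = _split_pixels(target.pixels, np.asarray(corr["polyline"], dtype=float))
            if len(parts) < 2:
                raise ValueError("split polyline does not partition the object")
            pool.remove(target)
            for part in parts:
                pool.append(Detection(
                    frame_index=frame, object_id=_next_id(pool, frame, target.lineage),
                    lineage=target.lineage, pixels=part, pixel_size=target.pixel_size,
                ))
        else:  # add
            if lineage is None:
                raise ValueError("add directive requires a lineage")
            pixel_size = float(corr.get("pixel_size") or _pool_pixel_size(pool))
            shape = image_shape or _infer_shape(pool, corr["polygon"])
            mask = rasterise_polygon(np.asarray(corr["polygon"], dtype=float), shape)
            rows, cols = np.nonzero(mask)
            if len(rows) == 0:
                raise ValueError("added polygon rasterises to an empty pixel set")
            pool.append(Detection(
                frame_index=frame, object_id=_next_id(pool, frame, lineage),
                lineage=lineage, pixels=np.column_stack([rows, cols]),
                pixel_size=pixel_size,
            ))

    return _reassign_ids(pool)


def _find(pool: Sequence[Detection], frame: int, lineage: str | None, object_id: int) -> Detection:
    hits = [d for d in pool
            if d.frame_index == frame and d.object_id == object_id
            and (lineage is None or d.lineage == lineage)]
    if not hits:
        raise KeyError(f"no detection with frame={frame}, lineage={lineage}, object_id={object_id}")
    if len(hits) > 1:
        raise KeyError(f"ambiguous directive (frame={frame}, object_id={object_id}); specify lineage")
    return hits[0]


def _next_id(pool: Sequence[Detection], frame: int, lineage: str) -> int:
    ids = [d.object_id for d in pool if d.frame_index == frame and d.lineage == lineage]
    return max(ids, default=-1) + 1


def _pool_pixel_size(pool: Sequence[Detection]) -> float:
    if not pool:
        raise ValueError("cannot infer pixel_size for add on an empty detection list; supply it")
    return pool[0].pixel_size


def _infer_shape(pool: Sequence[Detection], polygon) -> tuple[int, int]:
    verts = np.asarray(polygon, dtype=float)
    h = int(np.ceil(verts[:, 1].max())) + 1
    w = int(np.ceil(verts[:, 0].max())) + 1
    for d in pool:
        h = max(h, int(d.pixels[:, 0].max()) + 1)
        w = max(w, int(d.pixels[:, 1].max()) + 1)
    return (h, w)


def _split_pixels(pixels: np.ndarray, polyline: np.ndarray) -> list[np.ndarray]:
    """Remove pixels under the polyline, return the 8-connected remnants."""
    if polyline.ndim != 2 or polyline.shape[1] != 2 or len(polyline) < 2:
        raise ValueError("split polyline needs >= 2 (x, y) points")
    rmin, cmin = pixels.min(axis=0)
    rmax, cmax = pixels.max(axis=0)
    local = np.zeros((rmax - rmin + 1, cmax - cmin + 1), dtype=bool)
    local[pixels[:, 0] - rmin, pixels[:, 1] - cmin] = True
    cut = np.zeros_like(local)
    pts = np.round(polyline).astype(int)
    for (x0, y0), (x1, y1) in zip(pts[:-1], pts[1:]):
        rr, cc = draw_line(y0 - rmin, x0 - cmin, y1 - rmin, x1 - cmin)
        ok = (rr >= 0) & (rr < local.shape[0]) & (cc >= 0) & (cc < local.shape[1])
        cut[rr[ok], cc[ok]] = True
    remaining = local & ~cut
    labels, n = label_components(remaining)
    parts = []
    for lab in range(1, n + 1):
        rows, cols = np.nonzero(labels == lab)
        parts.append(np.column_stack([rows + rmin, cols + cmin]))
    return parts


def _reassign_ids(pool: list[Detection]) -> list[Detection]:
    def first_pixel(d: Detection) -> tuple[int, int]:
        order = np.lexsort((d.pixels[:, 1], d.pixels[:, 0]))
        p = d.pixels[order[0]]
        return (int(p[0]), int(p[1]))

    pool = sorted(pool, key=lambda d: (d.frame_index, d.lineage, first_pixel(d)))
    out = []
    counters: dict[tuple[int, str], int] = {}
    for d in pool:
        key = (d.frame_index, d.lineage)
        new_id = counters.get(key, 0)
        counters[key] = new_id + 1
        out.append(Detection(frame_index=d.frame_index, object_id=new_id,
                             lineage=d.lineage, pixels=d.pixels, pixel_size=d.pixel_size))
    return out
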