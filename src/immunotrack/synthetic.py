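"""Synthetic calibrated time-lapse movies with full ground truth.

The simulator renders bright cytoplasmic discs (neutrophil channel),
small bright nuclei (macrophage channel) and a lesion region (its own
channel), over a noisy background.  Cells move as persistent random
walks: each step direction is a normalised mixture of the previous
direction (weight = persistence), the unit vector toward the nearest
lesion centroid (weight = bias), and isotropic noise (residual weight).
Step length is ``speed * frame_interval``; boundaries are reflective
(billiard fold).  Everything is deterministic given the seed.

Ground truth carries every cell's centroid per frame, its radius, and
the lesion keyframes, from which :func:`true_events` derives reference
interaction events by brute-force pixel geometry (no distance
transforms), independent of the analysis pipeline.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy.spatial.distance import cdist
from shapely.geometry import Polygon

from .config import Calibration, ChannelRole
from .interactions import DEFAULT_THRESHOLDS_UM, InteractionEvent, extract_runs
from .lesion import boundary_mask, rasterise_polygon
from .movie_io import AnnotationFile, MovieStack

#: Channel layout of simulated movies.
SIM_CHANNEL_ROLES = {0: ChannelRole.NEUTROPHIL, 1: ChannelRole.MACROPHAGE, 2: ChannelRole.LESION}


def _default_lesion_polygon(width: int, height: int, radius_px: float = 40.0) -> list[list[float]]:
    cx, cy = 0.30 * width, 0.50 * height
    ang = np.linspace(0, 2 * np.pi, 17)[:-1]
    return [[cx + radius_px * np.cos(a), cy + radius_px * np.sin(a)] for a in ang]


@dataclass
class SimConfig:
    """Parameters of a simulated movie; ``seed`` is mandatory."""

    seed: int
    n_frames: int = 60
    frame_interval_min: float = 2.0
    pixel_size_um: float = 1.0
    height: int = 512
    width: int = 512
    n_neutrophils: int = 5
    n_macrophages: int = 5
    neutrophil_radius_um: tuple[float, float] = (7.0, 9.0)
    macrophage_radius_um: tuple[float, float] = (3.5, 4.5)
    foreground_intensity: float = 200.0
    background_intensity: float = 10.0
    noise_sd: float = 20.0  # default SNR ~ 10
    lesion_intensity: float = 150.0
    speed_um_min: float = 3.0
    persistence: float = 0.5
    bias: float = 0.0
    lesion_polygons: list[list[list[float]]] | None = None
    lesion_deform_amplitude: float = 0.0
    lesion_deform_period: int = 20
    avoid_overlap: bool = True
    #: minimum surface-to-surface gap kept between same-lineage cells (μm)
    min_gap_um: float = 4.0
    #: optional fixed starting centroids, cell id ("n0", "m0", ...) -> (x, y) μm
    initial_positions_um: dict[str, tuple[float, float]] | None = None

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if min(self.n_frames, self.height, self.width) < 1:
            raise ValueError("n_frames and image size must be >= 1")
        if self.n_neutrophils < 0 or self.n_macrophages < 0:
            raise ValueError("cell counts must be >= 0")
        if self.speed_um_min < 0:
            raise ValueError("speed must be >= 0")
        for name in ("persistence", "bias"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.lesion_deform_amplitude < 0:
            raise ValueError("deformation amplitude must be >= 0")
        if self.lesion_polygons is None:
            self.lesion_polygons = [_default_lesion_polygon(self.width, self.height)]

    def calibration(self) -> Calibration:
        return Calibration(pixel_size=self.pixel_size_um,
                           frame_interval=self.frame_interval_min,
                           channel_roles=dict(SIM_CHANNEL_ROLES))

    @classmethod
    def from_dict(cls, d: Mapping) -> "SimConfig":
        known = {f for f in cls.__dataclass_fields__}
        kwargs = {k: v for k, v in dict(d).items() if k in known}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown simulation parameters: {sorted(unknown)}")
        for key in ("neutrophil_radius_um", "macrophage_radius_um"):
            if key in kwargs:
                kwargs[key] = tuple(kwargs[key])
        return cls(**kwargs)


@dataclass
class GroundTruth:
    """Exact cell and lesion geometry behind a simulated movie."""

    config: SimConfig
    #: cell id -> (n_frames, 2) centroid (x, y) in μm
    positions_um: dict[str, np.ndarray]
    radii_um: dict[str, float]
    lineages: dict[str, str]
    #: lesion id -> [(frame, vertices), ...] in annotation pixel coordinates
    lesion_keyframes: dict[str, list[tuple[int, np.ndarray]]]

    def annotations(self) -> list[AnnotationFile]:
        return [AnnotationFile(lesion_id=lid, keyframes=[(f, v.copy()) for f, v in kfs])
                for lid, kfs in self.lesion_keyframes.items()]

    def cells(self, lineage: str | None = None) -> list[str]:
        ids = sorted(self.positions_um)
        if lineage is not None:
            ids = [c for c in ids if self.lineages[c] == lineage]
        return ids

    def to_json(self, path: str | Path) -> None:
        payload = {
            "config": asdict(self.config),
            "cells": {
                cid: {
                    "lineage": self.lineages[cid],
                    "radius_um": self.radii_um[cid],
                    "positions_um": self.positions_um[cid].tolist(),
                }
                for cid in sorted(self.positions_um)
            },
            "lesions": {
                lid: [{"frame": f, "vertices": v.tolist()} for f, v in kfs]
                for lid, kfs in self.lesion_keyframes.items()
            },
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        with open(path) as fh:
            payload = json.load(fh)
        cfg = SimConfig.from_dict(payload["config"])
        cells = payload["cells"]
        return cls(
            config=cfg,
            positions_um={c: np.asarray(v["positions_um"], float) for c, v in cells.items()},
            radii_um={c: float(v["radius_um"]) for c, v in cells.items()},
            lineages={c: str(v["lineage"]) for c, v in cells.items()},
            lesion_keyframes={
                lid: [(int(kf["frame"]), np.asarray(kf["vertices"], float)) for kf in kfs]
                for lid, kfs in payload["lesions"].items()
            },
        )


# ---------------------------------------------------------------------------
# Simulation


def _lesion_polygons_at(config: SimConfig, frame: int) -> list[np.ndarray]:
    polys = []
    for verts in config.lesion_polygons:
        v = np.asarray(verts, dtype=float)
        if config.lesion_deform_amplitude > 0:
            centre = v.mean(axis=0)
            scale = 1.0 + config.lesion_deform_amplitude * np.sin(
                2 * np.pi * frame / max(config.lesion_deform_period, 1))
            v = centre + (v - centre) * scale
            v = np.clip(v, 0.0, [config.width, config.height])
        polys.append(v)
    return polys


def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    return v / n if n > 0 else v


def simulate(config: SimConfig) -> tuple[MovieStack, GroundTruth]:
    """Render a simulated movie and return it with its ground truth."""
    rng = np.random.default_rng(config.seed)
    px = config.pixel_size_um
    extent = np.array([(config.width - 1) * px, (config.height - 1) * px])

    cell_ids, radii, lineages = [], {}, {}
    for i in range(config.n_neutrophils):
        cid = f"n{i}"
        cell_ids.append(cid)
        radii[cid] = float(rng.uniform(*config.neutrophil_radius_um))
        lineages[cid] = "neutrophil"
    for i in range(config.n_macrophages):
        cid = f"m{i}"
        cell_ids.append(cid)
        radii[cid] = float(rng.uniform(*config.macrophage_radius_um))
        lineages[cid] = "macrophage"

    positions = _place_cells(config, rng, cell_ids, radii, lineages, extent)

    # Lesion centroids per frame (bias targets), plus keyframes for annotations.
    deforming = config.lesion_deform_amplitude > 0
    keyframe_frames = range(config.n_frames) if deforming else [0]
    lesion_keyframes: dict[str, list[tuple[int, np.ndarray]]] = {}
    for li in range(len(config.lesion_polygons)):
        lesion_keyframes[f"lesion{li}"] = []
    for f in keyframe_frames:
        for li, verts in enumerate(_lesion_polygons_at(config, f)):
            lesion_keyframes[f"lesion{li}"].append((f, verts))

    def lesion_centroids(frame: int) -> np.ndarray:
        polys = _lesion_polygons_at(config, frame)
        # Annotation corner coords -> μm (centre convention): subtract half px.
        return np.array([(np.asarray(Polygon(v).centroid.coords[0]) - 0.5) * px for v in polys])

    tracks = {cid: np.zeros((config.n_frames, 2)) for cid in cell_ids}
    for cid in cell_ids:
        tracks[cid][0] = positions[cid]
    step_len = config.speed_um_min * config.frame_interval_min
    prev_dir = {cid: _unit(rng.standard_normal(2)) for cid in cell_ids}

    for frame in range(1, config.n_frames):
        centroids = lesion_centroids(frame)
        for cid in cell_ids:
            pos = tracks[cid][frame - 1].copy()
            if step_len == 0:
                tracks[cid][frame] = pos
                continue
            noise_w = max(0.0, 1.0 - config.persistence - config.bias)
            target = centroids[np.argmin(np.linalg.norm(centroids - pos, axis=1))]
            toward = _unit(target - pos)
            mix = (config.persistence * prev_dir[cid]
                   + config.bias * toward
                   + noise_w * _unit(rng.standard_normal(2)))
            direction = _unit(mix)
            if np.linalg.norm(direction) == 0:
                direction = _unit(rng.standard_normal(2))
            new_pos, direction = _reflect(pos + direction * step_len, direction,
                                          radii[cid], extent)
            if config.avoid_overlap:
                new_pos, direction = _resolve_collisions(
                    cid, new_pos, pos, direction, step_len, frame, tracks,
                    radii, lineages, extent, rng, config.min_gap_um)
            prev_dir[cid] = direction
            tracks[cid][frame] = new_pos

    stack = _render(config, rng, tracks, radii, lineages)
    truth = GroundTruth(config=config, positions_um=tracks, radii_um=radii,
                        lineages=lineages, lesion_keyframes=lesion_keyframes)
    return stack, truth


def _place_cells(config, rng, cell_ids, radii, lineages, extent):
    positions = {}
    fixed = config.initial_positions_um or {}
    for cid in cell_ids:
        r = radii[cid]
        lo, hi = r, extent - r
        if np.any(hi <= lo):
            raise ValueError("image too small for the configured cell radii")
        if cid in fixed:
            pos = np.asarray(fixed[cid], dtype=float)
            if np.any(pos < lo) or np.any(pos > hi):
                raise ValueError(f"fixed position for {cid} leaves the image (margin {r} μm)")
            positions[cid] = pos
            continue
        for _ in range(2000):
            cand = rng.uniform(lo, hi)
            ok = all(
                np.linalg.norm(cand - positions[other]) >= r + radii[other] + config.min_gap_um
                for other in positions if lineages[other] == lineages[cid]
            )
            if ok:
                positions[cid] = cand
                break
        else:
            raise ValueError(
                "could not place all cells without initial overlap; "
                "reduce cell counts or enlarge the image"
            )
    return positions


def _reflect(pos: np.ndarray, direction: np.ndarray, radius: float,
             extent: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Billiard reflection keeping the cell's centre within [r, extent - r]."""
    pos = pos.copy()
    direction = direction.copy()
    for ax in range(2):
        lo, hi = radius, extent[ax] - radius
        span = hi - lo
        if span <= 0:
            pos[ax] = np.clip(pos[ax], lo, hi)
            continue
        x = pos[ax]
        flips = 0
        while x < lo or x > hi:
            if x < lo:
                x = 2 * lo - x
            else:
                x = 2 * hi - x
            flips += 1
            if flips > 100:
                x = np.clip(x, lo, hi)
                break
        pos[ax] = x
        if flips % 2:
            direction[ax] = -direction[ax]
    return pos, direction


def _resolve_collisions(cid, new_pos, old_pos, direction, step_len, frame,
                        tracks, radii, lineages, extent, rng, min_gap_um):
    """Redirect (or halt) a step that would overlap a same-lineage neighbour."""
    def collides(p):
        for other, pos_arr in tracks.items():
            if other == cid or lineages[other] != lineages[cid]:
                continue
            other_pos = pos_arr[frame] if np.any(pos_arr[frame]) or frame == 0 else pos_arr[frame - 1]
            if np.linalg.norm(p - other_pos) < radii[cid] + radii[other] + min_gap_um:
                return True
        return False

    if not collides(new_pos):
        return new_pos, direction
    for _ in range(10):
        d = _unit(rng.standard_normal(2))
        cand, d2 = _reflect(old_pos + d * step_len, d, radii[cid], extent)
        if not collides(cand):
            return cand, d2
    return old_pos.copy(), direction


def _render(config: SimConfig, rng: np.random.Generator, tracks, radii, lineages) -> MovieStack:
    px = config.pixel_size_um
    h, w = config.height, config.width
    stack = np.empty((config.n_frames, 3, h, w), dtype=np.uint16)
    channel_of = {"neutrophil": 0, "macrophage": 1}

    lesion_frames = {}
    for frame in range(config.n_frames):
        key = frame if config.lesion_deform_amplitude > 0 else 0
        if key not in lesion_frames:
            m = np.zeros((h, w), dtype=bool)
            for verts in _lesion_polygons_at(config, key):
                m |= rasterise_polygon(verts, (h, w))
            lesion_frames[key] = m
        lesion_mask = lesion_frames[key]

        img = np.full((3, h, w), config.background_intensity, dtype=np.float64)
        img[2][lesion_mask] = config.lesion_intensity
        for cid, pos_arr in tracks.items():
            _render_disc(img[channel_of[lineages[cid]]], pos_arr[frame] / px,
                         radii[cid] / px, config.foreground_intensity,
                         config.background_intensity)
        img += rng.normal(0.0, config.noise_sd, size=img.shape)
        stack[frame] = np.clip(np.round(img), 0, 65535).astype(np.uint16)

    return MovieStack(pixels=stack, calibration=config.calibration())


def _render_disc(channel: np.ndarray, centre_px: np.ndarray, radius_px: float,
                 fg: float, bg: float) -> None:
    """Draw an anti-aliased disc; coverage 0.5 exactly at distance = radius."""
    xi, yi = centre_px
    h, w = channel.shape
    i0 = max(0, int(np.floor(yi - radius_px - 2)))
    i1 = min(h, int(np.ceil(yi + radius_px + 3)))
    j0 = max(0, int(np.floor(xi - radius_px - 2)))
    j1 = min(w, int(np.ceil(xi + radius_px + 3)))
    if i1 <= i0 or j1 <= j0:
        return
    jj, ii = np.meshgrid(np.arange(j0, j1), np.arange(i0, i1))
    d = np.hypot(jj - xi, ii - yi)
    coverage = np.clip(0.5 + (radius_px - d), 0.0, 1.0)
    patch = channel[i0:i1, j0:j1]
    np.maximum(patch, bg + (fg - bg) * coverage, out=patch)


# ---------------------------------------------------------------------------
# Ground-truth oracle for interaction events


def true_cell_mask(centre_um: np.ndarray, radius_um: float, shape: tuple[int, int],
                   pixel_size: float) -> np.ndarray:
    """Exact rasterisation of a disc: pixel centres within radius of the centre."""
    h, w = shape
    xi, yi = np.asarray(centre_um) / pixel_size
    r_px = radius_um / pixel_size
    i0 = max(0, int(np.floor(yi - r_px - 1)))
    i1 = min(h, int(np.ceil(yi + r_px + 2)))
    j0 = max(0, int(np.floor(xi - r_px - 1)))
    j1 = min(w, int(np.ceil(xi + r_px + 2)))
    mask = np.zeros(shape, dtype=bool)
    if i1 <= i0 or j1 <= j0:
        return mask
    jj, ii = np.meshgrid(np.arange(j0, j1), np.arange(i0, i1))
    mask[i0:i1, j0:j1] = np.hypot(jj - xi, ii - yi) <= r_px
    return mask


def true_events(ground_truth: GroundTruth,
                thresholds_um: Mapping[str, float] | None = None) -> list[InteractionEvent]:
    """Reference interaction events from exact geometry (acceptance oracle).

    Distances are computed by brute force: the minimum centre-to-centre
    distance between the rasterised cell's boundary pixels and the
    rasterised lesion's boundary pixels, with overlap whenever a cell
    boundary pixel lies on the lesion mask.  Run extraction and
    classification use the same rules as the analysis pipeline.
    """
    cfg = ground_truth.config
    thresholds = dict(DEFAULT_THRESHOLDS_UM)
    if thresholds_um:
        thresholds.update(thresholds_um)
    shape = (cfg.height, cfg.width)
    px = cfg.pixel_size_um

    # Rasterise lesion geometry once per governing keyframe.
    lesion_geo: dict[str, dict[int, tuple[np.ndarray, np.ndarray]]] = {}
    lesion_frame_key: dict[str, list[int]] = {}
    for lid, kfs in ground_truth.lesion_keyframes.items():
        lesion_geo[lid] = {}
        keys = []
        current = None
        kf_map = dict(kfs)
        for f in range(cfg.n_frames):
            if f in kf_map:
                current = f
            if current is None:
                raise ValueError(f"lesion {lid} has no keyframe at or before frame {f}")
            keys.append(current)
            if current not in lesion_geo[lid]:
                mask = rasterise_polygon(kf_map[current], shape)
                bpix = np.argwhere(boundary_mask(mask, connectivity=2))
                lesion_geo[lid][current] = (mask, bpix)
        lesion_frame_key[lid] = keys

    events: list[InteractionEvent] = []
    track_ids = {cid: k for k, cid in enumerate(ground_truth.cells())}
    for cid in ground_truth.cells():
        lineage = ground_truth.lineages[cid]
        thr = thresholds[lineage]
        for lid in sorted(lesion_geo):
            frames, dists, overlaps = [], [], []
            for f in range(cfg.n_frames):
                mask, lesion_bpix = lesion_geo[lid][lesion_frame_key[lid][f]]
                cmask = true_cell_mask(ground_truth.positions_um[cid][f],
                                       ground_truth.radii_um[cid], shape, px)
                cell_bpix = np.argwhere(boundary_mask(cmask))
                if len(cell_bpix) == 0:
                    continue
                if (mask & cmask).any():
                    d, ov = 0.0, True
                else:
                    d = float(cdist(cell_bpix, lesion_bpix).min()) * px
                    ov = False
                frames.append(f)
                dists.append(d)
                overlaps.append(ov)
            for start, end, any_ov, min_d in extract_runs(
                    np.array(frames), np.array(dists), np.array(overlaps), thr):
                events.append(InteractionEvent(
                    track_id=track_ids[cid], lesion_id=lid, lineage=lineage,
                    start_frame=start, end_frame=end,
                    event_class="contact" if any_ov else "close",
                    min_distance_um=min_d,
                    duration_min=(end - start + 1) * cfg.frame_interval_min,
                ))
    return events
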