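"""Minimal reader/writer for ImageJ ``.roi`` files and ``.zip`` bundles.

Only vertex-list ROI types are supported (polygon, freehand, traced,
polyline, freeline) since lesion outlines are drawn with the freehand /
polygon selection tools.  The binary layout follows ImageJ's
``RoiDecoder``: a 64-byte big-endian header, int16 vertex offsets, and an
optional second header carrying the C/Z/T stack positions.

Frame positions in the file format are 1-based (0 meaning "all frames");
they are exposed here unchanged and converted to 0-based indices by the
annotation layer.
"""

from __future__ import annotations

import struct
import zipfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

_MAGIC = b"Iout"
_VERSION = 228

# ROI type bytes used by ImageJ.
POLYGON = 0
FREEHAND = 7
TRACED = 8
POLYLINE = 5
FREELINE = 4

_VERTEX_TYPES = {POLYGON, FREEHAND, TRACED, POLYLINE, FREELINE}


@dataclass
class ImageJRoi:
    """A decoded vertex-list ROI."""

    name: str
    roi_type: int
    # Absolute (x, y) vertex coordinates in pixel units.
    vertices: list[tuple[float, float]] = field(default_factory=list)
    # 1-based positions as stored by ImageJ; 0 = not set / all.
    t_position: int = 0
    z_position: int = 0
    c_position: int = 0


def encode_roi(roi: ImageJRoi) -> bytes:
    """Serialise a vertex-list ROI to ImageJ's binary format."""
    if roi.roi_type not in _VERTEX_TYPES:
        raise ValueError(f"unsupported ROI type {roi.roi_type}")
    if not roi.vertices:
        raise ValueError("ROI has no vertices")
    xs = [int(round(x)) for x, _ in roi.vertices]
    ys = [int(round(y)) for _, y in roi.vertices]
    left, top = min(xs), min(ys)
    right, bottom = max(xs) + 1, max(ys) + 1
    n = len(xs)

    header = bytearray(64)
    header[0:4] = _MAGIC
    struct.pack_into(">h", header, 4, _VERSION)
    header[6] = roi.roi_type
    struct.pack_into(">hhhh", header, 8, top, left, bottom, right)
    struct.pack_into(">h", header, 16, n)
    hdr2_offset = 64 + 4 * n
    struct.pack_into(">i", header, 60, hdr2_offset)

    coords = bytearray(4 * n)
    for i, x in enumerate(xs):
        struct.pack_into(">h", coords, 2 * i, x - left)
    for i, y in enumerate(ys):
        struct.pack_into(">h", coords, 2 * n + 2 * i, y - top)

    name_bytes = roi.name.encode("utf-16-be") if roi.name else b""
    header2 = bytearray(64)
    struct.pack_into(">iii", header2, 4, roi.c_position, roi.z_position, roi.t_position)
    if name_bytes:
        struct.pack_into(">i", header2, 16, hdr2_offset + 64)  # name offset
        struct.pack_into(">i", header2, 20, len(roi.name))  # name length

    return bytes(header) + bytes(coords) + bytes(header2) + name_bytes


def decode_roi(data: bytes, name: str = "") -> ImageJRoi:
    """Parse the binary content of one ``.roi`` file."""
    if len(data) < 64 or data[0:4] != _MAGIC:
        raise ValueError("not an ImageJ ROI file (bad magic)")
    roi_type = data[6]
    if roi_type not in _VERTEX_TYPES:
        raise ValueError(f"unsupported ROI type {roi_type}; only vertex-list ROIs are readable")
    top, left, _bottom, _right = struct.unpack_from(">hhhh", data, 8)
    n = struct.unpack_from(">h", data, 16)[0]
    if len(data) < 64 + 4 * n:
        raise ValueError("truncated ROI coordinate block")
    xs = struct.unpack_from(f">{n}h", data, 64)
    ys = struct.unpack_from(f">{n}h", data, 64 + 2 * n)
    vertices = [(float(left + x), float(top + y)) for x, y in zip(xs, ys)]

    c_pos = z_pos = t_pos = 0
    hdr2_offset = struct.unpack_from(">i", data, 60)[0]
    if hdr2_offset > 0 and len(data) >= hdr2_offset + 16:
        c_pos, z_pos, t_pos = struct.unpack_from(">iii", data, hdr2_offset + 4)
        name_offset = name_length = 0
        if len(data) >= hdr2_offset + 24:
            name_offset, name_length = struct.unpack_from(">ii", data, hdr2_offset + 16)
        if not name and name_offset > 0 and name_length > 0:
            raw = data[name_offset : name_offset + 2 * name_length]
            name = raw.decode("utf-16-be", errors="replace")
    if t_pos == 0:
        # Older writers store the stack slice in the first-header position field.
        t_pos = struct.unpack_from(">i", data, 56)[0]
    return ImageJRoi(name=name, roi_type=roi_type, vertices=vertices,
                     t_position=t_pos, z_position=z_pos, c_position=c_pos)


def read_roi_file(path: str | Path) -> list[ImageJRoi]:
    """Read a single ``.roi`` file or a ``.zip`` bundle of ROIs."""
    path = Path(path)
    if zipfile.is_zipfile(path):
        rois = []
        with zipfile.ZipFile(path) as zf:
            for info in sorted(zf.infolist(), key=lambda i: i.filename):
                if not info.filename.lower().endswith(".roi"):
                    continue
                stem = Path(info.filename).stem
                rois.append(decode_roi(zf.read(info), name=stem))
        return rois
    return [decode_roi(path.read_bytes(), name=path.stem)]


def write_roi_zip(path: str | Path, rois: Sequence[ImageJRoi]) -> None:
    """Write ROIs to an ImageJ-compatible ``.zip`` bundle."""
    with zipfile.ZipFile(path, "w", zipfile.ZIP_DEFLATED) as zf:
        for i, roi in enumerate(rois):
            name = roi.name or f"roi_{i:04d}"
            zf.writestr(f"{name}.roi", encode_roi(roi))
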