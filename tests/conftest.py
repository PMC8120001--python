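import numpy as np
import pytest

from immunotrack import Calibration, Detection


@pytest.fixture
def calib():
    return Calibration(pixel_size=1.0, frame_interval=2.0,
                       channel_roles={0: "neutrophil", 1: "macrophage", 2: "lesion"})


def point_detection(frame, x, y, object_id=0, lineage="neutrophil", pixel_size=1.0):
    """Single-pixel detection whose centroid in μm is (x, y) * pixel_size."""
    return Detection(frame_index=frame, object_id=object_id, lineage=lineage,
                     pixels=np.array([[y, x]]), pixel_size=pixel_size)


def disc_detection(frame, cx, cy, radius_px, object_id=0, lineage="neutrophil",
                   pixel_size=1.0):
    """Rasterised disc detection centred at pixel index (cx, cy)."""
    r = int(np.ceil(radius_px)) + 1
    jj, ii = np.meshgrid(np.arange(cx - r, cx + r + 1), np.arange(cy - r, cy + r + 1))
    sel = np.hypot(jj - cx, ii - cy) <= radius_px
    pixels = np.column_stack([ii[sel], jj[sel]])
    return Detection(frame_index=frame, object_id=object_id, lineage=lineage,
                     pixels=pixels, pixel_size=pixel_size)


def flood_fill_label(mask):
    """Brute-force 8-connected labelling oracle: list of frozensets of (r, c)."""
    mask = np.asarray(mask, dtype=bool)
    seen = np.zeros_like(mask)
    components = []
    for r0 in range(mask.shape[0]):
        for c0 in range(mask.shape[1]):
            if not mask[r0, c0] or seen[r0, c0]:
                continue
            stack = [(r0, c0)]
            seen[r0, c0] = True
            comp = []
            while stack:
                r, c = stack.pop()
                comp.append((r, c))
                for dr in (-1, 0, 1):
                    for dc in (-1, 0, 1):
                        rr, cc = r + dr, c + dc
                        if (0 <= rr < mask.shape[0] and 0 <= cc < mask.shape[1]
                                and mask[rr, cc] and not seen[rr, cc]):
                            seen[rr, cc] = True
                            stack.append((rr, cc))
            components.append(frozenset(comp))
    return components
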