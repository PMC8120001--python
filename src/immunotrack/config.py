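"""Physical calibration and YAML configuration handling.

All downstream geometry is expressed in micrometres and minutes; the
:class:`Calibration` object is the single source of that scaling.
Calibration always comes from user configuration, never from image file
metadata (confocal export metadata is unreliable); a mismatch with
embedded metadata only logs a warning.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Mapping

import yaml

logger = logging.getLogger(__name__)


class ChannelRole(str, Enum):
    """What a fluorescence channel marks, dictating the measured surface."""

    NEUTROPHIL = "neutrophil"
    MACROPHAGE = "macrophage"
    LESION = "lesion"
    BRIGHTFIELD = "brightfield"
    OTHER = "other"


@dataclass(frozen=True)
class Calibration:
    """Physical scaling of a movie.

    Parameters
    ----------
    pixel_size : float
        Micrometres per pixel, isotropic in x and y.
    frame_interval : float
        Minutes per frame.
    channel_roles : mapping of int to ChannelRole
        Role of each channel index present in the movie.
    """

    pixel_size: float
    frame_interval: float
    channel_roles: Mapping[int, ChannelRole] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.pixel_size > 0:
            raise ValueError(f"pixel_size must be > 0, got {self.pixel_size}")
        if not self.frame_interval > 0:
            raise ValueError(f"frame_interval must be > 0, got {self.frame_interval}")
        roles = {}
        for idx, role in dict(self.channel_roles).items():
            if not isinstance(idx, int) or idx < 0:
                raise ValueError(f"channel index must be a non-negative int, got {idx!r}")
            roles[idx] = ChannelRole(role)
        object.__setattr__(self, "channel_roles", roles)

    def channel_for(self, role: ChannelRole | str) -> int:
        """Return the index of the (unique) channel with the given role."""
        role = ChannelRole(role)
        hits = [i for i, r in self.channel_roles.items() if r is role]
        if len(hits) != 1:
            raise KeyError(f"expected exactly one channel with role {role.value}, found {len(hits)}")
        return hits[0]

    @classmethod
    def from_dict(cls, d: Mapping) -> "Calibration":
        roles = {int(k): ChannelRole(v) for k, v in dict(d.get("channel_roles", {})).items()}
        return cls(
            pixel_size=float(d["pixel_size"]),
            frame_interval=float(d["frame_interval"]),
            channel_roles=roles,
        )


def load_config(path: str | Path) -> dict:
    """Load a YAML configuration file into a plain dictionary."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"configuration root must be a mapping, got {type(cfg).__name__}")
    return cfg


def calibration_from_config(cfg: Mapping) -> Calibration:
    """Build a :class:`Calibration` from a config dict (``calibration:`` block or flat)."""
    block = cfg.get("calibration", cfg)
    return Calibration.from_dict(block)
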