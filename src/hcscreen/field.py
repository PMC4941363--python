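"""Core in-memory container for one microscopy field.

A field is a single imaged position inside a well: a set of named 2-D
grayscale channels (e.g. ``dapi``, ``receptor``, ``edu``) that share one
pixel grid, plus plate/well/field identity. Coordinates are 0-based
``(row, col)``; intensities are non-negative floats in arbitrary units.
"""
from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np

__all__ = ["FieldImage"]


@dataclass
class FieldImage:
    """Named 2-D intensity channels sharing one pixel grid."""

    channels: dict[str, np.ndarray]
    well: str = "r01c01"
    field: int = 1
    plate: str = "plate01"
    pixel_size_um: float | None = None
    meta: dict = dc_field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.channels:
            raise ValueError("FieldImage needs at least one channel")
        shapes = {ch: np.asarray(a).shape for ch, a in self.channels.items()}
        first = next(iter(shapes.values()))
        if len(first) != 2:
            raise ValueError(f"channels must be 2-D, got shape {first}")
        for ch, shp in shapes.items():
            if shp != first:
                raise ValueError(
                    f"channel {ch!r} has shape {shp}, expected {first}"
                )
        for ch, arr in self.channels.items():
            arr = np.asarray(arr)
            if np.any(arr < 0):
                raise ValueError(f"channel {ch!r} contains negative intensities")
            self.channels[ch] = arr

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.channels.values())).shape

    def __getitem__(self, channel: str) -> np.ndarray:
        return self.channels[channel]

    def __contains__(self, channel: str) -> bool:
        return channel in self.channels
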