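"""Core value types shared across the pipeline.

Coordinate convention used everywhere in this package: 0-based pixel
coordinates with the origin at the top-left corner and y increasing
downward.  Box coordinates are *centers*, not corners; file-format
converters in :mod:`emloop.formats_io` handle corner-based dialects.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

__all__ = ["Box", "FilamentTrace", "Micrograph", "MovieStack"]


@dataclass(frozen=True)
class Box:
    """A picked particle: a square box centered on ``(center_x, center_y)``.

    ``confidence`` is the picker's score in [0, 1]; the picking threshold
    is applied against this value.  Filament segments carry the id of the
    trace they belong to and their ordinal position along it.
    """

    center_x: float
    center_y: float
    box_size: int
    confidence: float = 1.0
    micrograph_id: str = ""
    filament_id: Optional[int] = None
    segment_index: Optional[int] = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.confidence <= 1.0):
            raise ValueError(f"confidence must lie in [0, 1], got {self.confidence}")
        if self.box_size <= 0:
            raise ValueError(f"box_size must be positive, got {self.box_size}")
        if (self.filament_id is None) != (self.segment_index is None):
            raise ValueError("segment_index must be present iff filament_id is present")

    @property
    def center(self) -> tuple[float, float]:
        return (self.center_x, self.center_y)

    def with_confidence(self, confidence: float) -> "Box":
        return replace(self, confidence=confidence)

    def with_center(self, x: float, y: float) -> "Box":
        return replace(self, center_x=x, center_y=y)


@dataclass(frozen=True)
class FilamentTrace:
    """An ordered chain of segment boxes along one traced filament.

    ``confidence`` is the mean segment confidence; the picking threshold
    for filaments is applied per trace, not per segment.
    """

    filament_id: int
    segments: tuple[Box, ...]
    centerline: tuple[tuple[float, float], ...]

    @property
    def confidence(self) -> float:
        if not self.segments:
            return 0.0
        return float(np.mean([s.confidence for s in self.segments]))

    @property
    def n_segments(self) -> int:
        return len(self.segments)


@dataclass
class Micrograph:
    """A single drift-corrected 2D image with its pixel size."""

    image: np.ndarray
    pixel_size: float = 1.0
    micrograph_id: str = ""

    def __post_init__(self) -> None:
        self.image = np.asarray(self.image, dtype=np.float32)
        if self.image.ndim != 2:
            raise ValueError("micrograph image must be 2D")


@dataclass
class MovieStack:
    """A dose-fractionated movie: frames stacked along axis 0."""

    frames: np.ndarray
    pixel_size: float = 1.0
    micrograph_id: str = ""

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=np.float32)
        if self.frames.ndim != 3:
            raise ValueError("movie frames must be a 3D (n, h, w) array")

    @property
    def n_frames(self) -> int:
        return int(self.frames.shape[0])

    def sum_image(self) -> Micrograph:
        """Plain frame sum without drift compensation."""
        return Micrograph(
            self.frames.sum(axis=0), pixel_size=self.pixel_size,
            micrograph_id=self.micrograph_id,
        )


def boxes_to_array(boxes: Sequence[Box]) -> np.ndarray:
    """(n, 2) array of box centers as (x, y) rows."""
    if not boxes:
        return np.empty((0, 2), dtype=float)
    return np.array([[b.center_x, b.center_y] for b in boxes], dtype=float)
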