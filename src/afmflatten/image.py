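"""Core containers shared by every stage of the flattening pipeline.

The universal currency is the :class:`HeightImage`: a rectangular field of
heights in nanometers whose rows are scan lines acquired along the slow axis
(row 0 = first acquired line) and whose columns run along the fast axis.
All operations in this package are pure -- they return new images and never
modify their input in place.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np


class AFMFlattenError(Exception):
    """Base class for errors raised by afmflatten."""


class DegenerateMaskError(AFMFlattenError):
    """Raised when a background mask contains no usable pixels."""


class IllConditionedFitError(AFMFlattenError):
    """Raised when a polynomial surface fit is rank deficient.

    Typically the mask geometry does not constrain all basis monomials,
    e.g. a mask confined to a single scan line.
    """


class BackgroundIdentificationError(AFMFlattenError):
    """Raised when no background level can be isolated in an image."""

    def __init__(self, message: str, step_log=None):
        super().__init__(message)
        self.step_log = list(step_log) if step_log is not None else []


class ImageParseError(AFMFlattenError):
    """Raised when an input file cannot be parsed as a height map."""


@dataclass
class HeightImage:
    """A single-channel 2-D height map.

    Parameters
    ----------
    heights:
        2-D array of heights in nanometers; row index = scan line along the
        slow axis, column index = pixel along the fast axis.
    pixel_size:
        Physical extent of one pixel in nm/px.
    channel:
        Name of the data channel (the algorithm applies to any channel).
    frame_index:
        Position within an image sequence, if any.
    metadata:
        Free-form dictionary; the synthetic generator stores its ground-truth
        distortion record here.
    """

    heights: np.ndarray
    pixel_size: float = 1.0
    channel: str = "height"
    frame_index: Optional[int] = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        h = np.asarray(self.heights, dtype=float)
        if h.ndim != 2:
            raise ValueError(f"heights must be 2-D, got shape {h.shape}")
        if h.shape[0] < 1 or h.shape[1] < 1:
            raise ValueError("heights must be non-empty")
        self.heights = h

    @property
    def rows(self) -> int:
        return self.heights.shape[0]

    @property
    def cols(self) -> int:
        return self.heights.shape[1]

    @property
    def shape(self) -> tuple:
        return self.heights.shape

    def std(self) -> float:
        """Standard deviation of all heights (the flatness metric)."""
        return float(np.std(self.heights))

    def with_heights(self, heights: np.ndarray) -> "HeightImage":
        """Return a copy of this image carrying a new height field."""
        return HeightImage(
            np.asarray(heights, dtype=float),
            pixel_size=self.pixel_size,
            channel=self.channel,
            frame_index=self.frame_index,
            metadata=dict(self.metadata),
        )

    def copy(self) -> "HeightImage":
        return self.with_heights(self.heights.copy())


@dataclass
class LineOffsets:
    """One additive constant per scan line: the cumulative 1-D correction.

    ``values[n]`` is the total constant that has been subtracted from scan
    line ``n``.  Adding the offsets back reproduces the input, so they are
    invertible bookkeeping rather than a destructive edit.
    """

    values: np.ndarray
    provenance: list = field(default_factory=list)
    fallback_lines: tuple = ()

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 1:
            raise ValueError("offsets must be 1-D (one value per scan line)")
        self.values = v
        self.provenance = list(self.provenance)

    @classmethod
    def zeros(cls, n_lines: int, provenance=()) -> "LineOffsets":
        return cls(np.zeros(n_lines), list(provenance))

    def __len__(self) -> int:
        return self.values.size

    def __add__(self, other: "LineOffsets") -> "LineOffsets":
        if len(other) != len(self):
            raise ValueError("offset lengths differ")
        return LineOffsets(
            self.values + other.values,
            self.provenance + other.provenance,
            tuple(sorted(set(self.fallback_lines) | set(other.fallback_lines))),
        )

    def copy(self) -> "LineOffsets":
        return LineOffsets(self.values.copy(), list(self.provenance), self.fallback_lines)
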