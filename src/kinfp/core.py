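"""Shared containers and errors for single-molecule kinetic fingerprinting.

Conventions used throughout the package:

* pixel coordinates are 0-based ``(row, col)``;
* times are in seconds, intensities in arbitrary camera units;
* the three chromatic channels are ``C1`` (Cy3 only), ``C2`` (Cy5 only) and
  ``C12`` (mixed Cy3/Cy5 binding at the same location).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

__all__ = [
    "ColorChannel",
    "ROI",
    "Trace",
    "KinfpError",
    "InvalidParameterError",
    "InsufficientFramesError",
    "InsufficientDataError",
    "DegenerateTraceError",
    "DegenerateClusterError",
    "CapacityError",
    "InfeasibleThresholdError",
]


class KinfpError(Exception):
    """Base class for all package-specific errors."""


class InvalidParameterError(KinfpError, ValueError):
    """A kinetic, emission or configuration parameter is out of range."""


class InsufficientFramesError(KinfpError, ValueError):
    """An operation needs more movie frames than were provided."""


class InsufficientDataError(KinfpError, ValueError):
    """Too few data points to fit or summarize."""


class DegenerateTraceError(KinfpError, ValueError):
    """A trace carries no usable intensity variation."""


class DegenerateClusterError(KinfpError, ValueError):
    """A cluster collapsed to zero variance on at least one axis."""


class CapacityError(KinfpError, ValueError):
    """A field of view cannot hold the requested molecules at the required separation."""


class InfeasibleThresholdError(KinfpError, ValueError):
    """No threshold combination satisfies the blank-count constraint."""

    def __init__(self, message: str, best_blank_count: float):
        super().__init__(message)
        self.best_blank_count = best_blank_count


class ColorChannel(str, enum.Enum):
    """Chromatic detection channel of a molecule."""

    C1 = "C1"
    C2 = "C2"
    C12 = "C12"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


@dataclass(frozen=True)
class ROI:
    """A 3x3-pixel region of interest centered on a candidate binding site.

    ``value`` is the fluctuation-map value at the center, used for
    deterministic ordering downstream; it is optional metadata.
    """

    center: tuple[int, int]
    channel: str = "C1_raw"
    fov_id: str = "fov0"
    value: float = 0.0
    half_width: int = 1

    @property
    def window(self) -> tuple[slice, slice]:
        r, c = self.center
        h = self.half_width
        return slice(r - h, r + h + 1), slice(c - h, c + h + 1)


@dataclass
class Trace:
    """One ROI's background-subtracted intensity per frame in one channel."""

    intensities: np.ndarray
    frame_time: float
    roi: Optional[ROI] = None
    molecule_id: str = ""
    channel: str = "C1"
    fov_id: str = "fov0"

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.intensities.ndim != 1:
            raise InvalidParameterError("trace intensities must be 1-D")
        if self.frame_time <= 0:
            raise InvalidParameterError("frame_time must be positive")

    def __len__(self) -> int:
        return self.intensities.size

    @property
    def duration(self) -> float:
        return len(self) * self.frame_time
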