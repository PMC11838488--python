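"""From raw TIRF movie stacks to candidate ROIs and intensity traces.

Candidate binding sites are found on an intensity *fluctuation map* -- the
average absolute frame-to-frame intensity change at each pixel -- which
lights up wherever probes repeatedly bind and dissociate while suppressing
static background.  ROIs are 3x3-pixel windows centered on local maxima of
that map; per-frame integrated, background-subtracted window intensities
form the traces handed to idealization.

Pixel coordinates are 0-based ``(row, col)``; see FORMATS.md for the table
schemas written by the I/O helpers.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import ndimage

from .core import (
    InsufficientFramesError,
    InvalidParameterError,
    ROI,
    Trace,
)

__all__ = [
    "MovieStack",
    "FluctuationMap",
    "BackgroundSpec",
    "fluctuation_map",
    "detect_rois",
    "extract_trace",
    "read_tiff_stack",
    "write_tiff_stack",
    "write_traces_tsv",
    "read_traces_tsv",
    "write_rois_tsv",
]


@dataclass
class MovieStack:
    """One channel's movie for one field of view (time x height x width)."""

    frames: np.ndarray
    frame_time: float
    channel: str = "C1_raw"
    fov_id: str = "fov0"

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3:
            raise InvalidParameterError("movie frames must be 3-D (time, height, width)")
        if self.frame_time <= 0:
            raise InvalidParameterError("frame_time must be positive")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]


@dataclass
class FluctuationMap:
    """Average absolute frame-to-frame intensity change per pixel."""

    values: np.ndarray
    channel: str = "C1_raw"
    fov_id: str = "fov0"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise InvalidParameterError("fluctuation map must be 2-D")


@dataclass(frozen=True)
class BackgroundSpec:
    """How the local background of a ROI is estimated.

    ``method="annulus"`` uses the per-frame median of the 7x7 window minus
    the inner 3x3 (robust to neighboring puncta); ``method="global"`` uses
    the per-frame median of the whole frame.
    """

    method: str = "annulus"
    outer_half_width: int = 3

    def __post_init__(self) -> None:
        if self.method not in ("annulus", "global"):
            raise InvalidParameterError("background method must be 'annulus' or 'global'")


def fluctuation_map(movie: MovieStack) -> FluctuationMap:
    """Mean over t of |I(t+1, p) - I(t, p)| at every pixel p."""
    if movie.n_frames < 2:
        raise InsufficientFramesError("fluctuation map needs at least 2 frames")
    values = np.mean(np.abs(np.diff(movie.frames, axis=0)), axis=0)
    return FluctuationMap(values, movie.channel, movie.fov_id)


def detect_rois(
    fmap: FluctuationMap,
    min_separation: int = 3,
    threshold: Optional[float] = None,
    threshold_quantile: float = 0.995,
) -> list[ROI]:
    """Local maxima of the fluctuation map, greedily separated.

    Maxima above the threshold (absolute if given, else the
    ``threshold_quantile`` of the map) are sorted by descending value with
    lexicographic (row, col) tie-break and retained greedily so that kept
    centers are at least ``min_separation`` apart (Chebyshev distance) and
    the 3x3 window lies fully inside the frame.
    """
    v = fmap.values
    if threshold is None:
        threshold = float(np.quantile(v, threshold_quantile))
    # plateau-tolerant local maxima via a 3x3 maximum filter
    local_max = v >= ndimage.maximum_filter(v, size=3, mode="constant", cval=-np.inf)
    local_max &= v > threshold
    local_max[0, :] = local_max[-1, :] = False
    local_max[:, 0] = local_max[:, -1] = False
    rows, cols = np.nonzero(local_max)
    if rows.size == 0:
        return []
    order = np.lexsort((cols, rows, -v[rows, cols]))
    kept: list[tuple[int, int]] = []
    rois: list[ROI] = []
    for i in order:
        r, c = int(rows[i]), int(cols[i])
        if all(max(abs(r - kr), abs(c - kc)) >= min_separation for kr, kc in kept):
            kept.append((r, c))
            rois.append(ROI((r, c), fmap.channel, fmap.fov_id, float(v[r, c])))
    return rois


def _background(movie: MovieStack, roi: ROI, spec: BackgroundSpec) -> np.ndarray:
    """Per-frame background estimate (per pixel) for one ROI."""
    if spec.method == "global":
        return np.median(movie.frames.reshape(movie.n_frames, -1), axis=1)
    r, c = roi.center
    h_out = spec.outer_half_width
    h, w = movie.shape
    r0, r1 = max(0, r - h_out), min(h, r + h_out + 1)
    c0, c1 = max(0, c - h_out), min(w, c + h_out + 1)
    outer = movie.frames[:, r0:r1, c0:c1]
    mask = np.ones(outer.shape[1:], dtype=bool)
    ir0 = (r - roi.half_width) - r0
    ic0 = (c - roi.half_width) - c0
    mask[ir0 : ir0 + 2 * roi.half_width + 1, ic0 : ic0 + 2 * roi.half_width + 1] = False
    return np.median(outer[:, mask], axis=1)


def extract_trace(
    movie: MovieStack,
    roi: ROI,
    background: Optional[BackgroundSpec] = None,
    molecule_id: str = "",
) -> Trace:
    """Integrated, background-subtracted 3x3 window intensity per frame."""
    background = background or BackgroundSpec()
    r, c = roi.center
    h = roi.half_width
    height, width = movie.shape
    if not (h <= r < height - h and h <= c < width - h):
        raise InvalidParameterError(f"ROI at {roi.center} touches the frame border")
    window = movie.frames[:, r - h : r + h + 1, c - h : c + h + 1]
    n_px = (2 * h + 1) ** 2
    raw = window.reshape(movie.n_frames, -1).sum(axis=1)
    bg = _background(movie, roi, background)
    intensities = raw - n_px * bg
    return Trace(
        intensities,
        movie.frame_time,
        roi=roi,
        molecule_id=molecule_id or f"{movie.fov_id}:{r}_{c}",
        channel="C1" if movie.channel.startswith("C1") else "C2",
        fov_id=movie.fov_id,
    )


# ---------------------------------------------------------------------------
# File I/O (TIFF stacks in; TSV tables out) -- see FORMATS.md
# ---------------------------------------------------------------------------


def read_tiff_stack(
    path: Union[str, Path], frame_time: float, channel: str = "C1_raw", fov_id: str = "fov0"
) -> MovieStack:
    import tifffile

    frames = np.asarray(tifffile.imread(str(path)), dtype=float)
    if frames.ndim == 2:
        frames = frames[None, ...]
    return MovieStack(frames, frame_time, channel, fov_id)


def write_tiff_stack(path: Union[str, Path], movie: MovieStack) -> None:
    import tifffile

    tifffile.imwrite(str(path), movie.frames.astype(np.float32))


def write_rois_tsv(path: Union[str, Path], rois: Sequence[ROI]) -> None:
    df = pd.DataFrame(
        {
            "fov_id": [r.fov_id for r in rois],
            "channel": [r.channel for r in rois],
            "row": [r.center[0] for r in rois],
            "col": [r.center[1] for r in rois],
            "value": [r.value for r in rois],
        }
    )
    df.to_csv(path, sep="\t", index=False)


def write_traces_tsv(path: Union[str, Path], traces: Sequence[Trace]) -> None:
    """Long-format trace table: one row per (molecule, frame)."""
    parts = []
    for t in traces:
        n = len(t)
        parts.append(
            pd.DataFrame(
                {
                    "fov_id": np.repeat(t.fov_id, n),
                    "molecule_id": np.repeat(t.molecule_id, n),
                    "channel": np.repeat(t.channel, n),
                    "frame": np.arange(n),
                    "intensity": t.intensities,
                }
            )
        )
    df = (
        pd.concat(parts, ignore_index=True)
        if parts
        else pd.DataFrame(
            columns=["fov_id", "molecule_id", "channel", "frame", "intensity"]
        )
    )
    df.to_csv(path, sep="\t", index=False)


def read_traces_tsv(path: Union[str, Path], frame_time: float) -> list[Trace]:
    df = pd.read_csv(path, sep="\t")
    traces = []
    for (fov, mol, channel), grp in df.groupby(
        ["fov_id", "molecule_id", "channel"], sort=True
    ):
        grp = grp.sort_values("frame")
        traces.append(
            Trace(
                grp["intensity"].to_numpy(dtype=float),
                frame_time,
                molecule_id=str(mol),
                channel=str(channel),
                fov_id=str(fov),
            )
        )
    return traces
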