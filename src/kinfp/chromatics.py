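"""Chromatic channel assignment (C1 / C2 / C12) via two-color colocalization.

A molecule detected only in the Cy3 detector channel is C1, only in Cy5 is
C2, and a molecule showing kinetically accepted binding at the *same
location* in both channels is C12 (mixed-dye probes).  Channels are assumed
registered; colocalization is greedy nearest-neighbor matching of ROI
centers within a pixel tolerance.  C12 molecules carry one trace per color;
their merged bound path (frame-wise union -- the molecule is bound whenever
either probe color is bound) feeds fingerprinting as a single molecule.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .core import ColorChannel, InvalidParameterError, ROI, Trace
from .idealize import IdealizedTrace, _dwells_from_states

__all__ = [
    "MoleculeRecord",
    "colocalize",
    "assign_color_channel",
    "merge_c12",
]


@dataclass
class MoleculeRecord:
    """One detected molecule with its channel and per-color traces."""

    molecule_id: str
    fov_id: str
    position: tuple[int, int]
    channel: ColorChannel
    trace_c1: Optional[Trace] = None
    trace_c2: Optional[Trace] = None

    def __post_init__(self) -> None:
        self.channel = ColorChannel(self.channel)
        if self.channel == ColorChannel.C1 and (
            self.trace_c1 is None or self.trace_c2 is not None
        ):
            raise InvalidParameterError("C1 molecules carry exactly the Cy3 trace")
        if self.channel == ColorChannel.C2 and (
            self.trace_c2 is None or self.trace_c1 is not None
        ):
            raise InvalidParameterError("C2 molecules carry exactly the Cy5 trace")
        if self.channel == ColorChannel.C12 and (
            self.trace_c1 is None or self.trace_c2 is None
        ):
            raise InvalidParameterError("C12 molecules need both color traces")


def _roi_order(rois: Sequence[ROI]) -> list[int]:
    """Descending fluctuation value, then lexicographic (row, col)."""
    return sorted(
        range(len(rois)),
        key=lambda i: (-rois[i].value, rois[i].center[0], rois[i].center[1]),
    )


def colocalize(
    rois_c1: Sequence[ROI],
    rois_c2: Sequence[ROI],
    tolerance: float = 2.0,
) -> tuple[list[tuple[ROI, ROI, float]], list[ROI], list[ROI]]:
    """Greedy nearest-neighbor matching of ROI centers within ``tolerance`` px.

    Each ROI is used at most once.  C1 ROIs are processed in deterministic
    order (descending map value, then lexicographic center); candidate ties
    at equal distance go to the lexicographically smaller C2 center.
    Returns ``(matches, unmatched_c1, unmatched_c2)``.
    """
    if tolerance < 0:
        raise InvalidParameterError("tolerance must be non-negative")
    used_c2 = [False] * len(rois_c2)
    matches: list[tuple[ROI, ROI, float]] = []
    unmatched_c1: list[ROI] = []
    for i in _roi_order(rois_c1):
        r1 = rois_c1[i]
        best: Optional[tuple[float, tuple[int, int], int]] = None
        for j, r2 in enumerate(rois_c2):
            if used_c2[j]:
                continue
            d = math.hypot(
                r1.center[0] - r2.center[0], r1.center[1] - r2.center[1]
            )
            if d <= tolerance:
                key = (d, r2.center, j)
                if best is None or key < best:
                    best = key
        if best is None:
            unmatched_c1.append(r1)
        else:
            used_c2[best[2]] = True
            matches.append((r1, rois_c2[best[2]], best[0]))
    unmatched_c2 = [r for j, r in enumerate(rois_c2) if not used_c2[j]]
    return matches, unmatched_c1, unmatched_c2


def assign_color_channel(
    accepted_c1: bool, accepted_c2: bool, colocalized: bool = True
) -> Optional[ColorChannel]:
    """Channel from per-color kinetic acceptance at one location.

    Cy3 only -> C1; Cy5 only -> C2; both (and spatially colocalized) -> C12;
    neither -> ``None`` (rejected).  A location accepted in both colors but
    *not* colocalized is two separate molecules and must be split by the
    caller before this point.
    """
    if accepted_c1 and accepted_c2:
        return ColorChannel.C12 if colocalized else None
    if accepted_c1:
        return ColorChannel.C1
    if accepted_c2:
        return ColorChannel.C2
    return None


def merge_c12(ideal_c1: IdealizedTrace, ideal_c2: IdealizedTrace) -> IdealizedTrace:
    """Merge the two color paths of a C12 molecule into one bound path.

    The merged frame is bound when either color is bound; dwell lists are
    recomputed on the merged path.  Emission statistics are averaged across
    the two channels (they describe different fluorophores and only feed
    the S/N fingerprint parameter).
    """
    if ideal_c1.states.size != ideal_c2.states.size:
        raise InvalidParameterError("C12 traces have different lengths")
    if ideal_c1.frame_time != ideal_c2.frame_time:
        raise InvalidParameterError("C12 traces have different frame times")
    states = ideal_c1.states | ideal_c2.states
    d_on, d_off, cf, cl = _dwells_from_states(states, ideal_c1.frame_time)
    return IdealizedTrace(
        states=states,
        mean_bound=0.5 * (ideal_c1.mean_bound + ideal_c2.mean_bound),
        mean_unbound=0.5 * (ideal_c1.mean_unbound + ideal_c2.mean_unbound),
        noise_sd=0.5 * (ideal_c1.noise_sd + ideal_c2.noise_sd),
        dwells_on=d_on,
        dwells_off=d_off,
        censored_first=cf,
        censored_last=cl,
        frame_time=ideal_c1.frame_time,
        converged=ideal_c1.converged and ideal_c2.converged,
        molecule_id=ideal_c1.molecule_id,
        channel=str(ColorChannel.C12),
        fov_id=ideal_c1.fov_id,
    )
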