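"""Per-molecule kinetic fingerprints and kinetic filtering.

The kinetic fingerprint of a molecule summarizes its idealized trace by

* ``n_events`` -- N_b+d, the number of binding plus dissociation
  transitions in the state path (each transition counts once);
* ``tau_on_med`` / ``tau_off_med`` -- median complete dwell in the
  probe-bound / probe-unbound state (s);
* ``tau_off_max`` -- maximum complete unbound dwell (s);
* ``snr`` -- (mean_bound - mean_unbound) / noise_sd.

Kinetic filtering accepts a molecule when every bounded parameter lies
within target-specific thresholds; it is what separates repetitive,
target-specific probe binding from sparse nonspecific sticking.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .core import InfeasibleThresholdError, InvalidParameterError
from .idealize import IdealizedTrace

__all__ = [
    "KineticFingerprint",
    "FilterThresholds",
    "FINGERPRINT_PARAMS",
    "compute_fingerprint",
    "fingerprint_table",
    "fingerprints_to_frame",
    "apply_filters",
    "accepted_mask",
    "optimize_thresholds",
    "default_grid",
]

FINGERPRINT_PARAMS = ("n_events", "tau_on_med", "tau_off_med", "tau_off_max", "snr")


@dataclass(frozen=True)
class KineticFingerprint:
    """Per-molecule kinetic summary; NaN marks an undefined dwell statistic."""

    molecule_id: str
    channel: str
    n_events: int
    tau_on_med: float
    tau_off_med: float
    tau_off_max: float
    snr: float
    fov_id: str = "fov0"


def compute_fingerprint(
    ideal: Optional[IdealizedTrace],
    frame_time: Optional[float] = None,
    literal_inverse: bool = False,
) -> KineticFingerprint:
    """Summarize an idealized trace into its kinetic fingerprint.

    ``literal_inverse=True`` reports noise/signal instead of signal/noise
    for ``snr``; the signal/noise orientation is the default because filter
    semantics (a *minimum* S/N) require signal in the numerator.

    A ``None`` idealization (degenerate trace) yields an all-undefined
    fingerprint with zero events.
    """
    if ideal is None:
        return KineticFingerprint("", "C1", 0, math.nan, math.nan, math.nan, math.nan)
    ft = frame_time if frame_time is not None else ideal.frame_time
    scale = ft / ideal.frame_time  # rescale stored dwells if caller overrides
    d_on = ideal.dwells_on * scale
    d_off = ideal.dwells_off * scale
    tau_on_med = float(np.median(d_on)) if d_on.size else math.nan
    tau_off_med = float(np.median(d_off)) if d_off.size else math.nan
    tau_off_max = float(np.max(d_off)) if d_off.size else math.nan
    signal = ideal.mean_bound - ideal.mean_unbound
    if ideal.noise_sd > 0 and signal > 0:
        snr = ideal.noise_sd / signal if literal_inverse else signal / ideal.noise_sd
    else:
        snr = math.nan
    return KineticFingerprint(
        ideal.molecule_id,
        ideal.channel,
        ideal.n_transitions,
        tau_on_med,
        tau_off_med,
        tau_off_max,
        snr,
        ideal.fov_id,
    )


def fingerprint_table(
    ideals: Sequence[Optional[IdealizedTrace]],
    frame_time: Optional[float] = None,
    molecule_ids: Optional[Sequence[str]] = None,
    literal_inverse: bool = False,
) -> dict:
    """Column dict of fingerprints for a batch of idealized traces."""
    fps = [compute_fingerprint(i, frame_time, literal_inverse) for i in ideals]
    ids = (
        list(molecule_ids)
        if molecule_ids is not None
        else [fp.molecule_id for fp in fps]
    )
    return {
        "molecule_id": ids,
        "fov_id": [fp.fov_id for fp in fps],
        "n_events": np.array([fp.n_events for fp in fps], dtype=int),
        "tau_on_med": np.array([fp.tau_on_med for fp in fps]),
        "tau_off_med": np.array([fp.tau_off_med for fp in fps]),
        "tau_off_max": np.array([fp.tau_off_max for fp in fps]),
        "snr": np.array([fp.snr for fp in fps]),
    }


def fingerprints_to_frame(fps: Iterable[KineticFingerprint]) -> pd.DataFrame:
    fps = list(fps)
    return pd.DataFrame(
        {
            "molecule_id": [f.molecule_id for f in fps],
            "fov_id": [f.fov_id for f in fps],
            "channel": [f.channel for f in fps],
            "n_events": [f.n_events for f in fps],
            "tau_on_med": [f.tau_on_med for f in fps],
            "tau_off_med": [f.tau_off_med for f in fps],
            "tau_off_max": [f.tau_off_max for f in fps],
            "snr": [f.snr for f in fps],
        }
    )


@dataclass(frozen=True)
class FilterThresholds:
    """Optional (min, max) bound per fingerprint parameter.

    An absent parameter is unbounded; a fingerprint whose parameter is
    undefined (NaN) fails any bound placed on that parameter.
    """

    bounds: Mapping[str, tuple[Optional[float], Optional[float]]] = field(
        default_factory=dict
    )

    def __post_init__(self) -> None:
        for param, (lo, hi) in self.bounds.items():
            if param not in FINGERPRINT_PARAMS:
                raise InvalidParameterError(f"unknown fingerprint parameter {param!r}")
            if lo is not None and hi is not None and lo > hi:
                raise InvalidParameterError(f"min > max for {param!r}")

    def active_bound_count(self) -> int:
        return sum(
            (lo is not None) + (hi is not None) for lo, hi in self.bounds.values()
        )

    def to_dict(self) -> dict:
        return {p: list(b) for p, b in self.bounds.items()}

    @classmethod
    def from_dict(cls, d: Mapping) -> "FilterThresholds":
        return cls({p: (b[0], b[1]) for p, b in d.items()})


FingerprintsLike = Union[pd.DataFrame, Sequence[KineticFingerprint]]


def _as_frame(fps: FingerprintsLike) -> tuple[pd.DataFrame, bool]:
    if isinstance(fps, pd.DataFrame):
        return fps, True
    return fingerprints_to_frame(fps), False


def accepted_mask(df: pd.DataFrame, th: FilterThresholds) -> np.ndarray:
    """Boolean acceptance per row under the thresholds."""
    mask = np.ones(len(df), dtype=bool)
    for param, (lo, hi) in th.bounds.items():
        values = df[param].to_numpy(dtype=float)
        if lo is None and hi is None:
            continue
        defined = ~np.isnan(values)
        ok = defined.copy()
        if lo is not None:
            ok &= values >= lo
        if hi is not None:
            ok &= values <= hi
        mask &= ok
    return mask


def apply_filters(fps: FingerprintsLike, th: FilterThresholds):
    """Apply kinetic filtering; returns (accepted, counts_per_fov).

    ``accepted`` has the same type as the input (DataFrame in, DataFrame
    out); ``counts_per_fov`` maps each FOV present in the input to its
    accepted count (zero included).
    """
    df, was_frame = _as_frame(fps)
    mask = accepted_mask(df, th)
    counts = {
        fov: int(mask[(df["fov_id"] == fov).to_numpy()].sum())
        for fov in pd.unique(df["fov_id"])
    }
    if was_frame:
        return df[mask].reset_index(drop=True), counts
    return [fp for fp, m in zip(list(fps), mask) if m], counts


def default_grid() -> dict:
    """Candidate bounds searched by the threshold optimizer.

    ``None`` means "no bound on this side".  Dwell-time candidates span
    0.1-30 s in roughly logarithmic steps; the event-count minimum spans
    2-20 transitions; a minimum S/N rejects low-contrast traces whose
    idealization is dominated by noise.
    """
    dwell = [0.1, 0.2, 0.5, 1.0, 2.0, 5.0, 10.0, 30.0]
    return {
        "n_events": {"min": [None] + list(range(2, 21)), "max": [None]},
        "tau_on_med": {"min": [None] + dwell[:-1], "max": [None] + dwell[2:]},
        "tau_off_med": {"min": [None] + dwell[:-1], "max": [None] + dwell[2:]},
        "snr": {"min": [None, 2.0, 3.0], "max": [None]},
    }


def _side_mask(values: np.ndarray, bound: Optional[float], side: str) -> np.ndarray:
    if bound is None:
        return np.ones(values.size, dtype=bool)
    defined = ~np.isnan(values)
    if side == "min":
        return defined & (values >= bound)
    return defined & (values <= bound)


def optimize_thresholds(
    positives: FingerprintsLike,
    blanks: FingerprintsLike,
    grid: Optional[Mapping] = None,
    max_blank_count: float = 0.0,
    n_blank_fovs: Optional[int] = None,
) -> FilterThresholds:
    """Exhaustive grid search for filter thresholds.

    Maximizes accepted positives subject to accepted blanks per FOV
    <= ``max_blank_count``; ties are broken by fewer accepted blanks, then
    by fewer active bounds.  Raises :class:`InfeasibleThresholdError`
    (carrying the best achievable blank count) when no grid point meets the
    constraint.
    """
    pos_df, _ = _as_frame(positives)
    blank_df, _ = _as_frame(blanks)
    if len(pos_df) == 0 or len(blank_df) == 0:
        raise InvalidParameterError("positives and blanks must be non-empty")
    grid = dict(grid) if grid is not None else default_grid()
    if n_blank_fovs is None:
        n_blank_fovs = max(int(blank_df["fov_id"].nunique()), 1)

    slots: list[tuple[str, str, list]] = []
    for param, sides in grid.items():
        if param not in FINGERPRINT_PARAMS:
            raise InvalidParameterError(f"unknown fingerprint parameter {param!r}")
        for side in ("min", "max"):
            cands = list(sides.get(side, [None]))
            if cands:
                slots.append((param, side, cands))

    # precompute per-candidate acceptance masks for both tables
    pos_masks = [
        [_side_mask(pos_df[p].to_numpy(dtype=float), c, s) for c in cands]
        for p, s, cands in slots
    ]
    blank_masks = [
        [_side_mask(blank_df[p].to_numpy(dtype=float), c, s) for c in cands]
        for p, s, cands in slots
    ]

    best = None  # (n_pos, -n_blank, -n_active, combo)
    best_blank = math.inf
    for combo in itertools.product(*(range(len(c)) for _, _, c in slots)):
        # skip min > max combinations within a parameter
        valid = True
        chosen: dict[str, list[Optional[float]]] = {}
        for (param, side, cands), ci in zip(slots, combo):
            chosen.setdefault(param, [None, None])[0 if side == "min" else 1] = cands[ci]
        for lo, hi in chosen.values():
            if lo is not None and hi is not None and lo > hi:
                valid = False
                break
        if not valid:
            continue
        pm = np.ones(len(pos_df), dtype=bool)
        bm = np.ones(len(blank_df), dtype=bool)
        for k, ci in enumerate(combo):
            pm &= pos_masks[k][ci]
            bm &= blank_masks[k][ci]
        n_blank = int(bm.sum())
        blanks_per_fov = n_blank / n_blank_fovs
        best_blank = min(best_blank, blanks_per_fov)
        if blanks_per_fov > max_blank_count:
            continue
        n_active = sum(
            cands[ci] is not None for (_, _, cands), ci in zip(slots, combo)
        )
        key = (int(pm.sum()), -n_blank, -n_active)
        if best is None or key > best[0]:
            best = (key, chosen)
    if best is None:
        raise InfeasibleThresholdError(
            f"no grid point keeps blanks per FOV <= {max_blank_count} "
            f"(best achievable: {best_blank:.3g})",
            best_blank,
        )
    bounds = {
        p: (lo, hi) for p, (lo, hi) in best[1].items() if lo is not None or hi is not None
    }
    return FilterThresholds(bounds)
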