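"""Ensemble dwell-time fitting, standard curves, LOD and concentrations.

The ensemble mean dwell time of a state is estimated by fitting the
cumulative frequency of all dwell times, binned at the camera frame time,
to the single-exponential

    y = m * exp(-x / tau) + c,   with m fixed at -1,

whose coefficient tau is the average dwell time; the fit is accepted when
SSE < 0.05 and R^2 > 0.99.  Digital counting is quantified through linear
standard curves (mean accepted counts per FOV versus concentration), from
which LOD = 3 s / m (s: blank-count SD, m: slope) and concentrations
(count - intercept) / slope follow; spike-in normalization rescales
concentrations by the recovery of a doped exogenous control.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import optimize, stats

from .core import InsufficientDataError, InvalidParameterError

__all__ = [
    "CDFData",
    "ExpFit",
    "StandardCurve",
    "NormalizedConcentration",
    "cumulative_dwell_hist",
    "fit_exponential_cdf",
    "fit_standard_curve",
    "lod",
    "estimate_concentration",
    "normalize_spikein",
    "compare_groups",
]

SSE_ACCEPT = 0.05
R2_ACCEPT = 0.99


@dataclass
class CDFData:
    """Cumulative dwell-time frequency on a frame-time bin grid."""

    bin_edges: np.ndarray  # right edges, multiples of frame_time, starting at one frame
    cumulative_frequency: np.ndarray  # non-decreasing, ends at 1
    n_dwells: int


@dataclass
class ExpFit:
    """Single-exponential CDF fit y = m exp(-x/tau) + c with m = -1."""

    m: float
    tau: float
    c: float
    sse: float
    r2: float
    accepted: bool


@dataclass
class StandardCurve:
    """Linear model of mean accepted counts per FOV versus concentration."""

    slope: float
    intercept: float
    r2: float
    blank_sd: float
    concentration_unit: str = "pM"


@dataclass
class NormalizedConcentration:
    """Spike-in-corrected concentration [C]_N = C_raw * spike_true / spike_measured."""

    target: str
    c_raw: float
    c_norm: float
    spike_true: float
    spike_measured: float


def cumulative_dwell_hist(dwells: Sequence[float], frame_time: float) -> CDFData:
    """Cumulative fraction of dwells <= each frame-time bin edge."""
    d = np.asarray(list(dwells), dtype=float)
    if d.size == 0:
        raise InsufficientDataError("no dwells to histogram")
    if frame_time <= 0:
        raise InvalidParameterError("frame_time must be positive")
    if np.any(d <= 0):
        raise InvalidParameterError("dwell times must be positive")
    n_bins = int(np.ceil(np.max(d) / frame_time - 1e-9))
    edges = (np.arange(n_bins) + 1) * frame_time
    counts = np.array([(d <= e + 1e-12).sum() for e in edges], dtype=float)
    return CDFData(edges, counts / d.size, d.size)


def fit_exponential_cdf(cdf: CDFData, tau0: Optional[float] = None) -> ExpFit:
    """Least-squares fit of y = -exp(-x/tau) + c over the CDF points.

    The amplitude m is fixed at -1 (single-exponential); tau then estimates
    the average dwell time and c converges to 1 for exponential data.  The
    ``accepted`` flag applies the SSE < 0.05 and R^2 > 0.99 rules.
    """
    x = np.asarray(cdf.bin_edges, dtype=float)
    y = np.asarray(cdf.cumulative_frequency, dtype=float)
    if np.unique(x).size < 5:
        raise InsufficientDataError("need at least 5 distinct bins for the CDF fit")
    if tau0 is None:
        # initial guess: mean dwell implied by the first bin's mass, guarded
        first = max(min(y[0], 1.0 - 1e-9), 1e-9)
        tau0 = float(np.clip(-x[0] / np.log1p(-first), x[0] / 10, x[-1]))

    def model(xv, tau, c):
        return -np.exp(-xv / tau) + c

    try:
        popt, _ = optimize.curve_fit(
            model, x, y, p0=(tau0, 1.0), bounds=([1e-12, -np.inf], [np.inf, np.inf]),
            maxfev=10000,
        )
    except RuntimeError as exc:  # pragma: no cover - optimizer pathologies
        raise InsufficientDataError(f"exponential CDF fit failed: {exc}") from exc
    tau, c = float(popt[0]), float(popt[1])
    resid = y - model(x, tau, c)
    sse = float(np.sum(resid**2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - sse / ss_tot if ss_tot > 0 else float("nan")
    accepted = bool(sse < SSE_ACCEPT and r2 > R2_ACCEPT)
    return ExpFit(-1.0, tau, c, sse, r2, accepted)


def fit_standard_curve(
    concentrations: Sequence[float],
    counts_per_fov: Sequence[Sequence[float]],
    blank_counts: Sequence[float],
    concentration_unit: str = "pM",
) -> StandardCurve:
    """OLS of mean accepted counts per FOV on concentration.

    ``counts_per_fov`` holds the replicate counts at each concentration
    (the regression uses replicate means); ``blank_counts`` are target-free
    replicates whose sample SD enters the LOD.
    """
    conc = np.asarray(list(concentrations), dtype=float)
    if conc.size < 3:
        raise InsufficientDataError("need at least 3 concentration points")
    if np.unique(conc).size < 2:
        raise InvalidParameterError("degenerate design: one distinct concentration")
    blanks = np.asarray(list(blank_counts), dtype=float)
    if blanks.size < 2:
        raise InsufficientDataError("need at least 2 blank replicates")
    means = np.array([np.mean(np.asarray(c, dtype=float)) for c in counts_per_fov])
    if means.size != conc.size:
        raise InvalidParameterError("one replicate list per concentration required")
    res = stats.linregress(conc, means)
    return StandardCurve(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r2=float(res.rvalue**2),
        blank_sd=float(np.std(blanks, ddof=1)),
        concentration_unit=concentration_unit,
    )


def lod(curve: StandardCurve) -> float:
    """Limit of detection, 3 * blank SD / slope, in the curve's unit."""
    if curve.slope <= 0:
        raise InvalidParameterError("LOD needs a positive standard-curve slope")
    return 3.0 * curve.blank_sd / curve.slope


def estimate_concentration(count_per_fov: float, curve: StandardCurve) -> float:
    """(count - intercept) / slope, floored at zero."""
    if curve.slope <= 0:
        raise InvalidParameterError("concentration needs a positive slope")
    return max(0.0, (count_per_fov - curve.intercept) / curve.slope)


def normalize_spikein(
    c_raw: float,
    spike_measured: float,
    spike_true: float = 5.0,
    target: str = "",
) -> NormalizedConcentration:
    """Spike-in normalization against a doped control (default 5 pM)."""
    if spike_measured <= 0:
        raise InvalidParameterError("measured spike-in concentration must be positive")
    return NormalizedConcentration(
        target, c_raw, c_raw * spike_true / spike_measured, spike_true, spike_measured
    )


def compare_groups(a: Sequence[float], b: Sequence[float]) -> tuple[float, float]:
    """Classical two-sample Student's t (pooled variance), two-sided p."""
    a = np.asarray(list(a), dtype=float)
    b = np.asarray(list(b), dtype=float)
    if a.size < 2 or b.size < 2:
        raise InsufficientDataError("each group needs at least 2 values")
    t, p = stats.ttest_ind(a, b, equal_var=True)
    return float(t), float(p)
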