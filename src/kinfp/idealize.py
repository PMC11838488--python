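"""Two-state hidden-Markov idealization of intensity-versus-time traces.

Each trace is modeled as a two-state (probe-bound / probe-unbound) Markov
chain with Gaussian emissions sharing one noise standard deviation.  The
model is fitted per trace by Baum-Welch EM and the state path is decoded
with Viterbi; the state with the larger emission mean is "bound".

The implementation is a batch EM vectorized across traces of equal length,
since a fingerprinting experiment idealizes thousands of traces per field
of view; :func:`idealize_trace` is the single-trace convenience wrapper.

Dwell-time bookkeeping follows survival-analysis practice: the first and
last dwells of a path are censored by the observation window and are
excluded from dwell lists (flags record their presence), because truncated
dwells bias exponential statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from ._hmm import fb_pass, viterbi
from .core import DegenerateTraceError, InvalidParameterError, Trace

__all__ = [
    "HmmConfig",
    "IdealizedTrace",
    "DwellSet",
    "idealize_trace",
    "idealize_batch",
    "dwell_times",
]



@dataclass(frozen=True)
class HmmConfig:
    """EM settings for the two-state idealization.

    ``min_event_frames`` merges state runs shorter than the given number of
    frames into their flanking state; the default of 1 keeps single-frame
    events, since the shortest real bound dwells are a single 100-ms frame.
    """

    n_states: int = 2
    max_iter: int = 50
    tol: float = 1e-5
    init: str = "kmeans"
    min_event_frames: int = 1

    def __post_init__(self) -> None:
        if self.n_states != 2:
            raise InvalidParameterError("only the two-state model is supported")
        if self.max_iter < 1 or self.tol <= 0 or self.min_event_frames < 1:
            raise InvalidParameterError("invalid HMM configuration")
        if self.init not in ("kmeans", "quantile"):
            raise InvalidParameterError("init must be 'kmeans' or 'quantile'")


@dataclass
class IdealizedTrace:
    """Decoded bound/unbound path plus dwell segments of one trace."""

    states: np.ndarray  # bool per frame, True = bound
    mean_bound: float
    mean_unbound: float
    noise_sd: float
    dwells_on: np.ndarray  # complete bound dwells (s)
    dwells_off: np.ndarray  # complete unbound dwells (s)
    censored_first: bool
    censored_last: bool
    frame_time: float
    converged: bool = True
    molecule_id: str = ""
    channel: str = "C1"
    fov_id: str = "fov0"

    @property
    def n_transitions(self) -> int:
        return int(np.count_nonzero(np.diff(self.states.astype(np.int8))))


@dataclass
class DwellSet:
    """Complete dwell durations of one idealized trace."""

    bound: np.ndarray
    unbound: np.ndarray
    n_transitions: int

    @property
    def n_bound(self) -> int:
        return self.bound.size

    @property
    def n_unbound(self) -> int:
        return self.unbound.size


def _init_means(X: np.ndarray, how: str) -> np.ndarray:
    """Per-trace initial (low, high) emission means."""
    lo = np.percentile(X, 10, axis=1)
    hi = np.percentile(X, 90, axis=1)
    if how == "quantile":
        return np.stack([lo, hi], axis=1)
    # 1-D two-means (Lloyd) vectorized across traces; ties broken by mean order
    for _ in range(20):
        thr = 0.5 * (lo + hi)
        below = X < thr[:, None]
        nb = below.sum(axis=1)
        na = X.shape[1] - nb
        ok = (nb > 0) & (na > 0)
        sb = (X * below).sum(axis=1)
        lo = np.where(ok, sb / np.maximum(nb, 1), lo)
        hi = np.where(ok, (X.sum(axis=1) - sb) / np.maximum(na, 1), hi)
    return np.stack([lo, hi], axis=1)


def _em_fit(X: np.ndarray, cfg: HmmConfig):
    """Batch Baum-Welch for independent 2-state Gaussian HMMs.

    Returns (mu (n,2), sigma (n,), A (n,2,2), pi (n,2), converged (n,)).
    Convergence is tracked per trace (relative log-likelihood change below
    ``cfg.tol``); iteration stops once every trace has converged at least
    once or ``cfg.max_iter`` is reached, whichever comes first.
    """
    n, T = X.shape
    mu = _init_means(X, cfg.init)
    sep = np.maximum(mu[:, 1] - mu[:, 0], 1e-12)
    resid = X[:, :, None] - mu[:, None, :]
    sigma = np.sqrt(np.min(resid**2, axis=2).mean(axis=1))
    sigma = np.maximum(sigma, 1e-4 * sep)
    A = np.tile(np.array([[0.9, 0.1], [0.1, 0.9]]), (n, 1, 1))
    pi = np.full((n, 2), 0.5)
    prev_ll = np.full(n, -np.inf)
    converged = np.zeros(n, dtype=bool)
    eps = 1e-8
    for _ in range(cfg.max_iter):
        idx = np.flatnonzero(~converged)
        if idx.size == 0:
            break
        # only unconverged traces are re-passed; each trace's EM is independent
        ll, e, m, v, xi, gamma0 = fb_pass(
            np.ascontiguousarray(X[idx]), mu[idx], sigma[idx], A[idx], pi[idx]
        )
        # M-step (scattered back into the full parameter arrays)
        pi[idx] = gamma0 / np.maximum(gamma0.sum(axis=1, keepdims=True), 1e-300)
        row = xi.sum(axis=2, keepdims=True) + eps
        A[idx] = (xi + 0.5 * eps) / row
        mu[idx] = np.where(e > eps, m / np.maximum(e, eps), mu[idx])
        new_sigma = np.sqrt(v.sum(axis=1) / T)
        sigma[idx] = np.maximum(
            new_sigma,
            1e-4 * np.maximum(np.abs(mu[idx, 1] - mu[idx, 0]), 1e-12),
        )
        converged[idx] = np.abs(ll - prev_ll[idx]) <= cfg.tol * np.maximum(
            np.abs(ll), 1.0
        )
        prev_ll[idx] = ll
    # keep the larger-mean state in column 1 ("bound")
    swap = mu[:, 0] > mu[:, 1]
    if swap.any():
        mu[swap] = mu[swap][:, ::-1]
        pi[swap] = pi[swap][:, ::-1]
        A[swap] = A[swap][:, ::-1, :][:, :, ::-1]
    return mu, sigma, A, pi, converged


def _viterbi(X: np.ndarray, mu, sigma, A, pi) -> np.ndarray:
    """Batch Viterbi decoding in the log domain; returns bool (n, T) paths."""
    return viterbi(
        np.ascontiguousarray(X),
        np.ascontiguousarray(mu),
        np.ascontiguousarray(sigma),
        np.ascontiguousarray(A),
        np.ascontiguousarray(pi),
    )


def _merge_short_runs(states: np.ndarray, min_frames: int) -> np.ndarray:
    """Absorb runs shorter than ``min_frames`` into the flanking state."""
    if min_frames <= 1:
        return states
    s = states.copy()
    while True:
        edges = np.flatnonzero(np.diff(s.astype(np.int8)))
        starts = np.concatenate(([0], edges + 1))
        ends = np.concatenate((edges + 1, [s.size]))
        lengths = ends - starts
        if len(starts) <= 1:
            return s
        # interior runs only; boundary runs are censored, not events
        short = [
            i for i in range(1, len(starts) - 1) if lengths[i] < min_frames
        ]
        if not short:
            return s
        i = min(short, key=lambda j: (lengths[j], j))
        s[starts[i] : ends[i]] = ~s[starts[i]]


def _dwells_from_states(
    states: np.ndarray, frame_time: float
) -> tuple[np.ndarray, np.ndarray, bool, bool]:
    edges = np.flatnonzero(np.diff(states.astype(np.int8)))
    starts = np.concatenate(([0], edges + 1))
    ends = np.concatenate((edges + 1, [states.size]))
    lengths = (ends - starts) * frame_time
    run_states = states[starts]
    n_runs = len(starts)
    complete = np.ones(n_runs, dtype=bool)
    complete[0] = False
    complete[-1] = False
    dwells_on = lengths[complete & run_states]
    dwells_off = lengths[complete & ~run_states]
    censored_first = bool(n_runs >= 1)
    censored_last = bool(n_runs >= 1)
    return dwells_on, dwells_off, censored_first, censored_last


def idealize_batch(
    X: np.ndarray,
    frame_time: float,
    cfg: Optional[HmmConfig] = None,
    molecule_ids: Optional[Sequence[str]] = None,
    channels: Optional[Sequence[str]] = None,
    fov_ids: Optional[Sequence[str]] = None,
) -> list[Optional[IdealizedTrace]]:
    """Idealize a stack of equal-length traces.

    ``X`` is (n_traces, n_frames).  Traces with zero intensity variance are
    degenerate and yield ``None`` entries (the single-trace wrapper raises
    instead); callers treat them as carrying no kinetic information.
    """
    cfg = cfg or HmmConfig()
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise InvalidParameterError("idealize_batch expects a (n_traces, n_frames) array")
    n, T = X.shape
    if T < 10:
        raise InvalidParameterError("traces must have at least 10 frames")
    out: list[Optional[IdealizedTrace]] = [None] * n
    ok = X.std(axis=1) > 0
    idx_all = np.flatnonzero(ok)
    # bound working memory by chunking traces; each chunk is an independent fit
    chunk = max(1, int(2e7 // max(T, 1)))
    for start in range(0, idx_all.size, chunk):
        idx = idx_all[start : start + chunk]
        Xok = X[idx]
        mu, sigma, A, pi, conv = _em_fit(Xok, cfg)
        paths = _viterbi(Xok, mu, sigma, A, pi)
        for j, i in enumerate(idx):
            states = _merge_short_runs(paths[j], cfg.min_event_frames)
            d_on, d_off, cf, cl = _dwells_from_states(states, frame_time)
            out[i] = IdealizedTrace(
                states=states,
                mean_bound=float(mu[j, 1]),
                mean_unbound=float(mu[j, 0]),
                noise_sd=float(sigma[j]),
                dwells_on=d_on,
                dwells_off=d_off,
                censored_first=cf,
                censored_last=cl,
                frame_time=frame_time,
                converged=bool(conv[j]),
                molecule_id=molecule_ids[i] if molecule_ids is not None else f"m{i}",
                channel=channels[i] if channels is not None else "C1",
                fov_id=fov_ids[i] if fov_ids is not None else "fov0",
            )
    return out


def idealize_trace(trace: Trace, cfg: Optional[HmmConfig] = None) -> IdealizedTrace:
    """Fit the two-state HMM to one trace and decode its state path."""
    if len(trace) < 10:
        raise InvalidParameterError("trace must have at least 10 frames")
    if np.std(trace.intensities) == 0:
        raise DegenerateTraceError("trace has zero intensity variance")
    result = idealize_batch(
        trace.intensities[None, :],
        trace.frame_time,
        cfg,
        molecule_ids=[trace.molecule_id],
        channels=[trace.channel],
        fov_ids=[trace.fov_id],
    )[0]
    assert result is not None
    return result


def dwell_times(ideal: IdealizedTrace, frame_time: Optional[float] = None) -> DwellSet:
    """Complete dwell durations (run lengths x frame time) of an idealized path.

    Censored boundary dwells are excluded from the lists; the transition
    count is preserved regardless.
    """
    ft = frame_time if frame_time is not None else ideal.frame_time
    d_on, d_off, _, _ = _dwells_from_states(ideal.states, ft)
    return DwellSet(d_on, d_off, ideal.n_transitions)
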