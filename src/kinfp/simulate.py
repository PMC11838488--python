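"""Ground-truth simulator for single-molecule kinetic fingerprinting data.

Each surface-captured target molecule is modeled as an alternating renewal
process: a fluorescent probe binds for an exponentially distributed dwell
with mean ``tau_on`` and stays absent for an exponential dwell with mean
``tau_off``.  The continuous-time path is integrated by the camera frame by
frame (fractional occupancy scales emission linearly, matching photon
integration over the 100-ms exposure), and Gaussian read/shot noise is
added.  Nonspecific binders produce a small number of short, sparse events.

The simulator is the ground truth for every downstream stage: it records
exact transition times per molecule so that idealization, fingerprinting,
demultiplexing and quantification can all be validated against known
kinetics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from .core import (
    CapacityError,
    ColorChannel,
    InvalidParameterError,
    Trace,
)

__all__ = [
    "TargetKinetics",
    "EmissionModel",
    "NonspecificModel",
    "SimConfig",
    "TruthRecord",
    "LabeledTraceSet",
    "simulate_kinetic_trace",
    "simulate_nonspecific_trace",
    "simulate_fov",
    "render_movie",
    "simulate_clustering_dataset",
    "simulate_counts",
    "default_emission",
    "THREE_PLEX_KINETICS",
]


@dataclass(frozen=True)
class TargetKinetics:
    """Per-target binding kinetics: mean bound/unbound dwell times (s)."""

    name: str
    tau_on: float
    tau_off: float
    channel: ColorChannel = ColorChannel.C1

    def __post_init__(self) -> None:
        if not (self.tau_on > 0 and self.tau_off > 0):
            raise InvalidParameterError(
                f"tau_on and tau_off must be positive, got "
                f"({self.tau_on}, {self.tau_off})"
            )
        object.__setattr__(self, "channel", ColorChannel(self.channel))

    @property
    def bound_fraction(self) -> float:
        """Stationary probability of the bound state."""
        return self.tau_on / (self.tau_on + self.tau_off)


@dataclass(frozen=True)
class EmissionModel:
    """Camera-level emission model for rendering traces and movies.

    ``mean_bound``/``mean_unbound`` are the per-frame trace intensities of a
    fully bound / fully unbound frame; ``noise_sd`` the Gaussian noise added
    per frame; ``psf_sigma`` (pixels) is only used when rendering movies.
    """

    mean_bound: float = 1.0
    mean_unbound: float = 0.0
    noise_sd: float = 0.2
    psf_sigma: float = 1.0

    def __post_init__(self) -> None:
        if not self.mean_bound > self.mean_unbound:
            raise InvalidParameterError("mean_bound must exceed mean_unbound")
        if not self.noise_sd > 0:
            raise InvalidParameterError("noise_sd must be positive")


def default_emission() -> EmissionModel:
    """Default emission: SNR 5, typical of a well-tuned TIRF acquisition."""
    return EmissionModel()


@dataclass(frozen=True)
class NonspecificModel:
    """Sparse, short-lived nonspecific binding.

    ``events_mean`` is the Poisson mean of the number of binding events per
    acquisition (truncated to >= 1 event so every nonspecific trace shows at
    least one punctum); ``tau_on`` the mean bound dwell of those events.
    """

    events_mean: float = 1.5
    tau_on: float = 0.3
    channel: ColorChannel = ColorChannel.C1

    def __post_init__(self) -> None:
        if self.events_mean <= 0 or self.tau_on <= 0:
            raise InvalidParameterError("nonspecific parameters must be positive")


@dataclass(frozen=True)
class SimConfig:
    """Full configuration of a simulated field of view."""

    targets: tuple[tuple[TargetKinetics, int], ...]
    n_nonspecific: int = 0
    acquisition_time: float = 300.0
    frame_time: float = 0.1
    emission: EmissionModel = field(default_factory=default_emission)
    nonspecific: NonspecificModel = field(default_factory=NonspecificModel)
    seed: int = 0
    integration: str = "linear"
    fov_id: str = "fov0"

    def __post_init__(self) -> None:
        object.__setattr__(self, "targets", tuple((k, int(n)) for k, n in self.targets))
        _validate_times(self.acquisition_time, self.frame_time)
        if any(n < 0 for _, n in self.targets) or self.n_nonspecific < 0:
            raise InvalidParameterError("molecule counts must be >= 0")
        if self.integration not in ("linear", "binary"):
            raise InvalidParameterError("integration must be 'linear' or 'binary'")

    @property
    def n_frames(self) -> int:
        return int(round(self.acquisition_time / self.frame_time))

    @property
    def n_molecules(self) -> int:
        return sum(n for _, n in self.targets) + self.n_nonspecific


@dataclass
class TruthRecord:
    """Exact generating path of one simulated trace.

    ``transitions`` are the state-change times (s) of the trace's own color
    channel within (0, T); the path starts in the bound state iff
    ``initial_bound``.  For a C12 molecule the union path over both colors
    is kept in ``molecule_transitions``/``molecule_initial_bound``.
    """

    molecule_id: str
    label: str
    channel: ColorChannel
    initial_bound: bool
    transitions: np.ndarray
    acquisition_time: float
    frame_time: float
    position: Optional[tuple[int, int]] = None
    molecule_transitions: Optional[np.ndarray] = None
    molecule_initial_bound: Optional[bool] = None

    def boundaries(self) -> np.ndarray:
        return np.concatenate(([0.0], self.transitions, [self.acquisition_time]))

    def segment_states(self) -> np.ndarray:
        """Boolean bound/unbound state of each segment between boundaries."""
        n_seg = len(self.transitions) + 1
        states = np.zeros(n_seg, dtype=bool)
        states[0::2] = self.initial_bound
        states[1::2] = not self.initial_bound
        return states

    def bound_intervals(self) -> list[tuple[float, float]]:
        b = self.boundaries()
        s = self.segment_states()
        return [(b[i], b[i + 1]) for i in np.nonzero(s)[0]]

    def occupancy(self) -> np.ndarray:
        """Fraction of each frame spent in the bound state."""
        return _occupancy(
            self.boundaries(), self.segment_states(), self.acquisition_time, self.frame_time
        )

    def state_path(self) -> np.ndarray:
        """Majority-occupancy per-frame bound/unbound truth path."""
        return self.occupancy() >= 0.5

    def complete_dwells(self) -> tuple[np.ndarray, np.ndarray]:
        """(bound, unbound) dwell durations with censored boundary dwells dropped."""
        b = self.boundaries()
        s = self.segment_states()
        durations = np.diff(b)
        n = len(durations)
        complete = np.ones(n, dtype=bool)
        complete[0] = False
        complete[-1] = False
        return durations[complete & s], durations[complete & ~s]

    def bound_time(self) -> float:
        b = self.boundaries()
        return float(np.sum(np.diff(b)[self.segment_states()]))


@dataclass
class LabeledTraceSet:
    """Simulated traces plus one truth record per trace."""

    traces: list[Trace]
    truths: list[TruthRecord]
    frame_time: float = 0.1
    fov_id: str = "fov0"

    def __post_init__(self) -> None:
        if len(self.traces) != len(self.truths):
            raise InvalidParameterError("one truth record per trace is required")

    def __len__(self) -> int:
        return len(self.traces)


# --- printed three-plex kinetics (ensemble <tau_on>, <tau_off> in seconds) ---
THREE_PLEX_KINETICS: tuple[TargetKinetics, ...] = (
    TargetKinetics("miR-29", 0.49, 10.35),
    TargetKinetics("miR-16", 2.29, 2.69),
    TargetKinetics("let-7a", 6.25, 16.47),
)


def _validate_times(acquisition_time: float, frame_time: float) -> None:
    if frame_time <= 0 or acquisition_time <= 0:
        raise InvalidParameterError("acquisition_time and frame_time must be positive")
    n = acquisition_time / frame_time
    if n < 1:
        raise InvalidParameterError("acquisition_time is below one frame")
    if abs(n - round(n)) > 1e-6 * max(1.0, n):
        raise InvalidParameterError(
            "acquisition_time must be an integer multiple of frame_time"
        )


def _occupancy(
    boundaries: np.ndarray, states: np.ndarray, acquisition_time: float, frame_time: float
) -> np.ndarray:
    """Fraction of each frame covered by bound segments (exact integration)."""
    n_frames = int(round(acquisition_time / frame_time))
    # cumulative bound time is piecewise linear with slope 1 on bound segments
    cum = np.concatenate(([0.0], np.cumsum(np.diff(boundaries) * states)))
    edges = np.arange(n_frames + 1) * frame_time
    cum_at_edges = np.interp(edges, boundaries, cum)
    return np.clip(np.diff(cum_at_edges) / frame_time, 0.0, 1.0)


def _draw_renewal_path(
    rng: np.random.Generator, tau_on: float, tau_off: float, acquisition_time: float
) -> tuple[bool, np.ndarray]:
    """Alternating exponential dwells truncated at the acquisition window.

    The initial state is drawn from the stationary distribution, so long
    traces have bound fraction tau_on / (tau_on + tau_off).
    """
    initial_bound = bool(rng.random() < tau_on / (tau_on + tau_off))
    times: list[float] = []
    t = 0.0
    bound = initial_bound
    while True:
        t += rng.exponential(tau_on if bound else tau_off)
        if t >= acquisition_time:
            break
        times.append(t)
        bound = not bound
    return initial_bound, np.asarray(times)


def _trace_from_path(
    initial_bound: bool,
    transitions: np.ndarray,
    acquisition_time: float,
    frame_time: float,
    emission: EmissionModel,
    rng: np.random.Generator,
    integration: str = "linear",
) -> np.ndarray:
    boundaries = np.concatenate(([0.0], transitions, [acquisition_time]))
    n_seg = len(transitions) + 1
    states = np.zeros(n_seg, dtype=bool)
    states[0::2] = initial_bound
    states[1::2] = not initial_bound
    if integration == "linear":
        occ = _occupancy(boundaries, states, acquisition_time, frame_time)
    else:  # state sampled at frame midpoints
        n_frames = int(round(acquisition_time / frame_time))
        mids = (np.arange(n_frames) + 0.5) * frame_time
        seg = np.clip(np.searchsorted(boundaries, mids, side="right") - 1, 0, n_seg - 1)
        occ = states[seg].astype(float)
    clean = emission.mean_unbound + occ * (emission.mean_bound - emission.mean_unbound)
    return clean + rng.normal(0.0, emission.noise_sd, size=clean.size)


def simulate_kinetic_trace(
    kin: TargetKinetics,
    acquisition_time: float,
    frame_time: float = 0.1,
    emission: Optional[EmissionModel] = None,
    seed: int | np.random.Generator = 0,
    integration: str = "linear",
    molecule_id: str = "m0",
    fov_id: str = "fov0",
) -> tuple[Trace, TruthRecord]:
    """Simulate one molecule's intensity-versus-time trace plus its truth path."""
    _validate_times(acquisition_time, frame_time)
    emission = emission or default_emission()
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    initial_bound, transitions = _draw_renewal_path(
        rng, kin.tau_on, kin.tau_off, acquisition_time
    )
    intensities = _trace_from_path(
        initial_bound, transitions, acquisition_time, frame_time, emission, rng, integration
    )
    trace = Trace(
        intensities,
        frame_time,
        molecule_id=molecule_id,
        channel=str(kin.channel if kin.channel != ColorChannel.C12 else ColorChannel.C1),
        fov_id=fov_id,
    )
    truth = TruthRecord(
        molecule_id,
        kin.name,
        kin.channel,
        initial_bound,
        transitions,
        acquisition_time,
        frame_time,
    )
    return trace, truth


def _draw_nonspecific_path(
    rng: np.random.Generator, model: NonspecificModel, acquisition_time: float
) -> tuple[bool, np.ndarray]:
    """Sparse short events: truncated-Poisson count, uniform starts, exp dwells."""
    n_events = 0
    while n_events < 1:
        n_events = int(rng.poisson(model.events_mean))
    starts = np.sort(rng.uniform(0.0, acquisition_time, size=n_events))
    durations = rng.exponential(model.tau_on, size=n_events)
    # merge overlapping events into a single bound interval
    intervals: list[list[float]] = []
    for a, d in zip(starts, durations):
        b = min(a + d, acquisition_time)
        if intervals and a <= intervals[-1][1]:
            intervals[-1][1] = max(intervals[-1][1], b)
        else:
            intervals.append([a, b])
    times: list[float] = []
    for a, b in intervals:
        if a > 0.0:
            times.append(a)
        if b < acquisition_time:
            times.append(b)
    initial_bound = len(intervals) > 0 and intervals[0][0] == 0.0
    return initial_bound, np.asarray(times)


def simulate_nonspecific_trace(
    model: NonspecificModel,
    acquisition_time: float,
    frame_time: float = 0.1,
    emission: Optional[EmissionModel] = None,
    seed: int | np.random.Generator = 0,
    integration: str = "linear",
    molecule_id: str = "ns0",
    fov_id: str = "fov0",
) -> tuple[Trace, TruthRecord]:
    """Simulate a nonspecific binder: a few short, irregular events."""
    _validate_times(acquisition_time, frame_time)
    emission = emission or default_emission()
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    initial_bound, transitions = _draw_nonspecific_path(rng, model, acquisition_time)
    intensities = _trace_from_path(
        initial_bound, transitions, acquisition_time, frame_time, emission, rng, integration
    )
    trace = Trace(
        intensities, frame_time, molecule_id=molecule_id,
        channel=str(model.channel), fov_id=fov_id,
    )
    truth = TruthRecord(
        molecule_id, "nonspecific", model.channel, initial_bound, transitions,
        acquisition_time, frame_time,
    )
    return trace, truth


def _split_c12_path(
    rng: np.random.Generator,
    initial_bound: bool,
    transitions: np.ndarray,
    acquisition_time: float,
) -> dict[ColorChannel, tuple[bool, np.ndarray]]:
    """Color each bound event of a C12 molecule Cy3 or Cy5 with probability 1/2.

    The molecule is bound by at most one probe at a time, so the two color
    paths are disjoint and their union is the molecule path.
    """
    boundaries = np.concatenate(([0.0], transitions, [acquisition_time]))
    n_seg = len(transitions) + 1
    states = np.zeros(n_seg, dtype=bool)
    states[0::2] = initial_bound
    states[1::2] = not initial_bound
    out: dict[ColorChannel, tuple[bool, np.ndarray]] = {}
    bound_segs = np.nonzero(states)[0]
    colors = rng.random(bound_segs.size) < 0.5  # True -> C1
    for channel, keep in ((ColorChannel.C1, colors), (ColorChannel.C2, ~colors)):
        times: list[float] = []
        init = False
        for seg, k in zip(bound_segs, keep):
            if not k:
                continue
            a, b = boundaries[seg], boundaries[seg + 1]
            if a == 0.0:
                init = True
            else:
                times.append(a)
            if b < acquisition_time:
                times.append(b)
        out[channel] = (init, np.asarray(times))
    return out


def simulate_fov(cfg: SimConfig) -> LabeledTraceSet:
    """Simulate every molecule of one field of view.

    C12 targets yield two traces per molecule (one per color channel) with
    binding events interleaved 50:50 between the colors; all other molecules
    yield a single trace.
    """
    rng = np.random.default_rng(cfg.seed)
    traces: list[Trace] = []
    truths: list[TruthRecord] = []
    idx = 0
    for kin, n in cfg.targets:
        for _ in range(n):
            mol_id = f"{cfg.fov_id}:m{idx:05d}"
            idx += 1
            if kin.channel == ColorChannel.C12:
                initial_bound, transitions = _draw_renewal_path(
                    rng, kin.tau_on, kin.tau_off, cfg.acquisition_time
                )
                per_color = _split_c12_path(
                    rng, initial_bound, transitions, cfg.acquisition_time
                )
                for channel in (ColorChannel.C1, ColorChannel.C2):
                    init, times = per_color[channel]
                    intensities = _trace_from_path(
                        init, times, cfg.acquisition_time, cfg.frame_time,
                        cfg.emission, rng, cfg.integration,
                    )
                    traces.append(
                        Trace(intensities, cfg.frame_time, molecule_id=mol_id,
                              channel=str(channel), fov_id=cfg.fov_id)
                    )
                    truths.append(
                        TruthRecord(
                            mol_id, kin.name, ColorChannel.C12, init, times,
                            cfg.acquisition_time, cfg.frame_time,
                            molecule_transitions=transitions,
                            molecule_initial_bound=initial_bound,
                        )
                    )
            else:
                trace, truth = simulate_kinetic_trace(
                    kin, cfg.acquisition_time, cfg.frame_time, cfg.emission,
                    rng, cfg.integration, molecule_id=mol_id, fov_id=cfg.fov_id,
                )
                traces.append(trace)
                truths.append(truth)
    for _ in range(cfg.n_nonspecific):
        mol_id = f"{cfg.fov_id}:ns{idx:05d}"
        idx += 1
        trace, truth = simulate_nonspecific_trace(
            cfg.nonspecific, cfg.acquisition_time, cfg.frame_time, cfg.emission,
            rng, cfg.integration, molecule_id=mol_id, fov_id=cfg.fov_id,
        )
        traces.append(trace)
        truths.append(truth)
    return LabeledTraceSet(traces, truths, cfg.frame_time, cfg.fov_id)


def _place_molecules(
    rng: np.random.Generator,
    n: int,
    fov_shape: tuple[int, int],
    min_separation: float = 4.0,
    margin: int = 4,
) -> np.ndarray:
    """Uniform positions with a minimum pairwise separation (Euclidean)."""
    h, w = fov_shape
    if h <= 2 * margin or w <= 2 * margin:
        raise CapacityError("field of view too small for the margin")
    usable = (h - 2 * margin) * (w - 2 * margin)
    if n * math.pi * (min_separation / 2.0) ** 2 > 0.7 * usable:
        raise CapacityError(
            f"cannot place {n} molecules at separation {min_separation} in {fov_shape}"
        )
    positions: list[tuple[int, int]] = []
    tries = 0
    while len(positions) < n:
        tries += 1
        if tries > 2000 * max(n, 1):
            raise CapacityError("placement failed at the requested separation")
        r = int(rng.integers(margin, h - margin))
        c = int(rng.integers(margin, w - margin))
        if all((r - p) ** 2 + (c - q) ** 2 >= min_separation**2 for p, q in positions):
            positions.append((r, c))
    return np.asarray(positions)


def _psf_kernel(sigma: float, radius: int) -> np.ndarray:
    """Symmetric 2-D Gaussian normalized to unit integral over its footprint."""
    ax = np.arange(-radius, radius + 1)
    g = np.exp(-(ax**2) / (2.0 * sigma**2))
    k = np.outer(g, g)
    return k / k.sum()


def render_movie(
    trace_set: LabeledTraceSet,
    fov_shape: tuple[int, int],
    emission: Optional[EmissionModel] = None,
    seed: int | np.random.Generator = 0,
    background: float = 0.0,
    min_separation: float = 4.0,
):
    """Render a trace set into per-channel TIFF-ready movie stacks.

    Each molecule becomes a 2-D Gaussian punctum (``psf_sigma``) whose
    integrated amplitude follows its noiseless occupancy path; per-pixel
    Gaussian read noise (``noise_sd``) is then added.  Molecule positions
    (shared between the color channels of a C12 molecule) are written back
    into the truth records and also returned.

    Returns ``(movies, positions)`` where ``movies`` maps raw channel names
    (``C1_raw``/``C2_raw``) to :class:`~kinfp.movie.MovieStack`.
    """
    from .movie import MovieStack  # deferred to keep module dependencies one-way

    emission = emission or default_emission()
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    mol_ids = sorted({t.molecule_id for t in trace_set.traces})
    pos = _place_molecules(rng, len(mol_ids), fov_shape, min_separation)
    positions = {m: (int(r), int(c)) for m, (r, c) in zip(mol_ids, pos)}
    for truth in trace_set.truths:
        truth.position = positions[truth.molecule_id]

    n_frames = int(round(
        trace_set.traces[0].duration / trace_set.frame_time
    )) if trace_set.traces else 0
    radius = max(2, int(math.ceil(3 * emission.psf_sigma)))
    kernel = _psf_kernel(emission.psf_sigma, radius)
    present = {t.channel for t in trace_set.traces} or {"C1"}
    movies = {}
    for channel in sorted(present):
        frames = np.zeros((max(n_frames, 1), *fov_shape), dtype=float)
        for trace, truth in zip(trace_set.traces, trace_set.truths):
            if trace.channel != channel:
                continue
            r, c = positions[trace.molecule_id]
            amp = (
                emission.mean_unbound
                + truth.occupancy() * (emission.mean_bound - emission.mean_unbound)
            )
            r0, r1 = r - radius, r + radius + 1
            c0, c1 = c - radius, c + radius + 1
            kr0, kc0 = max(0, -r0), max(0, -c0)
            fr0, fc0 = max(0, r0), max(0, c0)
            fr1, fc1 = min(fov_shape[0], r1), min(fov_shape[1], c1)
            sub = kernel[kr0 : kr0 + (fr1 - fr0), kc0 : kc0 + (fc1 - fc0)]
            frames[:, fr0:fr1, fc0:fc1] += amp[:, None, None] * sub[None, :, :]
        frames += background
        frames += rng.normal(0.0, emission.noise_sd, size=frames.shape)
        raw = "C1_raw" if channel == "C1" else "C2_raw"
        movies[raw] = MovieStack(frames, trace_set.frame_time, raw, trace_set.fov_id)
    return movies, positions


def simulate_clustering_dataset(
    kinetics: Sequence[TargetKinetics],
    n_per_target: int,
    acquisition_time: float,
    seed: int | np.random.Generator = 0,
    frame_time: float = 0.1,
    emission: Optional[EmissionModel] = None,
    hmm_config=None,
):
    """Simulate -> idealize -> fingerprint for a labeled multi-target dataset.

    Returns a :class:`pandas.DataFrame` of kinetic fingerprints with a
    ``true_label`` column, one row per molecule, suitable for cluster
    training and assignment experiments at any acquisition time.
    """
    import pandas as pd

    from .fingerprint import fingerprint_table
    from .idealize import HmmConfig, idealize_batch

    if n_per_target < 1:
        raise InvalidParameterError("n_per_target must be >= 1")
    _validate_times(acquisition_time, frame_time)
    emission = emission or default_emission()
    hmm_config = hmm_config or HmmConfig()
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed

    traces: list[np.ndarray] = []
    labels: list[str] = []
    ids: list[str] = []
    idx = 0
    for kin in kinetics:
        for _ in range(n_per_target):
            mol_id = f"sim:m{idx:05d}"
            idx += 1
            trace, _ = simulate_kinetic_trace(
                kin, acquisition_time, frame_time, emission, rng, molecule_id=mol_id
            )
            traces.append(trace.intensities)
            labels.append(kin.name)
            ids.append(mol_id)
    ideals = idealize_batch(np.asarray(traces), frame_time, hmm_config)
    table = fingerprint_table(ideals, frame_time, molecule_ids=ids)
    table["true_label"] = labels
    table["channel"] = [str(k.channel) for k in kinetics for _ in range(n_per_target)]
    return pd.DataFrame(table)


def simulate_counts(
    concentrations: Sequence[float],
    counts_per_unit: float,
    n_fov: int,
    seed: int | np.random.Generator = 0,
    background_rate: float = 0.0,
) -> np.ndarray:
    """Digital per-FOV counts at given concentrations (Poisson counting).

    Accepted single-molecule counts per FOV are Poisson with mean
    ``counts_per_unit * concentration + background_rate``; this is the
    counting-statistics level of the assay, used for standard curves, LOD
    and ratio-metric studies.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    conc = np.asarray(list(concentrations), dtype=float)
    lam = counts_per_unit * conc + background_rate
    if np.any(lam < 0):
        raise InvalidParameterError("negative expected count")
    return rng.poisson(lam[:, None], size=(conc.size, n_fov)).astype(float)
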