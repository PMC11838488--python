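"""Reproducible end-to-end pipelines tying the analysis stages together.

These functions back both the command-line interface and the package's
simulation studies: the acquisition-time clustering study, the kinetic-
filtering specificity study, and the ratio-metric quantification study.
Every entry point takes an explicit seed and derives all per-stage random
streams from it.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import demux, fingerprint, quantify
from .core import InvalidParameterError
from .idealize import HmmConfig
from .simulate import (
    EmissionModel,
    NonspecificModel,
    SimConfig,
    TargetKinetics,
    THREE_PLEX_KINETICS,
    default_emission,
    simulate_clustering_dataset,
    simulate_counts,
    simulate_fov,
)

__all__ = [
    "clustering_study",
    "filtering_study",
    "ratiometric_study",
    "nonspecific_fingerprints",
    "target_fingerprints",
]


def _rng(*entropy: int) -> np.random.Generator:
    return np.random.default_rng(list(entropy))


def clustering_study(
    kinetics: Sequence[TargetKinetics] = THREE_PLEX_KINETICS,
    acquisition_times: Sequence[float] = (50.0, 100.0, 300.0, 1000.0),
    n_per_target: int = 500,
    n_train_per_target: int = 200,
    confidence: float = 0.95,
    rule: str = "confidence",
    seed: int = 0,
    n_seeds: int = 10,
    frame_time: float = 0.1,
    emission: Optional[EmissionModel] = None,
    hmm_config: Optional[HmmConfig] = None,
) -> pd.DataFrame:
    """Unassigned fraction versus acquisition time for a multiplexed mixture.

    For each acquisition time and seed, an independent single-target
    training set is simulated and idealized to pretrain the cluster model,
    then a mixed test set (``n_per_target`` molecules per target) is
    assigned at the given confidence.  Molecules without computable dwell
    medians count as unassigned -- they cannot be placed in any cluster.

    Returns one row per (acquisition_time, seed) with the unassigned
    fraction and molecule counts.
    """
    emission = emission or default_emission()
    rows = []
    for ti, acq in enumerate(acquisition_times):
        for si in range(n_seeds):
            train = simulate_clustering_dataset(
                kinetics, n_train_per_target, acq,
                _rng(seed, ti, si, 0), frame_time, emission, hmm_config,
            )
            model = demux.train_cluster_model(train)
            test = simulate_clustering_dataset(
                kinetics, n_per_target, acq,
                _rng(seed, ti, si, 1), frame_time, emission, hmm_config,
            )
            assignments = demux.assign_molecules(
                test, model, confidence, rule=rule, undefined="unassign"
            )
            frac = demux.unassigned_fraction(assignments)
            rows.append(
                {
                    "acquisition_time": acq,
                    "seed": si,
                    "unassigned_fraction": frac,
                    "n_molecules": len(test),
                    "confidence": confidence,
                }
            )
    return pd.DataFrame(rows)


def target_fingerprints(
    kin: TargetKinetics,
    n: int,
    acquisition_time: float,
    rng: np.random.Generator,
    frame_time: float = 0.1,
    emission: Optional[EmissionModel] = None,
    hmm_config: Optional[HmmConfig] = None,
    fov_id: str = "fov0",
) -> pd.DataFrame:
    """Simulate and fingerprint ``n`` molecules of one target in one FOV."""
    df = simulate_clustering_dataset(
        [kin], n, acquisition_time, rng, frame_time, emission, hmm_config
    )
    df["fov_id"] = fov_id
    return df


def nonspecific_fingerprints(
    n_fovs: int,
    n_per_fov: int,
    acquisition_time: float,
    rng: np.random.Generator,
    model: Optional[NonspecificModel] = None,
    frame_time: float = 0.1,
    emission: Optional[EmissionModel] = None,
    hmm_config: Optional[HmmConfig] = None,
) -> pd.DataFrame:
    """Simulate and fingerprint target-free FOVs of nonspecific binders."""
    from .fingerprint import fingerprint_table
    from .idealize import idealize_batch
    from .simulate import simulate_nonspecific_trace

    model = model or NonspecificModel()
    emission = emission or default_emission()
    traces, ids, fovs = [], [], []
    for f in range(n_fovs):
        fov = f"blank{f:02d}"
        for i in range(n_per_fov):
            mol = f"{fov}:ns{i:05d}"
            tr, _ = simulate_nonspecific_trace(
                model, acquisition_time, frame_time, emission, rng, molecule_id=mol
            )
            traces.append(tr.intensities)
            ids.append(mol)
            fovs.append(fov)
    ideals = idealize_batch(np.asarray(traces), frame_time, hmm_config)
    table = fingerprint_table(ideals, frame_time, molecule_ids=ids)
    df = pd.DataFrame(table)
    df["fov_id"] = fovs
    df["channel"] = str(model.channel)
    return df


def filtering_study(
    target: TargetKinetics = TargetKinetics("miR-16", 2.29, 2.69),
    acquisition_time: float = 300.0,
    n_target_train: int = 300,
    n_target_test: int = 500,
    n_blank_train_fovs: int = 2,
    n_blank_test_fovs: int = 20,
    n_blank_per_fov: int = 500,
    seed: int = 0,
    max_blank_count: float = 0.0,
    frame_time: float = 0.1,
    emission: Optional[EmissionModel] = None,
    nonspecific: Optional[NonspecificModel] = None,
) -> dict:
    """Kinetic-filtering specificity: false positives per blank FOV.

    Thresholds are optimized on an independent simulated target/blank pair
    (grid search, accepted training blanks per FOV <= ``max_blank_count``),
    then applied to ``n_blank_test_fovs`` fresh target-free FOVs and to an
    independent target test set.  Returns the optimized thresholds, the
    mean accepted nonspecific traces per FOV and the target retention.
    """
    emission = emission or default_emission()
    nonspecific = nonspecific or NonspecificModel()
    pos_train = target_fingerprints(
        target, n_target_train, acquisition_time, _rng(seed, 10), frame_time, emission
    )
    blank_train = nonspecific_fingerprints(
        n_blank_train_fovs, n_blank_per_fov, acquisition_time,
        _rng(seed, 11), nonspecific, frame_time, emission,
    )
    thresholds = fingerprint.optimize_thresholds(
        pos_train, blank_train, max_blank_count=max_blank_count
    )
    blank_test = nonspecific_fingerprints(
        n_blank_test_fovs, n_blank_per_fov, acquisition_time,
        _rng(seed, 12), nonspecific, frame_time, emission,
    )
    _, blank_counts = fingerprint.apply_filters(blank_test, thresholds)
    pos_test = target_fingerprints(
        target, n_target_test, acquisition_time, _rng(seed, 13), frame_time, emission
    )
    accepted_pos, _ = fingerprint.apply_filters(pos_test, thresholds)
    return {
        "thresholds": thresholds,
        "false_positives_per_fov": float(np.mean(list(blank_counts.values()))),
        "blank_counts": blank_counts,
        "target_retention": len(accepted_pos) / len(pos_test),
        "n_blank_fovs": n_blank_test_fovs,
    }


def ratiometric_study(
    seed: int = 0,
    total_concentration: float = 5.0,
    ratios: Sequence[float] = (0.01, 0.05, 0.1, 0.25, 0.5, 0.75, 0.9, 0.95, 0.99),
    counts_per_unit: tuple[float, float] = (40.0, 40.0),
    calibration_concentrations: Sequence[float] = (0.5, 1.0, 2.0, 5.0, 10.0),
    n_fov: int = 10,
    blank_rate: float = 0.5,
) -> dict:
    """Two-target mixtures at complementary ratios of a fixed total.

    Per-target standard curves are fitted from simulated calibration counts
    (Poisson counting statistics, per-FOV rate proportional to
    concentration plus a small nonspecific background); mixture counts are
    then converted to concentrations through each curve and regressed on
    the expected concentrations.  A slope near 1 means the ratio-metric
    readout is quantitatively accurate across 1:99 ... 99:1.
    """
    rng = _rng(seed, 20)
    curves = []
    for k, cpu in enumerate(counts_per_unit):
        cal = simulate_counts(
            calibration_concentrations, cpu, n_fov, rng, background_rate=blank_rate
        )
        blanks = simulate_counts([0.0] * 6, cpu, 1, rng, background_rate=blank_rate)[:, 0]
        curves.append(
            quantify.fit_standard_curve(calibration_concentrations, cal, blanks)
        )
    expected, estimated = [], []
    for r in ratios:
        conc = (r * total_concentration, (1.0 - r) * total_concentration)
        for k in (0, 1):
            counts = simulate_counts(
                [conc[k]], counts_per_unit[k], n_fov, rng, background_rate=blank_rate
            )[0]
            est = quantify.estimate_concentration(float(np.mean(counts)), curves[k])
            expected.append(conc[k])
            estimated.append(est)
    from scipy import stats as sstats

    res = sstats.linregress(expected, estimated)
    return {
        "slope": float(res.slope),
        "intercept": float(res.intercept),
        "r2": float(res.rvalue**2),
        "expected": np.asarray(expected),
        "estimated": np.asarray(estimated),
        "lods": [quantify.lod(c) for c in curves],
    }
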