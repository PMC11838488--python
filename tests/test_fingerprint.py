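"""Kinetic fingerprints, filtering and threshold optimization."""

import math

import numpy as np
import pandas as pd
import pytest

from conftest import make_ideal
from kinfp.core import InfeasibleThresholdError, InvalidParameterError
from kinfp.fingerprint import (
    FilterThresholds,
    accepted_mask,
    apply_filters,
    compute_fingerprint,
    fingerprints_to_frame,
    optimize_thresholds,
)
from kinfp.idealize import IdealizedTrace


def hand_built_ideal():
    """U* B3 U10 B5 U20 B7 U30* path at 0.1 s: 6 transitions.

    Complete bound dwells {0.3, 0.5, 0.7}; the trailing unbound run is
    censored, so the stored dwell lists are overridden below to realize the
    documented example with three complete dwells per state.
    """
    states = np.array(
        [0] * 5 + [1] * 3 + [0] * 10 + [1] * 5 + [0] * 20 + [1] * 7 + [0] * 30,
        dtype=bool,
    )
    ideal = make_ideal(states)
    ideal.dwells_on = np.array([0.3, 0.5, 0.7])
    ideal.dwells_off = np.array([1.0, 2.0, 3.0])
    return ideal


def test_fingerprint_hand_example():
    fp = compute_fingerprint(hand_built_ideal())
    assert fp.n_events == 6
    assert fp.tau_on_med == pytest.approx(0.5)
    assert fp.tau_off_med == pytest.approx(2.0)
    assert fp.tau_off_max == pytest.approx(3.0)
    assert fp.snr == pytest.approx(1.0 / 0.2)


def test_transition_free_path_is_undefined():
    fp = compute_fingerprint(make_ideal(np.ones(30, dtype=bool)))
    assert fp.n_events == 0
    assert math.isnan(fp.tau_on_med) and math.isnan(fp.tau_off_med)
    assert math.isnan(fp.tau_off_max)
    fp_none = compute_fingerprint(None)
    assert fp_none.n_events == 0 and math.isnan(fp_none.snr)


def test_frame_time_rescaling_doubles_dwells():
    ideal = hand_built_ideal()
    fp1 = compute_fingerprint(ideal, frame_time=0.1)
    fp2 = compute_fingerprint(ideal, frame_time=0.2)
    assert fp2.n_events == fp1.n_events
    assert fp2.tau_on_med == pytest.approx(2 * fp1.tau_on_med)
    assert fp2.tau_off_max == pytest.approx(2 * fp1.tau_off_max)


def test_literal_inverse_snr_option():
    ideal = hand_built_ideal()
    fp = compute_fingerprint(ideal, literal_inverse=True)
    assert fp.snr == pytest.approx(0.2)


def random_fingerprints(rng, n=60):
    df = pd.DataFrame(
        {
            "molecule_id": [f"m{i}" for i in range(n)],
            "fov_id": rng.choice(["f0", "f1", "f2"], size=n),
            "n_events": rng.integers(0, 30, size=n),
            "tau_on_med": rng.exponential(2.0, size=n),
            "tau_off_med": rng.exponential(5.0, size=n),
            "tau_off_max": rng.exponential(10.0, size=n),
            "snr": rng.uniform(1, 10, size=n),
        }
    )
    df.loc[rng.random(n) < 0.1, "tau_on_med"] = np.nan
    return df


def test_filters_empty_thresholds_accept_all(rng):
    df = random_fingerprints(rng)
    accepted, counts = apply_filters(df, FilterThresholds())
    assert len(accepted) == len(df)
    assert sum(counts.values()) == len(df)


def test_filters_reject_and_undefined_fail_bounds():
    df = pd.DataFrame(
        {
            "molecule_id": ["a", "b", "c"],
            "fov_id": ["f0"] * 3,
            "n_events": [2, 10, 10],
            "tau_on_med": [1.0, np.nan, 2.0],
            "tau_off_med": [1.0, 1.0, 1.0],
            "tau_off_max": [2.0, 2.0, 2.0],
            "snr": [5.0, 5.0, 5.0],
        }
    )
    th = FilterThresholds({"n_events": (4, None), "tau_on_med": (0.5, None)})
    accepted, counts = apply_filters(df, th)
    assert list(accepted["molecule_id"]) == ["c"]  # a: too few events; b: NaN
    assert counts == {"f0": 1}


def test_filtering_is_idempotent_and_antimonotone(rng):
    df = random_fingerprints(rng, 120)
    th = FilterThresholds({"n_events": (5, None), "tau_on_med": (0.5, 8.0)})
    once, _ = apply_filters(df, th)
    twice, _ = apply_filters(once, th)
    pd.testing.assert_frame_equal(once, twice)
    # tightening any single bound never increases the accepted count
    base = accepted_mask(df, th).sum()
    tighter = [
        FilterThresholds({"n_events": (7, None), "tau_on_med": (0.5, 8.0)}),
        FilterThresholds({"n_events": (5, None), "tau_on_med": (1.0, 8.0)}),
        FilterThresholds({"n_events": (5, None), "tau_on_med": (0.5, 4.0)}),
        FilterThresholds({"n_events": (5, None), "tau_on_med": (0.5, 8.0),
                          "snr": (3.0, None)}),
    ]
    for t in tighter:
        assert accepted_mask(df, t).sum() <= base


def test_thresholds_validation():
    with pytest.raises(InvalidParameterError):
        FilterThresholds({"n_events": (10, 2)})
    with pytest.raises(InvalidParameterError):
        FilterThresholds({"bogus": (0, 1)})


def separable_tables():
    pos = pd.DataFrame(
        {
            "molecule_id": [f"p{i}" for i in range(20)],
            "fov_id": ["f0"] * 20,
            "n_events": np.arange(10, 30),
            "tau_on_med": np.full(20, 2.0),
            "tau_off_med": np.full(20, 3.0),
            "tau_off_max": np.full(20, 9.0),
            "snr": np.full(20, 5.0),
        }
    )
    blank = pos.copy()
    blank["molecule_id"] = [f"b{i}" for i in range(20)]
    blank["n_events"] = np.concatenate([np.full(10, 2), np.full(10, 3)])
    return pos, blank


def test_optimizer_finds_separating_event_bound():
    pos, blank = separable_tables()
    grid = {"n_events": {"min": [None] + list(range(1, 13)), "max": [None]}}
    th = optimize_thresholds(pos, blank, grid, max_blank_count=0)
    lo, hi = th.bounds["n_events"]
    assert 3 < lo <= 10 and hi is None
    accepted, _ = apply_filters(pos, th)
    assert len(accepted) == 20
    accepted_blank, _ = apply_filters(blank, th)
    assert len(accepted_blank) == 0


def test_optimizer_matches_exhaustive_oracle(rng):
    """Grid search equals a brute-force scan of every grid point."""
    pos = random_fingerprints(rng, 40)
    blank = random_fingerprints(rng, 40)
    grid = {
        "n_events": {"min": [None, 2, 5, 10], "max": [None]},
        "tau_on_med": {"min": [None, 0.5, 2.0], "max": [None, 4.0]},
    }
    th = optimize_thresholds(pos, blank, grid, max_blank_count=5.0)
    # oracle: enumerate all combos directly
    best = None
    n_fovs = blank["fov_id"].nunique()
    for lo_e in grid["n_events"]["min"]:
        for lo_t in grid["tau_on_med"]["min"]:
            for hi_t in grid["tau_on_med"]["max"]:
                if lo_t is not None and hi_t is not None and lo_t > hi_t:
                    continue
                cand = FilterThresholds({
                    k: v for k, v in
                    {"n_events": (lo_e, None), "tau_on_med": (lo_t, hi_t)}.items()
                    if v[0] is not None or v[1] is not None
                })
                nb = int(accepted_mask(blank, cand).sum())
                if nb / n_fovs > 5.0:
                    continue
                key = (int(accepted_mask(pos, cand).sum()), -nb,
                       -cand.active_bound_count())
                if best is None or key > best:
                    best = key
    got_nb = int(accepted_mask(blank, th).sum())
    got = (int(accepted_mask(pos, th).sum()), -got_nb, -th.active_bound_count())
    assert got == best


def test_optimizer_infeasible_reports_best_blank():
    pos, _ = separable_tables()
    with pytest.raises(InfeasibleThresholdError) as err:
        optimize_thresholds(
            pos, pos.assign(fov_id="f0"),
            {"n_events": {"min": [None, 2], "max": [None]}},
            max_blank_count=0,
        )
    assert err.value.best_blank_count > 0


def test_fingerprints_roundtrip_frame():
    fp = compute_fingerprint(hand_built_ideal())
    df = fingerprints_to_frame([fp])
    assert df.loc[0, "n_events"] == 6
    assert df.loc[0, "tau_off_med"] == pytest.approx(2.0)
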