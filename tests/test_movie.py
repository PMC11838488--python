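"""Fluctuation maps, ROI detection and trace extraction."""

import numpy as np
import pytest

from kinfp.core import InsufficientFramesError, InvalidParameterError, ROI
from kinfp.movie import (
    BackgroundSpec,
    FluctuationMap,
    MovieStack,
    detect_rois,
    extract_trace,
    fluctuation_map,
)
from kinfp.simulate import (
    EmissionModel,
    SimConfig,
    TargetKinetics,
    render_movie,
    simulate_fov,
)


def brute_force_rois(values, min_separation, threshold):
    """Reference ROI detector: explicit maxima scan + greedy suppression."""
    h, w = values.shape
    cands = []
    for r in range(1, h - 1):
        for c in range(1, w - 1):
            v = values[r, c]
            if v <= threshold:
                continue
            if all(
                v >= values[r + dr, c + dc]
                for dr in (-1, 0, 1)
                for dc in (-1, 0, 1)
                if (dr, dc) != (0, 0)
            ):
                cands.append((r, c, v))
    cands.sort(key=lambda x: (-x[2], x[0], x[1]))
    kept = []
    for r, c, v in cands:
        if all(max(abs(r - kr), abs(c - kc)) >= min_separation for kr, kc, _ in kept):
            kept.append((r, c, v))
    return [(r, c) for r, c, _ in kept]


def test_fluctuation_map_hand_case():
    frames = np.zeros((3, 8, 8))
    frames[1, 4, 4] = 100.0
    fmap = fluctuation_map(MovieStack(frames, 0.1))
    assert fmap.values[4, 4] == pytest.approx(100.0)  # mean(|100|, |-100|)
    fmap.values[4, 4] = 0.0
    assert np.all(fmap.values == 0.0)


def test_fluctuation_map_constant_and_errors():
    assert np.all(fluctuation_map(MovieStack(np.full((5, 4, 4), 3.0), 0.1)).values == 0)
    with pytest.raises(InsufficientFramesError):
        fluctuation_map(MovieStack(np.zeros((1, 4, 4)), 0.1))


def test_offset_invariance(rng):
    frames = rng.normal(10.0, 2.0, size=(30, 16, 16))
    m1 = fluctuation_map(MovieStack(frames, 0.1)).values
    m2 = fluctuation_map(MovieStack(frames + 7.25, 0.1)).values
    np.testing.assert_allclose(m1, m2, rtol=0, atol=1e-9)
    roi = ROI((8, 8))
    t1 = extract_trace(MovieStack(frames, 0.1), roi).intensities
    t2 = extract_trace(MovieStack(frames + 7.25, 0.1), roi).intensities
    np.testing.assert_allclose(t1, t2, rtol=0, atol=1e-8)


def test_detect_rois_simple_cases():
    z = FluctuationMap(np.zeros((10, 10)))
    assert detect_rois(z, threshold=0.0) == []
    v = np.zeros((20, 20))
    v[10, 10] = 5.0
    rois = detect_rois(FluctuationMap(v), threshold=0.1)
    assert len(rois) == 1 and rois[0].center == (10, 10)
    # two peaks 2 px apart, min_separation 3 -> only the brighter kept
    v2 = np.zeros((20, 20))
    v2[5, 5] = 3.0
    v2[5, 7] = 4.0
    rois = detect_rois(FluctuationMap(v2), min_separation=3, threshold=0.1)
    assert [r.center for r in rois] == [(5, 7)]


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_detect_rois_matches_brute_force(seed):
    rng = np.random.default_rng(seed)
    values = rng.random((24, 24))
    values[rng.random((24, 24)) < 0.08] += 3.0
    fmap = FluctuationMap(values)
    got = [r.center for r in detect_rois(fmap, min_separation=3, threshold=1.0)]
    assert got == brute_force_rois(values, 3, 1.0)


def test_extract_trace_constant_movie_is_zero():
    movie = MovieStack(np.full((20, 15, 15), 7.0), 0.1)
    tr = extract_trace(movie, ROI((7, 7)))
    assert len(tr) == 20
    np.testing.assert_allclose(tr.intensities, 0.0, atol=1e-9)
    with pytest.raises(InvalidParameterError):
        extract_trace(movie, ROI((0, 7)))


def test_render_always_bound_molecule_is_static():
    kin = TargetKinetics("t", 1e6, 1e-3)  # effectively always bound
    cfg = SimConfig(
        targets=((kin, 1),), acquisition_time=2.0,
        emission=EmissionModel(noise_sd=1e-6), seed=0,
    )
    ts = simulate_fov(cfg)
    movies, pos = render_movie(ts, (24, 24), cfg.emission, seed=1)
    stack = movies["C1_raw"]
    fmap = fluctuation_map(stack)
    assert fmap.values.max() < 1e-4
    (r, c) = next(iter(pos.values()))
    assert stack.frames[0, r, c] > stack.frames[0].mean()


def test_rendered_blinking_molecule_recovered_within_1px(quiet_emission):
    kin = TargetKinetics("t", 1.0, 1.0)
    cfg = SimConfig(targets=((kin, 1),), acquisition_time=30.0,
                    emission=quiet_emission, seed=2)
    ts = simulate_fov(cfg)
    movies, pos = render_movie(ts, (32, 32), quiet_emission, seed=3)
    fmap = fluctuation_map(movies["C1_raw"])
    rois = detect_rois(fmap, min_separation=3, threshold_quantile=0.99)
    truth = next(iter(pos.values()))
    best = min(
        max(abs(r.center[0] - truth[0]), abs(r.center[1] - truth[1])) for r in rois
    )
    assert best <= 1


def test_detection_fidelity_on_rendered_fovs():
    """>=95% of truth positions found within 1 px, <=5% spurious (10 seeds).

    Bright, frequently blinking puncta (>=5 binding events each, punctum
    SNR well above 3) on a read-noise background; the fluctuation-map
    threshold is set relative to its noise floor (median).
    """
    emission = EmissionModel(mean_bound=5.0, mean_unbound=0.0, noise_sd=0.05)
    kin = TargetKinetics("fast", 0.5, 1.0)
    hits, total, spurious = 0, 0, 0
    for seed in range(10):
        cfg = SimConfig(targets=((kin, 12),), acquisition_time=50.0,
                        emission=emission, seed=seed)
        ts = simulate_fov(cfg)
        movies, pos = render_movie(ts, (64, 64), emission, seed=100 + seed)
        fmap = fluctuation_map(movies["C1_raw"])
        rois = detect_rois(fmap, min_separation=3,
                           threshold=1.5 * float(np.median(fmap.values)))
        centers = [r.center for r in rois]
        matched = set()
        for t_pos in pos.values():
            total += 1
            for i, (r, c) in enumerate(centers):
                if i not in matched and max(abs(r - t_pos[0]), abs(c - t_pos[1])) <= 1:
                    matched.add(i)
                    hits += 1
                    break
        spurious += len(centers) - len(matched)
    assert hits / total >= 0.95
    assert spurious / total <= 0.05


def test_extracted_amplitude_tracks_truth(quiet_emission, miR16):
    """Punctum traces read back ~A when bound and ~0 when unbound."""
    cfg = SimConfig(targets=((miR16, 4),), acquisition_time=40.0,
                    emission=quiet_emission, seed=4)
    ts = simulate_fov(cfg)
    movies, pos = render_movie(ts, (48, 48), quiet_emission, seed=5)
    stack = movies["C1_raw"]
    # 3x3 window captures most but not all of a sigma=1 px Gaussian
    capture = quiet_emission.mean_bound * 0.70
    for truth in ts.truths:
        tr = extract_trace(stack, ROI(truth.position), BackgroundSpec())
        occ = truth.occupancy()
        bound = occ > 0.9
        unbound = occ < 0.1
        if bound.sum() >= 5:
            assert tr.intensities[bound].mean() > capture
        if unbound.sum() >= 5:
            assert abs(tr.intensities[unbound].mean()) < 0.1
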