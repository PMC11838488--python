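"""Cluster training, confidence geometry and molecule assignment."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import chi2

from kinfp.core import (
    ColorChannel,
    DegenerateClusterError,
    InsufficientDataError,
    InvalidParameterError,
)
from kinfp.demux import (
    UNASSIGNED,
    Assignment,
    ClusterModel,
    ClusterSpec,
    assign_molecules,
    fit_gaussian_no_cov,
    train_cluster_model,
    unassigned_fraction,
)

CHI2_95 = chi2.ppf(0.95, 2)  # 5.991


def fps_frame(points, channel="C1"):
    pts = np.asarray(points, dtype=float)
    return pd.DataFrame(
        {
            "molecule_id": [f"m{i}" for i in range(len(pts))],
            "channel": channel,
            "tau_on_med": pts[:, 0],
            "tau_off_med": pts[:, 1],
        }
    )


def two_cluster_model(sep=2.0, sigma=0.1):
    return ClusterModel(
        (
            ClusterSpec("A", ColorChannel.C1, (0.0, 0.0), (sigma, sigma), 100),
            ClusterSpec("B", ColorChannel.C1, (sep, sep), (sigma, sigma), 100),
        ),
        transform="identity",
    )


def test_prune_removes_gross_outlier(rng):
    pts = rng.normal([1.0, 2.0], [0.2, 0.3], size=(1000, 2))
    pts = np.vstack([pts, [1.0 + 10 * 0.2, 2.0]])  # 10-sigma outlier
    mean, sigma, n_kept = fit_gaussian_no_cov(pts)
    assert n_kept <= 1000
    se = 0.2 / np.sqrt(1000)
    assert abs(mean[0] - 1.0) < 3 * se * 2
    assert abs(mean[1] - 2.0) < 3 * (0.3 / np.sqrt(1000)) * 2


def test_prune_is_a_fixed_point(rng):
    pts = rng.normal(0, 1, size=(500, 2))
    mean1, sigma1, n1 = fit_gaussian_no_cov(pts)
    # re-running on the retained set changes nothing: refit with the same
    # points minus whatever was pruned must return identical parameters
    keep = np.all(np.abs(pts - mean1) <= 3 * sigma1, axis=1)
    mean2, sigma2, n2 = fit_gaussian_no_cov(pts[keep])
    np.testing.assert_allclose(mean1, mean2)
    np.testing.assert_allclose(sigma1, sigma2)
    assert n1 == n2 == keep.sum()


def test_degenerate_and_small_inputs_raise():
    with pytest.raises(DegenerateClusterError):
        fit_gaussian_no_cov(np.ones((10, 2)))
    with pytest.raises(InsufficientDataError):
        fit_gaussian_no_cov(np.zeros((3, 2)))


def test_training_is_order_invariant(rng):
    pts_a = 10 ** rng.normal(0.3, 0.1, size=(50, 2))
    pts_b = 10 ** rng.normal(0.9, 0.1, size=(50, 2))
    df = fps_frame(np.vstack([pts_a, pts_b]))
    df["true_label"] = ["A"] * 50 + ["B"] * 50
    shuffled = df.sample(frac=1.0, random_state=7).reset_index(drop=True)
    m1 = train_cluster_model(df)
    m2 = train_cluster_model(shuffled)
    by_name1 = {c.name: c for c in m1.clusters}
    by_name2 = {c.name: c for c in m2.clusters}
    for name in ("A", "B"):
        np.testing.assert_allclose(by_name1[name].mean, by_name2[name].mean)
        np.testing.assert_allclose(by_name1[name].sigma, by_name2[name].sigma)


def test_trained_means_recover_generating_parameters(rng):
    """Two well-separated targets -> fitted means within 3 SE of truth."""
    n = 400
    pts_a = 10 ** rng.normal(np.log10(0.5), 0.05, size=(n, 2))
    pts_b = 10 ** rng.normal(np.log10(5.0), 0.05, size=(n, 2))
    df = fps_frame(np.vstack([pts_a, pts_b]))
    df["true_label"] = ["A"] * n + ["B"] * n
    model = train_cluster_model(df)
    se = 0.05 / np.sqrt(n)
    for c in model.clusters:
        target = np.log10(0.5) if c.name == "A" else np.log10(5.0)
        assert abs(c.mean[0] - target) < 3.5 * se
        assert abs(c.mean[1] - target) < 3.5 * se


def test_point_at_mean_and_3sigma_point():
    model = two_cluster_model(sep=5.0)
    at_mean = fps_frame([[0.0, 0.0]])
    res = assign_molecules(at_mean, model, 0.95, rule="ellipse")
    assert res.loc[0, "label"] == "A"
    assert res.loc[0, "d2_A"] == pytest.approx(0.0)
    # d2 = 9 > 5.991: outside the 95% ellipse -> unassigned under the
    # containment rule; the confidence rule rescues it (posterior ~ 1,
    # still inside the 3-sigma outlier envelope)
    at_3sigma = fps_frame([[0.3, 0.0]])
    res_e = assign_molecules(at_3sigma, model, 0.95, rule="ellipse")
    assert res_e.loc[0, "d2_A"] == pytest.approx(9.0)
    assert res_e.loc[0, "label"] == UNASSIGNED
    res_c = assign_molecules(at_3sigma, model, 0.95, rule="confidence")
    assert res_c.loc[0, "label"] == "A"


def test_undefined_medians_skip_or_unassign():
    model = two_cluster_model()
    df = fps_frame([[0.0, 0.0], [np.nan, 0.0]])
    skipped = assign_molecules(df, model, 0.95)
    assert len(skipped) == 1 and skipped.attrs["n_skipped"] == 1
    kept = assign_molecules(df, model, 0.95, undefined="unassign")
    assert len(kept) == 2 and kept.loc[1, "label"] == UNASSIGNED


def test_channel_restriction():
    model = ClusterModel(
        (
            ClusterSpec("A", ColorChannel.C1, (0.0, 0.0), (0.1, 0.1), 10),
            ClusterSpec("B", ColorChannel.C2, (0.0, 0.0), (0.1, 0.1), 10),
        ),
        transform="identity",
    )
    df = fps_frame([[0.0, 0.0]], channel="C2")
    res = assign_molecules(df, model, 0.95)
    assert res.loc[0, "label"] == "B"


def test_ellipse_assignments_nest_with_confidence(rng):
    model = two_cluster_model(sep=1.0, sigma=0.2)
    pts = rng.normal(0.3, 0.5, size=(300, 2))
    df = fps_frame(pts)
    assigned = {}
    for conf in (0.90, 0.95, 0.99):
        res = assign_molecules(df, model, conf, rule="ellipse")
        assigned[conf] = set(res[res["label"] != UNASSIGNED]["molecule_id"])
    assert assigned[0.90] <= assigned[0.95] <= assigned[0.99]


def test_confidence_rule_is_superset_of_ellipse_rule(rng):
    """Posterior rescue only ever adds assignments to the containment rule."""
    model = two_cluster_model(sep=1.0, sigma=0.35)
    pts = np.vstack([
        rng.normal(0.0, 0.35, size=(200, 2)),
        rng.normal(1.0, 0.35, size=(200, 2)),
    ])
    df = fps_frame(pts)
    for conf in (0.90, 0.95, 0.99):
        by_ellipse = assign_molecules(df, model, conf, rule="ellipse")
        by_conf = assign_molecules(df, model, conf, rule="confidence")
        ell = set(by_ellipse[by_ellipse["label"] != UNASSIGNED]["molecule_id"])
        con = set(by_conf[by_conf["label"] != UNASSIGNED]["molecule_id"])
        assert ell <= con


def test_95pct_ellipse_contains_95pct_of_own_points(rng):
    pts = rng.normal(0.0, 1.0, size=(10_000, 2))
    d2 = (pts**2).sum(axis=1)
    frac = np.mean(d2 <= CHI2_95)
    assert frac == pytest.approx(0.95, abs=0.01)


def test_assignment_matches_brute_force(rng):
    """Labels equal an exhaustive distance computation (<=100 molecules)."""
    model = two_cluster_model(sep=1.5, sigma=0.3)
    pts = rng.normal(0.7, 0.8, size=(100, 2))
    df = fps_frame(pts)
    for rule in ("ellipse", "confidence"):
        res = assign_molecules(df, model, 0.95, rule=rule)
        for i, (x, y) in enumerate(pts):
            d2 = {}
            logp = {}
            for c in model.clusters:
                z = ((x - c.mean[0]) / c.sigma[0], (y - c.mean[1]) / c.sigma[1])
                d2[c.name] = z[0] ** 2 + z[1] ** 2
                logp[c.name] = -0.5 * d2[c.name] - np.log(c.sigma[0] * c.sigma[1])
            inside = {k: v for k, v in d2.items() if v <= CHI2_95}
            if inside:
                expect = min(inside, key=inside.get)
            elif rule == "confidence":
                best = max(logp, key=logp.get)
                p = np.exp(np.array(list(logp.values())) - max(logp.values()))
                post = 1.0 / p.sum()
                spec = {c.name: c for c in model.clusters}[best]
                in3 = (abs(x - spec.mean[0]) <= 3 * spec.sigma[0]
                       and abs(y - spec.mean[1]) <= 3 * spec.sigma[1])
                expect = best if (post >= 0.95 and in3) else UNASSIGNED
            else:
                expect = UNASSIGNED
            assert res.loc[i, "label"] == expect, (rule, i)
            for c in model.clusters:
                assert res.loc[i, f"d2_{c.name}"] == pytest.approx(
                    d2[c.name], rel=1e-9
                )


def test_misassignment_vanishes_with_separation(rng):
    pts = rng.normal(0.0, 0.1, size=(500, 2))
    df = fps_frame(pts)
    model = two_cluster_model(sep=100.0, sigma=0.1)
    res = assign_molecules(df, model, 0.95, rule="confidence")
    assert (res["label"] == "B").sum() == 0


def test_kmeans_cross_check(rng):
    """Nearest-center assignment agrees with k-means prediction at the
    pretrained centers (equal sigmas make Euclidean == scaled distance)."""
    KMeans = pytest.importorskip("sklearn.cluster").KMeans
    model = two_cluster_model(sep=2.0, sigma=0.25)
    pts = np.vstack([
        rng.normal(0.0, 0.25, size=(100, 2)),
        rng.normal(2.0, 0.25, size=(100, 2)),
    ])
    df = fps_frame(pts)
    res = assign_molecules(df, model, 0.9999, rule="confidence")
    centers = np.array([c.mean for c in model.clusters])
    km = KMeans(n_clusters=2, init=centers, n_init=1, max_iter=1).fit(centers)
    pred = km.predict(pts)
    names = np.array([c.name for c in model.clusters])
    agree = (res["label"].to_numpy() == names[pred])
    assigned = res["label"] != UNASSIGNED
    assert np.all(agree[assigned.to_numpy()])


def test_unassigned_fraction_basics():
    assert unassigned_fraction(["A", "B", "A"]) == 0.0
    labels = [UNASSIGNED] * 3 + ["A"] * 97
    assert unassigned_fraction(labels) == pytest.approx(0.03)
    assert unassigned_fraction(
        [Assignment("m", UNASSIGNED, {}, 0.95)]
    ) == 1.0
    with pytest.raises(InvalidParameterError):
        unassigned_fraction([])


def test_model_yaml_roundtrip(tmp_path):
    model = two_cluster_model()
    path = tmp_path / "model.yaml"
    model.save(path)
    loaded = ClusterModel.load(path)
    assert loaded.transform == model.transform
    for a, b in zip(loaded.clusters, model.clusters):
        assert a.name == b.name and a.channel == b.channel
        np.testing.assert_allclose(a.mean, b.mean)
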