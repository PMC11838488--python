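"""Demultiplexing molecules into targets in dwell-time space.

Each target forms a cluster in (tau_on_med, tau_off_med) space -- log10-
transformed by default, since dwell times span decades -- described by an
axis-aligned Gaussian (mean, per-axis sigma) pretrained on single-target
data after iterative 3-sigma outlier pruning.  Color is the discrete third
dimension: clusters only compete for molecules of their own channel.

Two assignment rules are provided:

``rule="ellipse"``
    A molecule belongs to a cluster iff its squared scaled distance
    d^2 = sum_axis ((x - mean) / sigma)^2 is within the chi-square
    (2 dof) quantile of the confidence level (5.991 at 95%); it is
    assigned to the containing cluster of smallest d^2, else unassigned.
    Assignment sets grow (are nested) as the confidence level rises.

``rule="confidence"`` (pipeline default)
    A molecule is assigned when it lies inside some confidence ellipse
    *or* is classified with posterior probability >= the confidence level
    (diagonal-Gaussian mixture, equal priors) while falling within the
    3-sigma per-axis outlier envelope of that cluster.  This rescues the
    ~5% of a cluster's own population that necessarily falls outside its
    fitted 95% ellipse, so unassigned fractions drop toward zero as
    clusters tighten with longer acquisitions, while ambiguous points in
    cluster-overlap regions and 3-sigma outliers stay unassigned.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy.stats import chi2

from .core import (
    ColorChannel,
    DegenerateClusterError,
    InsufficientDataError,
    InvalidParameterError,
)

__all__ = [
    "ClusterSpec",
    "ClusterModel",
    "Assignment",
    "fit_gaussian_no_cov",
    "train_cluster_model",
    "assign_molecules",
    "unassigned_fraction",
    "UNASSIGNED",
]

UNASSIGNED = "unassigned"


@dataclass(frozen=True)
class ClusterSpec:
    """One target's axis-aligned Gaussian in transformed dwell-time space."""

    name: str
    channel: ColorChannel
    mean: tuple[float, float]
    sigma: tuple[float, float]
    n_train: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "channel", ColorChannel(self.channel))
        if any(s <= 0 for s in self.sigma):
            raise DegenerateClusterError(f"cluster {self.name!r} has non-positive sigma")


@dataclass(frozen=True)
class ClusterModel:
    """Pretrained per-target clusters plus the dwell-space transform."""

    clusters: tuple[ClusterSpec, ...]
    transform: str = "log10"

    def __post_init__(self) -> None:
        if self.transform not in ("log10", "identity"):
            raise InvalidParameterError("transform must be 'log10' or 'identity'")
        seen: dict[ColorChannel, list[tuple[float, float]]] = {}
        for c in self.clusters:
            for m in seen.setdefault(c.channel, []):
                if m == c.mean:
                    raise InvalidParameterError(
                        "same-channel clusters must have distinct means"
                    )
            seen[c.channel].append(c.mean)

    def apply_transform(self, xy: np.ndarray) -> np.ndarray:
        xy = np.asarray(xy, dtype=float)
        return np.log10(xy) if self.transform == "log10" else xy

    def to_dict(self) -> dict:
        return {
            "transform": self.transform,
            "clusters": [
                {
                    "name": c.name,
                    "channel": str(c.channel),
                    "mean": [float(v) for v in c.mean],
                    "sigma": [float(v) for v in c.sigma],
                    "n_train": int(c.n_train),
                }
                for c in self.clusters
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ClusterModel":
        return cls(
            tuple(
                ClusterSpec(
                    c["name"],
                    ColorChannel(c["channel"]),
                    tuple(c["mean"]),
                    tuple(c["sigma"]),
                    int(c.get("n_train", 0)),
                )
                for c in d["clusters"]
            ),
            d.get("transform", "log10"),
        )

    def save(self, path) -> None:
        import yaml

        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh)

    @classmethod
    def load(cls, path) -> "ClusterModel":
        import yaml

        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


@dataclass
class Assignment:
    """One molecule's cluster assignment at a given confidence level."""

    molecule_id: str
    label: str
    squared_scaled_distance: dict
    confidence: float


def fit_gaussian_no_cov(
    points: np.ndarray, max_rounds: int = 100
) -> tuple[np.ndarray, np.ndarray, int]:
    """Axis-aligned Gaussian fit with iterative 3-sigma outlier pruning.

    Points lying beyond 3 sigma of the current mean on *any* axis are
    discarded and the fit repeated until no point is discarded.  Returns
    ``(mean, sigma, n_retained)``.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2:
        raise InvalidParameterError("points must be a (n, d) array")
    if len(pts) < 5:
        raise InsufficientDataError("need at least 5 points to fit a cluster")
    for _ in range(max_rounds):
        mean = pts.mean(axis=0)
        sigma = pts.std(axis=0, ddof=1)
        if np.any(sigma <= 0):
            raise DegenerateClusterError("zero variance on a cluster axis")
        keep = np.all(np.abs(pts - mean) <= 3.0 * sigma, axis=1)
        if keep.all():
            return mean, sigma, len(pts)
        pts = pts[keep]
        if len(pts) < 5:
            raise InsufficientDataError("fewer than 5 points left after pruning")
    return mean, sigma, len(pts)


def train_cluster_model(
    labeled_fps: pd.DataFrame,
    transform: str = "log10",
    label_column: str = "true_label",
) -> ClusterModel:
    """Fit one pruned axis-aligned Gaussian per labeled target.

    ``labeled_fps`` needs columns ``tau_on_med``, ``tau_off_med``, the
    label column and (optionally) ``channel``; rows with undefined medians
    are ignored.  Training is invariant to row order.
    """
    if label_column not in labeled_fps.columns:
        raise InvalidParameterError(f"missing label column {label_column!r}")
    clusters = []
    for name in pd.unique(labeled_fps[label_column]):
        sub = labeled_fps[labeled_fps[label_column] == name]
        xy = sub[["tau_on_med", "tau_off_med"]].to_numpy(dtype=float)
        xy = xy[~np.isnan(xy).any(axis=1)]
        if transform == "log10":
            xy = np.log10(xy)
        mean, sigma, n_kept = fit_gaussian_no_cov(xy)
        channel = (
            ColorChannel(sub["channel"].iloc[0])
            if "channel" in sub.columns
            else ColorChannel.C1
        )
        clusters.append(
            ClusterSpec(str(name), channel, tuple(mean), tuple(sigma), n_kept)
        )
    return ClusterModel(tuple(clusters), transform)


def _scaled_d2(X: np.ndarray, cluster: ClusterSpec) -> np.ndarray:
    mean = np.asarray(cluster.mean)
    sigma = np.asarray(cluster.sigma)
    return (((X - mean) / sigma) ** 2).sum(axis=1)


def assign_molecules(
    fps: pd.DataFrame,
    model: ClusterModel,
    confidence: float = 0.95,
    rule: str = "ellipse",
    undefined: str = "skip",
) -> pd.DataFrame:
    """Assign each fingerprint to a same-channel cluster or "unassigned".

    Returns a DataFrame with ``molecule_id``, ``label``, per-cluster
    ``d2_<name>`` columns, ``posterior`` (confidence of the best same-
    channel cluster) and the confidence level used.  Molecules with
    undefined medians are skipped (``undefined="skip"``, with the skipped
    count in ``DataFrame.attrs["n_skipped"]``) or kept as unassigned rows
    (``undefined="unassign"``, used when reporting unassigned fractions of
    a whole simulated population).
    """
    if not (0.0 < confidence < 1.0):
        raise InvalidParameterError("confidence must be in (0, 1)")
    if rule not in ("ellipse", "confidence"):
        raise InvalidParameterError("rule must be 'ellipse' or 'confidence'")
    if undefined not in ("skip", "unassign"):
        raise InvalidParameterError("undefined must be 'skip' or 'unassign'")

    xy = fps[["tau_on_med", "tau_off_med"]].to_numpy(dtype=float)
    defined = ~np.isnan(xy).any(axis=1)
    channels = (
        fps["channel"].astype(str).to_numpy()
        if "channel" in fps.columns
        else np.full(len(fps), str(ColorChannel.C1))
    )
    mol_ids = (
        fps["molecule_id"].to_numpy()
        if "molecule_id" in fps.columns
        else np.arange(len(fps))
    )
    d2_thresh = float(chi2.ppf(confidence, df=2))

    labels = np.full(len(fps), UNASSIGNED, dtype=object)
    d2_cols = {f"d2_{c.name}": np.full(len(fps), np.nan) for c in model.clusters}
    posterior = np.full(len(fps), np.nan)

    X = np.empty_like(xy)
    X[defined] = model.apply_transform(xy[defined])
    for channel in np.unique(channels):
        members = [c for c in model.clusters if str(c.channel) == channel]
        sel = defined & (channels == channel)
        if not sel.any():
            continue
        Xs = X[sel]
        if not members:
            continue
        d2 = np.stack([_scaled_d2(Xs, c) for c in members], axis=0)  # (k, n)
        for c, row in zip(members, d2):
            d2_cols[f"d2_{c.name}"][sel] = row
        log_norm = np.array([np.log(c.sigma[0] * c.sigma[1]) for c in members])
        logp = -0.5 * d2 - log_norm[:, None]
        logp -= logp.max(axis=0, keepdims=True)
        p = np.exp(logp)
        post = p.max(axis=0) / p.sum(axis=0)
        posterior[sel] = post

        inside = d2 <= d2_thresh
        nearest = np.argmin(d2, axis=0)
        best_post = np.argmax(logp, axis=0)
        chosen = np.full(Xs.shape[0], -1)
        any_inside = inside.any(axis=0)
        # containing cluster of smallest d2
        d2_masked = np.where(inside, d2, np.inf)
        chosen[any_inside] = np.argmin(d2_masked, axis=0)[any_inside]
        if rule == "confidence":
            in_3sigma = np.zeros(Xs.shape[0], dtype=bool)
            for k, c in enumerate(members):
                pick = best_post == k
                if pick.any():
                    dev = np.abs(Xs[pick] - np.asarray(c.mean)) / np.asarray(c.sigma)
                    in_3sigma[pick] = np.all(dev <= 3.0, axis=1)
            rescue = (~any_inside) & (post >= confidence) & in_3sigma
            chosen[rescue] = best_post[rescue]
        idx = np.flatnonzero(sel)
        for i, ch in zip(idx, chosen):
            if ch >= 0:
                labels[i] = members[ch].name

    out = pd.DataFrame(
        {
            "molecule_id": mol_ids,
            "label": labels,
            **d2_cols,
            "posterior": posterior,
            "confidence": confidence,
        }
    )
    if undefined == "skip":
        n_skipped = int((~defined).sum())
        out = out[defined].reset_index(drop=True)
        out.attrs["n_skipped"] = n_skipped
    else:
        out.attrs["n_skipped"] = 0
    return out


def unassigned_fraction(
    assignments: Union[pd.DataFrame, Sequence[str], Sequence[Assignment]],
) -> float:
    """Fraction of molecules labeled "unassigned" (also useful as percent*100)."""
    if isinstance(assignments, pd.DataFrame):
        labels = assignments["label"].to_numpy()
    else:
        labels = np.asarray(
            [a.label if isinstance(a, Assignment) else a for a in assignments]
        )
    if labels.size == 0:
        raise InvalidParameterError("unassigned_fraction of an empty assignment list")
    return float(np.mean(labels == UNASSIGNED))
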