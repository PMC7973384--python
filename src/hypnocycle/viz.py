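"""Visualization: hypnodensity graphs, correlation curves, GDV profiles and
MDS projections.

All plot functions are pure with respect to their inputs: they render to the
named output file (format chosen by extension: .png/.svg/.pdf) and return
the path.  MDS projections carry the usual caveat — absolute coordinates
have no meaning beyond scaling relative distances — which is stamped onto
the plots that use them.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import matplotlib

matplotlib.use("Agg", force=False)
import matplotlib.pyplot as plt
import numpy as np
from scipy.spatial.distance import pdist, squareform
from sklearn.manifold import smacof

from .core import STAGE_LABELS, HypnodensitySeries, validate_series
from .correlation import CorrelationCurve, PeriodEstimate
from .gdv import GdvProfile

#: Canonical stage colors: Wake gold, N1-N3 light-to-dark blue, REM red.
STAGE_COLORS = ("#e6b800", "#9ecae1", "#4292c6", "#084594", "#d62728")


@dataclass
class ProjectionResult:
    """Low-dimensional MDS coordinates plus the achieved stress."""

    coords: np.ndarray
    stress: float
    seed: int

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if self.stress < 0:
            raise ValueError("stress must be non-negative")


def mds_project(
    points: np.ndarray,
    out_dim: int = 2,
    seed: int = 0,
    n_init: int = 4,
    max_iter: int = 500,
    eps: float = 1e-9,
) -> ProjectionResult:
    """Metric MDS of a point cloud onto 2 or 3 dimensions.

    Uses SMACOF on Euclidean distances with a fixed random seed, so the
    projection is deterministic for a given (points, seed).  The raw stress
    is reported.  Only relative distances between projected points are
    meaningful.
    """
    points = np.asarray(points, dtype=float)
    if points.ndim != 2 or points.shape[0] < 3:
        raise ValueError("need an N x D matrix with N >= 3")
    if not np.all(np.isfinite(points)):
        raise ValueError("points contain non-finite values")
    if out_dim not in (2, 3):
        raise ValueError("out_dim must be 2 or 3")
    dist = squareform(pdist(points))
    coords, stress = smacof(
        dist,
        metric=True,
        n_components=out_dim,
        n_init=n_init,
        max_iter=max_iter,
        eps=eps,
        random_state=seed,
        normalized_stress=False,
    )
    return ProjectionResult(coords=coords, stress=float(stress), seed=seed)


def _finish(fig, out_path: str | os.PathLike) -> str:
    fig.savefig(out_path, bbox_inches="tight", dpi=150)
    plt.close(fig)
    return str(out_path)


def plot_hypnodensity(
    series: HypnodensitySeries | list[HypnodensitySeries],
    out_path: str | os.PathLike,
) -> str:
    """Stacked-area hypnodensity graph, one panel per channel.

    Stage probabilities stack to 1 at every time point; x-axis in hours
    from record start; panels share the time axis.
    """
    series_list = [series] if isinstance(series, HypnodensitySeries) else list(series)
    if not series_list:
        raise ValueError("no series to plot")
    for s in series_list:
        report = validate_series(s)
        if not report.ok:
            raise ValueError(f"invalid series for channel {s.channel!r}: {report.message}")
    fig, axes = plt.subplots(
        len(series_list), 1, sharex=True,
        figsize=(10, 2.2 * len(series_list)), squeeze=False,
    )
    for ax, s in zip(axes[:, 0], series_list):
        hours = s.times / 3600.0
        ax.stackplot(hours, s.probs.T, labels=STAGE_LABELS, colors=STAGE_COLORS)
        ax.set_ylim(0, 1)
        ax.set_ylabel("probability")
        ax.set_title(f"channel {s.channel}" if s.channel else "hypnodensity", fontsize=10)
    axes[-1, 0].set_xlabel("time (h)")
    axes[0, 0].legend(loc="upper right", ncols=5, fontsize=8)
    return _finish(fig, out_path)


def plot_correlation(
    curves: CorrelationCurve | list[CorrelationCurve] | dict,
    out_path: str | os.PathLike,
    estimate: PeriodEstimate | None = None,
) -> str:
    """Correlation curve(s) with optional detected-maxima markers.

    Accepts a single curve, a list (overlaid in one panel), or the dict of
    a channel-pair summary (rendered as a grid).  Lags are shown in
    minutes; when a period estimate is given its maxima are marked and the
    period annotated.
    """
    if isinstance(curves, dict):
        labels_x = sorted({k[0] for k in curves})
        labels_y = sorted({k[1] for k in curves})
        n = len(labels_x)
        fig, axes = plt.subplots(n, len(labels_y), figsize=(3.2 * len(labels_y), 2.4 * n),
                                 sharex=True, sharey=True, squeeze=False)
        for i, lx in enumerate(labels_x):
            for j, ly in enumerate(labels_y):
                ax = axes[i, j]
                c = curves[(lx, ly)]
                ax.plot(c.lags / 60.0, c.values, lw=1)
                ax.set_title(f"{lx} vs {ly}", fontsize=9)
                if i == n - 1:
                    ax.set_xlabel("lag (min)")
                if j == 0:
                    ax.set_ylabel("r")
        return _finish(fig, out_path)

    curve_list = [curves] if isinstance(curves, CorrelationCurve) else list(curves)
    if not curve_list:
        raise ValueError("no curves to plot")
    fig, ax = plt.subplots(figsize=(8, 4))
    for c in curve_list:
        name = f"{c.channel_x}" if c.kind == "auto" else f"{c.channel_x} x {c.channel_y}"
        ax.plot(c.lags / 60.0, c.values, lw=1.2, label=f"{c.kind} {name}".strip())
    if estimate is not None and estimate.found:
        ax.plot(estimate.maxima_lags / 60.0, estimate.maxima_values, "v", color="k",
                ms=8, label="local maxima")
        ax.annotate(
            f"period ≈ {estimate.period_seconds / 60.0:.0f} min",
            xy=(estimate.maxima_lags[0] / 60.0, estimate.maxima_values[0]),
            xytext=(10, 12), textcoords="offset points",
        )
    ax.set_xlabel("lag (min)")
    ax.set_ylabel("r")
    ax.legend(fontsize=8)
    return _finish(fig, out_path)


def plot_gdv_profile(profile: GdvProfile, out_path: str | os.PathLike) -> str:
    """Layer-wise GDV profile with 0 (non-separable) and −1 (perfect) guides."""
    fig, ax = plt.subplots(figsize=(7, 4))
    x = np.arange(len(profile.layer_names))
    ax.plot(x, profile.gdv_values, "o-", color="#d62728")
    ax.axhline(0.0, color="gray", lw=0.8, ls="--")
    ax.axhline(-1.0, color="gray", lw=0.8, ls=":")
    ax.set_xticks(x, profile.layer_names, rotation=45, ha="right", fontsize=8)
    ax.set_ylabel("GDV")
    ax.set_xlabel("layer")
    return _finish(fig, out_path)


def plot_embedding_projection(
    projection: ProjectionResult,
    labels: np.ndarray,
    out_path: str | os.PathLike,
    label_names: dict | None = None,
) -> str:
    """2-D/3-D scatter of an MDS projection colored by class label."""
    coords = projection.coords
    labels = np.asarray(labels)
    if labels.shape[0] != coords.shape[0]:
        raise ValueError("labels length must equal number of projected points")
    is3d = coords.shape[1] == 3
    fig = plt.figure(figsize=(6, 5.5))
    ax = fig.add_subplot(111, projection="3d" if is3d else None)
    for k, cls in enumerate(np.unique(labels)):
        m = labels == cls
        name = (label_names or {}).get(cls, str(cls))
        color = STAGE_COLORS[k % len(STAGE_COLORS)]
        if is3d:
            ax.scatter(coords[m, 0], coords[m, 1], coords[m, 2], s=8, label=name, color=color)
        else:
            ax.scatter(coords[m, 0], coords[m, 1], s=8, label=name, color=color)
    ax.legend(fontsize=8)
    ax.set_title(f"MDS projection (stress {projection.stress:.3g})", fontsize=10)
    fig.text(
        0.5, 0.005,
        "absolute MDS coordinates carry no meaning beyond relative distances",
        ha="center", fontsize=7, style="italic",
    )
    return _finish(fig, out_path)
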