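"""Plotting helpers: importance bars, H-vs-null displays, PD plots.

All functions return the matplotlib Axes (or Figure for multi-panel
plots) so callers can adjust or save them.  The H display draws, per
subset, a box over the 25th-75th null percentiles, whiskers over the
5th-95th, tick marks for null draws outside them, and a filled dot for
the observed value — a simplified box-percentile rendering.
"""

from __future__ import annotations

import numpy as np

import matplotlib

matplotlib.use("Agg", force=False)
import matplotlib.pyplot as plt  # noqa: E402

__all__ = [
    "plot_importance",
    "plot_h_assessments",
    "plot_pd_1d",
    "plot_pd_2d",
    "plot_pd_conditioned",
]


def plot_importance(importance, top: int = 10, ax=None):
    imp = importance.head(top)[::-1]
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 0.4 * len(imp) + 1))
    ax.barh(np.arange(len(imp)), imp.to_numpy(), color="0.4")
    ax.set_yticks(np.arange(len(imp)), imp.index)
    ax.set_xlabel("relative importance (max = 100)")
    return ax


def plot_h_assessments(assessments, ax=None, xlim=None, common_range: bool = False):
    """Observed H (dots) against the null distributions (boxes)."""
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 0.45 * len(assessments) + 1))
    hi = 0.0
    for pos, a in enumerate(assessments):
        null = np.asarray(a.null_samples, dtype=float)
        p5, p25, p75, p95 = np.percentile(null, [5, 25, 75, 95])
        ax.add_patch(
            plt.Rectangle((p25, pos - 0.2), p75 - p25, 0.4,
                          facecolor="0.85", edgecolor="0.3")
        )
        ax.plot([p5, p95], [pos, pos], color="0.3", lw=1)
        outside = null[(null < p5) | (null > p95)]
        ax.plot(outside, np.full(outside.shape, pos), "|", color="0.3", ms=8)
        ax.plot([a.h_observed], [pos], "o", color="black", ms=5)
        hi = max(hi, a.h_observed, p95, null.max(initial=0.0))
    ax.set_yticks(
        np.arange(len(assessments)), [" * ".join(a.subset) for a in assessments]
    )
    ax.set_xlabel("H")
    if xlim is not None:
        ax.set_xlim(*xlim)
    elif common_range:
        ax.set_xlim(0, max(hi * 1.05, 1e-3))
    ax.set_ylim(-0.5, len(assessments) - 0.5)
    return ax


def plot_pd_1d(pdf, ax=None, by=None, labels=("0", "1")):
    """Line plot of a 1-D PD, optionally split by a binary second column.

    With ``by`` (index of the conditioning column in ``pdf.points``),
    one line per level is drawn — e.g. sex-conditional BPA curves.
    """
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 3.5))
    pts = pdf.points
    if by is None:
        order = np.argsort(pts[:, 0])
        ax.plot(pts[order, 0], pdf.values[order], color="black")
    else:
        free = 1 - by
        for lev, style, lab in zip((0.0, 1.0), ("-", "--"), labels):
            mask = pts[:, by] == lev
            order = np.argsort(pts[mask, free])
            ax.plot(pts[mask, free][order], pdf.values[mask][order],
                    style, color="black", label=lab)
        ax.legend(title=pdf.subset[by])
    ax.set_xlabel(pdf.subset[0 if by is None else 1 - by])
    ax.set_ylabel("partial dependence")
    return ax


def plot_pd_2d(pdf, ax=None, levels: int = 20):
    """Level plot of a 2-D PD evaluated on a regular grid."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    x, yv = pdf.points[:, 0], pdf.points[:, 1]
    xs, ys = np.unique(x), np.unique(yv)
    z = pdf.values.reshape(len(xs), len(ys))
    m = ax.contourf(xs, ys, z.T, levels=levels, cmap="viridis")
    plt.colorbar(m, ax=ax, label="partial dependence")
    ax.set_xlabel(pdf.subset[0])
    ax.set_ylabel(pdf.subset[1])
    return ax


def plot_pd_conditioned(results, subset, n_grid: int = 20, n_panels: int = 3):
    """Four-variable PD as a panel grid (shingle-style conditioning).

    The first two subset variables span each panel's axes; the last two
    are conditioned on quantile-bin midpoints, panels ordered left-right
    and bottom-top by increasing level.
    """
    if len(subset) != 4:
        raise ValueError("conditioned PD plot needs exactly four variables")
    from .pd import percentile_grid

    X = results.model.X
    ax1 = percentile_grid(X[subset[0]], n_points=n_grid)
    ax2 = percentile_grid(X[subset[1]], n_points=n_grid)
    qs = np.linspace(10, 90, n_panels)
    lev3 = np.percentile(X[subset[2]], qs)
    lev4 = np.percentile(X[subset[3]], qs)
    g1, g2 = np.meshgrid(ax1, ax2, indexing="ij")

    fig, axes = plt.subplots(
        n_panels, n_panels, figsize=(3 * n_panels, 2.6 * n_panels),
        sharex=True, sharey=True,
    )
    values = []
    for i3, v3 in enumerate(lev3):
        for i4, v4 in enumerate(lev4):
            pts = np.column_stack(
                [g1.ravel(), g2.ravel(),
                 np.full(g1.size, v3), np.full(g1.size, v4)]
            )
            pdf = results.partial_dependence(list(subset), points=pts)
            values.append((i3, i4, pdf.uncentered.reshape(n_grid, n_grid)))
    vmin = min(v[2].min() for v in values)
    vmax = max(v[2].max() for v in values)
    for i3, i4, z in values:
        ax = axes[n_panels - 1 - i4, i3]
        m = ax.pcolormesh(ax1, ax2, z.T, vmin=vmin, vmax=vmax, cmap="viridis")
    fig.colorbar(m, ax=axes, label="partial dependence")
    fig.supxlabel(f"{subset[0]} (panels left-right: {subset[2]} increasing)")
    fig.supylabel(f"{subset[1]} (panels bottom-top: {subset[3]} increasing)")
    return fig
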