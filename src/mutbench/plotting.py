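"""Static diagnostic plots (matplotlib, Agg-safe); each function returns
the Figure so callers can save or embed it."""

from __future__ import annotations

import numpy as np
import pandas as pd

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

_STATUS_COLORS = {"TP": "tab:blue", "FP": "tab:green", "FN": "tab:red"}


def rainfall_plot(records: pd.DataFrame, title: str = "Rainfall"):
    """Log-scale inter-mutation distance along the genome, coloured by
    TP/FP/FN status."""
    fig, ax = plt.subplots(figsize=(10, 3.5))
    offset = 0
    ticks, labels = [], []
    for chrom, grp in records.groupby("chrom", sort=True):
        for status, sub in grp.groupby("status"):
            ax.scatter(sub["pos"] + offset, np.maximum(sub["distance"], 1),
                       s=6, c=_STATUS_COLORS.get(status, "grey"), label=None)
        span = grp["pos"].max() + 1
        ticks.append(offset + span / 2)
        labels.append(str(chrom))
        offset += span
    ax.set_yscale("log")
    ax.set_xticks(ticks, labels)
    ax.set_ylabel("distance to previous mutation (bp)")
    ax.set_title(title)
    for status, color in _STATUS_COLORS.items():
        ax.scatter([], [], c=color, s=6, label=status)
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    return fig


def saturation_plot(points: pd.DataFrame, fit=None, coverages=None):
    """Observed counts vs coverage per contamination level, with fitted
    curves when a SaturationFit is supplied."""
    fig, ax = plt.subplots(figsize=(5, 4))
    for f, grp in points.groupby("contamination"):
        ax.plot(grp["coverage"], grp["count"], "o-", label=f"contamination {f:g}")
        if fit is not None:
            cs = np.linspace(1, max(coverages or grp["coverage"]), 100)
            ax.plot(cs, fit.predict(cs, f), "--", color=ax.lines[-1].get_color())
    ax.set_xlabel("mean coverage (x)")
    ax.set_ylabel("mutations detected")
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    return fig


def gc_scatter(windows: pd.DataFrame):
    """Normalised coverage against window GC fraction."""
    fig, ax = plt.subplots(figsize=(5, 4))
    inc = windows[~windows["excluded"]]
    ax.scatter(inc["gc"], inc["normalized"], s=4, alpha=0.3)
    ax.axhline(1.0, color="grey", lw=0.5)
    ax.set_xlabel("window GC fraction")
    ax.set_ylabel("normalised coverage")
    fig.tight_layout()
    return fig


def enrichment_heatmap(em) -> "matplotlib.figure.Figure":
    """Clustered submissions x features heatmap of an EnrichmentMatrix."""
    mat = em.matrix.loc[em.row_order, em.col_order]
    fig, ax = plt.subplots(figsize=(0.45 * mat.shape[1] + 2, 0.3 * mat.shape[0] + 2))
    vmax = np.abs(mat.to_numpy()).max() or 1.0
    im = ax.imshow(mat.to_numpy(), cmap="RdBu_r", vmin=-vmax, vmax=vmax,
                   aspect="auto")
    ax.set_xticks(range(mat.shape[1]), mat.columns, rotation=90, fontsize=7)
    ax.set_yticks(range(mat.shape[0]), mat.index, fontsize=7)
    fig.colorbar(im, ax=ax, label=f"{em.mode} enrichment")
    fig.tight_layout()
    return fig


def cumulative_coverage_plot(curves: dict[str, pd.DataFrame]):
    """Cumulative coverage curves for one or more depth tracks."""
    fig, ax = plt.subplots(figsize=(5, 4))
    for name, curve in curves.items():
        ax.step(curve["threshold"], 100 * curve["fraction"], where="post", label=name)
    ax.set_xlabel("minimum coverage (x)")
    ax.set_ylabel("% of genome covered")
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    return fig
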