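"""Human-readable report: figures assembled from a completed run directory.

Reads the stage TSVs written by :func:`fluvnet.pipeline.run` and emits
PNG panels mirroring the standard presentation of a network
biodiversity survey: downstream trend scatters with percentile curves,
paired confluence plots, and distance-decay scatters with per-group
similarity densities.  Missing stage files are flagged and skipped.
"""

from __future__ import annotations

import logging
import os

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .alpha import INDEX_NAMES
from .beta import INDICES

__all__ = ["report"]

log = logging.getLogger(__name__)

_GROUP_COLORS = {"HH": "tab:blue", "MM": "tab:green"}


def _maybe(path: str) -> pd.DataFrame | None:
    if not os.path.exists(path):
        log.warning("report: missing %s; section skipped", os.path.basename(path))
        return None
    return pd.read_csv(path, sep="\t")


def report(run_dir: str, figdir: str | None = None) -> list[str]:
    """Render figures for a run directory; returns the files written."""
    figdir = figdir or os.path.join(run_dir, "figures")
    os.makedirs(figdir, exist_ok=True)
    written: list[str] = []
    skipped: list[str] = []

    alpha = _maybe(os.path.join(run_dir, "alpha_diversity.tsv"))
    fractions = _maybe(os.path.join(run_dir, "core_satellite_fractions.tsv"))
    curves = _maybe(os.path.join(run_dir, "percentile_curves.tsv"))
    if alpha is not None and fractions is not None and curves is not None:
        merged = alpha.merge(
            fractions[["sample_id" if "sample_id" in fractions else "site_id", "log10_area"]]
            .rename(columns={"site_id": "sample_id"}),
            on="sample_id",
            how="inner",
        ) if "sample_id" in fractions.columns or "site_id" in fractions.columns else None
        fig, axes = plt.subplots(1, len(INDEX_NAMES), figsize=(4 * len(INDEX_NAMES), 3.2))
        for ax, index in zip(np.atleast_1d(axes), INDEX_NAMES):
            if merged is not None:
                ax.scatter(merged["log10_area"], merged[index], s=12, alpha=0.6, c="k")
            sub = curves[curves["response"] == index]
            for col in ("p5", "p25", "p75", "p95"):
                if col in sub:
                    ax.plot(sub["log10_area"], sub[col], color="grey", lw=0.8)
            if "mu" in sub:
                ax.plot(sub["log10_area"], sub["mu"], color="black", lw=1.5)
            ax.set_xlabel("log10 catchment area (km²)")
            ax.set_title(index)
        fig.tight_layout()
        path = os.path.join(figdir, "trends.png")
        fig.savefig(path, dpi=120)
        plt.close(fig)
        written.append(path)
    else:
        skipped.append("trends")

    contrasts = _maybe(os.path.join(run_dir, "confluence_contrasts.tsv"))
    if contrasts is not None:
        metrics = [m for m in INDEX_NAMES if m in set(contrasts["metric"])]
        fig, axes = plt.subplots(1, max(len(metrics), 1), figsize=(3 * max(len(metrics), 1), 3.2))
        for ax, metric in zip(np.atleast_1d(axes), metrics):
            sub = contrasts[contrasts["metric"] == metric]
            ax.boxplot(
                [sub["upstream_mean"].dropna(), sub["downstream"].dropna()],
                tick_labels=["tributaries", "recipient"],
            )
            ax.set_title(metric)
        fig.tight_layout()
        path = os.path.join(figdir, "confluences.png")
        fig.savefig(path, dpi=120)
        plt.close(fig)
        written.append(path)
    else:
        skipped.append("confluences")

    pairs = _maybe(os.path.join(run_dir, "pair_table.tsv"))
    dens = _maybe(os.path.join(run_dir, "similarity_density.tsv"))
    if pairs is not None:
        fig, axes = plt.subplots(len(INDICES), 2, figsize=(9, 3 * len(INDICES)))
        for row, index in enumerate(INDICES):
            ax = axes[row, 0]
            for grp, color in _GROUP_COLORS.items():
                sub = pairs[pairs["group"] == grp]
                ax.scatter(sub["d_hydro_m"] / 1000, sub[index], s=6, alpha=0.4, c=color, label=grp)
            ax.set_xlabel("hydrologic distance (km)")
            ax.set_ylabel(index)
            ax.legend(frameon=False, fontsize=8)
            ax = axes[row, 1]
            if dens is not None:
                for grp, color in _GROUP_COLORS.items():
                    sub = dens[(dens["index"] == index) & (dens["group"] == grp)]
                    ax.plot(sub["similarity"], sub["density"], c=color, label=grp)
            ax.set_xlabel(index)
            ax.set_ylabel("density")
        fig.tight_layout()
        path = os.path.join(figdir, "distance_decay.png")
        fig.savefig(path, dpi=120)
        plt.close(fig)
        written.append(path)
    else:
        skipped.append("distance_decay")

    if skipped:
        with open(os.path.join(figdir, "REPORT_NOTES.txt"), "w") as fh:
            fh.write("sections skipped (missing stage outputs): " + ", ".join(skipped) + "\n")
    return written
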