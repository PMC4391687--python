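"""Scatter-plot exports of dosage and CGH results for reviewer-style views.

Both plots follow the convention of the review software they emulate: all
genes side by side on the x-axis, regions in 5'->3' genomic order, one
point per region (dosage view) or per probe (CGH view), with the wild-type
level and call thresholds drawn as horizontal guides.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

from . import cgh as cgh_mod
from . import dosage as dosage_mod
from .model import PanelDefinition


def plot_dosage_scatter(
    dosages: pd.DataFrame,
    panel: PanelDefinition,
    sample_id: str,
    out_path: str | Path,
) -> None:
    """One sample's region dosages vs region index (linear scale, WT at 2)."""
    data = dosage_mod.scatter_data(dosages, panel, sample_id)
    fig, ax = plt.subplots(figsize=(8, 3))
    for gene, sub in data.groupby("gene_name", sort=False):
        ax.scatter(sub["region_index"], sub["dosage"], s=18, label=gene)
    ax.axhline(2.0, color="grey", lw=0.8)
    ax.axhline(dosage_mod.DEL_THRESHOLD, color="red", lw=0.6, ls="--")
    ax.axhline(dosage_mod.DUP_THRESHOLD, color="red", lw=0.6, ls="--")
    ax.set_xlabel("region (genes 5'->3')")
    ax.set_ylabel("dosage (copies)")
    ax.set_title(f"amplicon dosage — {sample_id}")
    ax.set_ylim(0, 4)
    ax.legend(fontsize=6, ncol=6, frameon=False)
    fig.tight_layout()
    fig.savefig(out_path, dpi=120)
    plt.close(fig)


def plot_cgh_summary(
    normalized: pd.DataFrame,
    panel: PanelDefinition,
    sample_id: str,
    out_path: str | Path,
    zoom_gene: str | None = None,
) -> None:
    """Summary view (all genes) plus an optional zoom panel on one gene,
    on the log2 scale with wild type at 0."""
    df = normalized[normalized["sample_id"] == sample_id]
    order: list[tuple[str, str]] = []
    for contig in panel.contigs:
        for region in panel.regions_on(contig):
            order.append((region.gene_name, region.region_label))
    rank = {key: i for i, key in enumerate(order)}
    df = df.assign(
        x=[rank.get((g, r), -1) for g, r in zip(df["gene_name"],
                                                df["region_label"])]
    )
    n_rows = 2 if zoom_gene else 1
    fig, axes = plt.subplots(n_rows, 1, figsize=(8, 3 * n_rows), squeeze=False)
    ax = axes[0][0]
    for gene, sub in df.groupby("gene_name", sort=False):
        ax.scatter(sub["x"], sub["normalized_log2"], s=6, label=gene)
    ax.axhline(0.0, color="grey", lw=0.8)
    ax.axhline(cgh_mod.DEL_THRESHOLD, color="red", lw=0.6, ls="--")
    ax.axhline(cgh_mod.DUP_THRESHOLD, color="red", lw=0.6, ls="--")
    ax.set_ylabel("normalized log2 ratio")
    ax.set_title(f"CGH summary — {sample_id}")
    ax.legend(fontsize=6, ncol=6, frameon=False)
    if zoom_gene:
        axz = axes[1][0]
        sub = df[df["gene_name"] == zoom_gene]
        axz.scatter(sub["position"], sub["normalized_log2"], s=10)
        axz.axhline(0.0, color="grey", lw=0.8)
        axz.set_xlabel(f"{zoom_gene} position (bp)")
        axz.set_ylabel("normalized log2 ratio")
        axz.set_title(f"zoom — {zoom_gene}")
    fig.tight_layout()
    fig.savefig(out_path, dpi=120)
    plt.close(fig)
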