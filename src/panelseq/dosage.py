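"""Large-rearrangement detection from amplicon read-count dosage.

The chain works on a samples x amplicons count matrix for one batch
(typically 96 samples) and relies on the batch itself as the reference
population:

1. ``normalize_sample``  — each amplicon count divided by the sample's mean
   count (removes per-sample library size).
2. ``normalize_batch``   — each ratio divided by the amplicon's batch median
   (removes per-amplicon PCR efficiency; the median is robust to a mutant
   sample among ~96).
3. ``summarize_region``  — mean of adjusted ratios over the amplicons
   overlapping each region of interest.
4. ``region_dosage``     — rescaled to copy-number units so diploid wild
   type sits at 2.0, again via the batch median.

Deletions/duplications are called where dosage crosses the midpoints
between integer copy states (1.5 / 2.5); single-allele amplification of an
individual amplicon (PCR allele dropout) is flagged from the adjusted
ratios against the batch standard deviation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import PanelDefinition, PanelRegion

MIN_BATCH_SIZE = 8
DEL_THRESHOLD = 1.5
DUP_THRESHOLD = 2.5
SD_FLOOR = 1e-6


@dataclass(frozen=True)
class LRCall:
    sample_id: str
    gene_name: str
    contig: str
    region_labels: tuple[str, ...]  # contiguous regions, 5'->3'
    type: str  # "deletion" | "duplication"
    mean_dosage: float
    region_dosages: tuple[float, ...]


@dataclass(frozen=True)
class DropoutFlag:
    sample_id: str
    amplicon_id: str
    adjusted_ratio: float
    z_score: float


def failed_samples(matrix: pd.DataFrame) -> list[str]:
    """Samples with an all-zero row: no result, excluded downstream."""
    return list(matrix.index[(matrix.sum(axis=1) == 0)])


def normalize_sample(matrix: pd.DataFrame) -> pd.DataFrame:
    """Divide each count by its sample's mean count over amplicons.

    All-zero samples (failed libraries) are dropped from the result; use
    :func:`failed_samples` to report them as "No Result".
    """
    if (matrix.values < 0).any():
        raise ValueError("count matrix contains negative values")
    keep = matrix.loc[matrix.sum(axis=1) > 0]
    return keep.div(keep.mean(axis=1), axis=0)


def normalize_batch(ratios: pd.DataFrame) -> pd.DataFrame:
    """Divide each ratio by the amplicon's median across the batch.

    Amplicons whose batch median is zero cannot be normalized and are
    masked (dropped, reported via the ``masked_amplicons`` attribute of the
    returned frame's ``attrs``).
    """
    if len(ratios) < MIN_BATCH_SIZE:
        raise ValueError(
            f"batch normalization needs >= {MIN_BATCH_SIZE} non-failed samples, "
            f"got {len(ratios)}"
        )
    med = ratios.median(axis=0)
    masked = list(med.index[med == 0])
    kept = ratios.drop(columns=masked)
    out = kept.div(med.drop(masked), axis=1)
    out.attrs["masked_amplicons"] = masked
    return out


def summarize_region(
    adjusted: pd.DataFrame, panel: PanelDefinition, tested_only: bool = True
) -> pd.DataFrame:
    """Mean adjusted ratio over each region's overlapping amplicons.

    Returns a samples x regions frame (columns are ``gene/region`` labels in
    panel order).  Regions with every overlapping amplicon masked become
    all-NaN columns (untestable for this batch).  Regions not tested by the
    LR assay are skipped when ``tested_only``.
    """
    cols: dict[str, pd.Series] = {}
    for region in panel.regions:
        if tested_only and not region.tested_by_lr:
            continue
        amps = [a.amplicon_id for a in panel.region_to_amplicons[region.key]
                if a.amplicon_id in adjusted.columns]
        label = f"{region.gene_name}/{region.region_label}"
        if not amps:
            cols[label] = pd.Series(np.nan, index=adjusted.index)
        else:
            cols[label] = adjusted[amps].mean(axis=1)
    return pd.DataFrame(cols, index=adjusted.index)


def region_dosage(summaries: pd.DataFrame) -> pd.DataFrame:
    """Copy-number dosage: 2 x summary / batch median of the summary.

    Also attaches the per-region batch SD in ``attrs['dispersion']``.
    """
    if len(summaries) < MIN_BATCH_SIZE:
        raise ValueError(f"dosage needs >= {MIN_BATCH_SIZE} samples")
    med = summaries.median(axis=0)
    dosages = 2.0 * summaries.div(med, axis=1)
    dosages.attrs["dispersion"] = summaries.std(axis=0, ddof=1)
    return dosages


def dosage_chain(
    matrix: pd.DataFrame, panel: PanelDefinition
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Full normalization chain: counts -> (adjusted ratios, region dosages)."""
    adjusted = normalize_batch(normalize_sample(matrix))
    dosages = region_dosage(summarize_region(adjusted, panel))
    return adjusted, dosages


def dosage_long_table(dosages: pd.DataFrame, panel: PanelDefinition) -> pd.DataFrame:
    """Flatten a dosage frame to the on-disk long format (one row per cell)."""
    dispersion = dosages.attrs.get("dispersion", pd.Series(dtype=float))
    region_by_label = {
        f"{r.gene_name}/{r.region_label}": r for r in panel.regions
    }
    rows = []
    for label in dosages.columns:
        r = region_by_label[label]
        n_amp = len(panel.region_to_amplicons[r.key])
        disp = float(dispersion.get(label, np.nan))
        for sample_id in dosages.index:
            rows.append({
                "sample_id": sample_id, "gene_name": r.gene_name,
                "region_label": r.region_label, "contig": r.contig,
                "dosage": dosages.at[sample_id, label],
                "n_amplicons": n_amp, "dispersion": disp,
            })
    return pd.DataFrame(rows)


def _ordered_tested_regions(panel: PanelDefinition) -> list[PanelRegion]:
    out: list[PanelRegion] = []
    for contig in panel.contigs:
        out.extend(r for r in panel.regions_on(contig) if r.tested_by_lr)
    return out


def call_lr(
    dosages: pd.DataFrame,
    panel: PanelDefinition,
    del_threshold: float = DEL_THRESHOLD,
    dup_threshold: float = DUP_THRESHOLD,
) -> list[LRCall]:
    """Call deletions/duplications as maximal runs of adjacent aberrant regions.

    Adjacency follows genomic order (5'->3') within a contig; a run may span
    several regions (contiguous multi-exon events) or a single region.
    """
    regions = _ordered_tested_regions(panel)
    calls: list[LRCall] = []
    for sample_id in dosages.index:
        run: list[tuple[PanelRegion, float]] = []
        run_type: str | None = None

        def flush() -> None:
            nonlocal run, run_type
            if run and run_type:
                vals = tuple(v for _, v in run)
                calls.append(LRCall(
                    sample_id=str(sample_id),
                    gene_name=run[0][0].gene_name,
                    contig=run[0][0].contig,
                    region_labels=tuple(r.region_label for r, _ in run),
                    type=run_type,
                    mean_dosage=float(np.mean(vals)),
                    region_dosages=vals,
                ))
            run, run_type = [], None

        prev_contig: str | None = None
        for region in regions:
            label = f"{region.gene_name}/{region.region_label}"
            if label not in dosages.columns:
                flush()
                continue
            d = dosages.at[sample_id, label]
            if region.contig != prev_contig:
                flush()
            prev_contig = region.contig
            if pd.isna(d):
                flush()
                continue
            if d < del_threshold:
                this = "deletion"
            elif d > dup_threshold:
                this = "duplication"
            else:
                this = None
            if this != run_type:
                flush()
            if this:
                run_type = this
                run.append((region, float(d)))
        flush()
    return calls


def flag_dropout(
    adjusted: pd.DataFrame,
    panel: PanelDefinition,
    lr_calls: list[LRCall] | None = None,
    z_threshold: float = 4.0,
    target: float = 0.5,
    tolerance: float = 0.15,
) -> list[DropoutFlag]:
    """Flag amplicons that appear amplified from a single allele.

    A cell is flagged when its adjusted ratio sits within ``tolerance`` of
    the single-allele level (``target``, i.e. one copy out of two) AND lies
    ``z_threshold`` batch standard deviations from the amplicon's batch
    mean, AND the amplicon's region is not already part of an LR call for
    that sample (whole-region events are reported as LR, not as dropout).
    A floor of 1e-6 is applied to the batch SD so noise-free synthetic
    batches remain well-defined.
    """
    mean = adjusted.mean(axis=0)
    sd = adjusted.std(axis=0, ddof=1).clip(lower=SD_FLOOR)
    lr_regions: set[tuple[str, str, str]] = set()
    for c in lr_calls or []:
        for label in c.region_labels:
            lr_regions.add((c.sample_id, c.gene_name, label))
    flags: list[DropoutFlag] = []
    for amp_id in adjusted.columns:
        regions = panel.amplicon_to_regions.get(amp_id, [])
        for sample_id in adjusted.index:
            ratio = float(adjusted.at[sample_id, amp_id])
            if abs(ratio - target) > tolerance:
                continue
            z = abs(ratio - mean[amp_id]) / sd[amp_id]
            if z < z_threshold:
                continue
            if any((str(sample_id), r.gene_name, r.region_label) in lr_regions
                   for r in regions):
                continue
            flags.append(DropoutFlag(
                sample_id=str(sample_id), amplicon_id=amp_id,
                adjusted_ratio=ratio, z_score=float(z),
            ))
    return flags


def scatter_data(dosages: pd.DataFrame, panel: PanelDefinition,
                 sample_id: str) -> pd.DataFrame:
    """Per-sample dosage vs region index (genes 5'->3'), for scatter plots."""
    rows = []
    for i, region in enumerate(_ordered_tested_regions(panel)):
        label = f"{region.gene_name}/{region.region_label}"
        if label in dosages.columns:
            rows.append({
                "region_index": i, "gene_name": region.gene_name,
                "region_label": region.region_label,
                "dosage": dosages.at[sample_id, label],
            })
    return pd.DataFrame(rows)
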