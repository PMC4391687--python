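"""End-to-end orchestration: sequencing, LR dosage, CGH, and validation runs.

These functions are the library-level equivalents of the CLI subcommands;
each takes in-memory objects and returns a small result dataclass, so the
whole pipeline is scriptable without touching the filesystem.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import pandas as pd

from . import calling, cgh, dosage, stats
from .calling import CoverageFlag, VariantCall
from .model import PanelDefinition, ReferenceSet, SampleSheet
from .reads import (
    PrimerSet,
    ReferenceIndex,
    Pileup,
    TrimmedRead,
    demultiplex,
    revcomp,
    trim_read,
)


@dataclass
class SeqRunResult:
    calls: list[VariantCall]
    coverage_flags: list[CoverageFlag]
    counters: dict[str, int]
    amplicon_counts: pd.DataFrame  # samples x amplicons (from primer hits, R1)
    pileup: Pileup
    mean_depth: dict[str, float] = field(default_factory=dict)


def run_seq_batch(
    r1: Iterable[tuple[str, str, str]],
    r2: Iterable[tuple[str, str, str]],
    sheet: SampleSheet,
    panel: PanelDefinition,
    references: ReferenceSet,
    q_threshold: int = 30,
    min_depth: int = calling.DEFAULT_MIN_DEPTH,
    batch_id: str | None = None,
) -> SeqRunResult:
    """Demultiplex -> trim -> assign -> pileup -> call for one batch.

    R2 reads are reverse-complemented after trimming so all alignment runs
    in reference orientation; their pileup contributions are recorded on
    the reverse strand.  Read-conservation counters are kept throughout:
    routed + unassigned == input, assigned + discarded + unmapped == routed.
    """
    index = ReferenceIndex(references)
    primers = PrimerSet.from_panel(panel)
    counters = {
        "total_reads": 0, "routed": 0, "unassigned": 0,
        "assigned": 0, "discarded_pseudogene": 0, "unmapped": 0,
        "ignored_outside_panel": 0,
    }
    pileup = Pileup(references)
    spans: dict[str, list[tuple[int, int]]] = {}
    for region in panel.regions:
        spans.setdefault(region.contig, []).append(region.span)
    counts: dict[tuple[str, str], int] = {}

    for mate, reads in (("+", r1), ("-", r2)):
        demux = demultiplex(reads, sheet, batch_id)
        counters["total_reads"] += demux.total
        counters["unassigned"] += demux.unassigned
        for sample_id, sample_reads in demux.by_sample.items():
            for read in sample_reads:
                counters["routed"] += 1
                tr = trim_read(read, sample_id=sample_id,
                               q_threshold=q_threshold, primers=primers)
                if mate == "+" and tr.amplicon_hint and tr.primer_direction == "fwd":
                    counts[(sample_id, tr.amplicon_hint)] = counts.get(
                        (sample_id, tr.amplicon_hint), 0) + 1
                if mate == "-":
                    tr = TrimmedRead(
                        read_id=tr.read_id, sample_id=sample_id,
                        sequence=revcomp(tr.sequence),
                        qualities=tr.qualities[::-1],
                        primer_removed=tr.primer_removed,
                        bases_trimmed=tr.bases_trimmed,
                        amplicon_hint=tr.amplicon_hint,
                        primer_direction=tr.primer_direction,
                    )
                a = index.assign(tr, "+")
                a.strand = mate
                if a.status == "assigned":
                    counters["assigned"] += 1
                    interval = a.aligned_interval
                    ok = interval is not None and any(
                        interval[0] < hi and lo < interval[1]
                        for lo, hi in spans.get(a.best_gene, ())
                    )
                    if not ok:  # assigned but off-panel: counted, not piled
                        counters["ignored_outside_panel"] += 1
                        continue
                    pileup.add(a)
                elif a.status == "discarded_pseudogene":
                    counters["discarded_pseudogene"] += 1
                else:
                    counters["unmapped"] += 1

    calls, flags = calling.call_variants(pileup, panel, min_depth=min_depth)

    samples = sorted({e.sample_id for e in sheet.entries
                      if batch_id is None or e.batch_id == batch_id})
    amp_ids = [a.amplicon_id for a in panel.amplicons]
    count_df = pd.DataFrame(0, index=pd.Index(samples, name="sample_id"),
                            columns=amp_ids)
    for (s, a_id), n in counts.items():
        if a_id in count_df.columns:
            count_df.at[s, a_id] = n

    mean_depth: dict[str, float] = {}
    for s in samples:
        depths = []
        for contig, pos in panel.iter_positions():
            f, r = pileup.depth(s, contig, pos)
            depths.append(f + r)
        mean_depth[s] = float(sum(depths) / len(depths)) if depths else 0.0

    return SeqRunResult(calls=calls, coverage_flags=flags, counters=counters,
                        amplicon_counts=count_df, pileup=pileup,
                        mean_depth=mean_depth)


@dataclass
class LRRunResult:
    dosages: pd.DataFrame  # samples x regions, copy-number scale
    dosage_table: pd.DataFrame  # long on-disk format
    lr_calls: list[dosage.LRCall]
    dropout_flags: list[dosage.DropoutFlag]
    failed_samples: list[str]
    masked_amplicons: list[str]


def run_lr_batch(
    matrix: pd.DataFrame,
    panel: PanelDefinition,
    del_threshold: float = dosage.DEL_THRESHOLD,
    dup_threshold: float = dosage.DUP_THRESHOLD,
    dropout_z: float = 4.0,
) -> LRRunResult:
    """Counts -> dosage chain -> LR calls + dropout flags for one batch.

    Failed (all-zero) samples are reported as "No Result" and excluded;
    the remaining batch must still hold at least 8 samples.
    """
    failed = dosage.failed_samples(matrix)
    adjusted = dosage.normalize_batch(dosage.normalize_sample(matrix))
    masked = adjusted.attrs.get("masked_amplicons", [])
    dosages = dosage.region_dosage(dosage.summarize_region(adjusted, panel))
    lr_calls = dosage.call_lr(dosages, panel, del_threshold, dup_threshold)
    flags = dosage.flag_dropout(adjusted, panel, lr_calls, z_threshold=dropout_z)
    long = dosage.dosage_long_table(dosages, panel)
    if failed:
        rows = []
        for s in failed:
            for r in panel.regions:
                if not r.tested_by_lr:
                    continue
                rows.append({
                    "sample_id": s, "gene_name": r.gene_name,
                    "region_label": r.region_label, "contig": r.contig,
                    "dosage": float("nan"),
                    "n_amplicons": len(panel.region_to_amplicons[r.key]),
                    "dispersion": float("nan"),
                })
        long = pd.concat([long, pd.DataFrame(rows)], ignore_index=True)
    return LRRunResult(dosages=dosages, dosage_table=long, lr_calls=lr_calls,
                       dropout_flags=flags, failed_samples=failed,
                       masked_amplicons=list(masked))


@dataclass
class CGHRunResult:
    normalized: pd.DataFrame
    calls: list[cgh.CGHCall]


def run_cgh_batch(
    probes: pd.DataFrame,
    panel: PanelDefinition,
    historic: cgh.HistoricProbeStats | None = None,
    del_threshold: float = cgh.DEL_THRESHOLD,
    dup_threshold: float = cgh.DUP_THRESHOLD,
) -> CGHRunResult:
    """Log ratios -> four-stage normalization -> region calls, per sample."""
    frames = []
    for sample_id, df in probes.groupby("sample_id"):
        norm = cgh.normalize_cgh(cgh.compute_log_ratios(df), historic=historic)
        frames.append(norm)
    normalized = pd.concat(frames, ignore_index=True)
    calls = cgh.call_cgh_regions(normalized, panel, del_threshold, dup_threshold)
    return CGHRunResult(normalized=normalized, calls=calls)


@dataclass
class ValidationResult:
    table: stats.ConcordanceTable
    sensitivity: float
    specificity: float
    sensitivity_bound: stats.ConfidenceBound
    specificity_bound: stats.ConfidenceBound
    report: str


def run_validation(
    test_calls: list[VariantCall],
    truth_calls: list[VariantCall],
    panel: PanelDefinition | None = None,
    bases_analyzed_per_sample: int | None = None,
    n_samples: int | None = None,
    confidence: float = 0.95,
) -> ValidationResult:
    table = stats.compare_callsets(
        test_calls, truth_calls, panel=panel,
        bases_analyzed_per_sample=bases_analyzed_per_sample,
        n_samples=n_samples,
    )
    sens = stats.sensitivity(table)
    spec = stats.specificity(table)
    sens_b = stats.exact_lower_bound(
        table.true_positives, table.true_positives + table.false_negatives,
        confidence)
    spec_b = stats.exact_lower_bound(
        table.true_negatives, table.true_negatives + table.false_positives,
        confidence)
    return ValidationResult(
        table=table, sensitivity=sens, specificity=spec,
        sensitivity_bound=sens_b, specificity_bound=spec_b,
        report=stats.summary_report(table, confidence),
    )
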