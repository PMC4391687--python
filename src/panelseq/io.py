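"""Readers and writers for every on-disk format the pipeline touches.

Formats
-------
* Panel manifest: a BED-like TSV dialect with a header line and a
  ``record`` column distinguishing ``region`` and ``amplicon`` rows
  (columns documented in :data:`MANIFEST_COLUMNS`).  Coordinates are
  0-based half-open.
* References: plain FASTA plus a two-column TSV of gene/pseudogene pairs.
* Variant calls: VCF 4.2, one record per variant with per-sample FORMAT
  fields; written as text, read back through :mod:`pysam`.
* Dosage tables, count matrices, probe tables, sample sheets: TSV.
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
import pysam
from Bio import SeqIO

from .calling import CallStatus, VariantCall, Zygosity
from .model import (
    AmpliconDef,
    PanelDefinition,
    PanelRegion,
    PanelValidationError,
    ReferenceSet,
    SampleEntry,
    SampleSheet,
)

MANIFEST_COLUMNS = [
    "record", "contig", "start", "end", "gene_name", "region_label",
    "upstream_flank", "downstream_flank", "tested_by_lr",
    "amplicon_id", "forward_primer", "reverse_primer", "multiplex_group",
]

MISSING = "."
NO_RESULT = "NA"  # explicit null marker for failed samples ("No Result")


class ManifestParseError(ValueError):
    """Malformed panel manifest line (message names the line number)."""


def load_panel(manifest_path: str | Path) -> PanelDefinition:
    """Parse a panel manifest into a validated :class:`PanelDefinition`."""
    regions: list[PanelRegion] = []
    amplicons: list[AmpliconDef] = []
    with open(manifest_path) as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader, None)
        if header != MANIFEST_COLUMNS:
            raise ManifestParseError(
                f"{manifest_path}: line 1: expected header {MANIFEST_COLUMNS}, got {header}"
            )
        for lineno, row in enumerate(reader, start=2):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if len(row) != len(MANIFEST_COLUMNS):
                raise ManifestParseError(
                    f"{manifest_path}: line {lineno}: expected "
                    f"{len(MANIFEST_COLUMNS)} fields, got {len(row)}"
                )
            rec = dict(zip(MANIFEST_COLUMNS, row))
            try:
                if rec["record"] == "region":
                    regions.append(
                        PanelRegion(
                            gene_name=rec["gene_name"],
                            region_label=rec["region_label"],
                            contig=rec["contig"],
                            start=int(rec["start"]),
                            end=int(rec["end"]),
                            upstream_flank=int(rec["upstream_flank"]),
                            downstream_flank=int(rec["downstream_flank"]),
                            tested_by_lr=rec["tested_by_lr"] == "1",
                        )
                    )
                elif rec["record"] == "amplicon":
                    amplicons.append(
                        AmpliconDef(
                            amplicon_id=rec["amplicon_id"],
                            contig=rec["contig"],
                            insert_start=int(rec["start"]),
                            insert_end=int(rec["end"]),
                            forward_primer=rec["forward_primer"],
                            reverse_primer=rec["reverse_primer"],
                            multiplex_group=rec["multiplex_group"],
                        )
                    )
                else:
                    raise ManifestParseError(
                        f"{manifest_path}: line {lineno}: unknown record type "
                        f"{rec['record']!r}"
                    )
            except (ValueError, KeyError) as exc:
                if isinstance(exc, (ManifestParseError, PanelValidationError)):
                    raise
                raise ManifestParseError(
                    f"{manifest_path}: line {lineno}: {exc}"
                ) from exc
    return PanelDefinition(regions, amplicons)


def write_panel(panel: PanelDefinition, out_path: str | Path) -> None:
    with open(out_path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(MANIFEST_COLUMNS)
        for r in panel.regions:
            w.writerow([
                "region", r.contig, r.start, r.end, r.gene_name, r.region_label,
                r.upstream_flank, r.downstream_flank, int(r.tested_by_lr),
                MISSING, MISSING, MISSING, MISSING,
            ])
        for a in panel.amplicons:
            w.writerow([
                "amplicon", a.contig, a.insert_start, a.insert_end,
                MISSING, MISSING, MISSING, MISSING, MISSING,
                a.amplicon_id, a.forward_primer, a.reverse_primer,
                a.multiplex_group or MISSING,
            ])


def load_references(
    fasta_path: str | Path, homology_path: str | Path | None = None
) -> ReferenceSet:
    """Load gene/pseudogene references from FASTA + a homology pair TSV.

    Sequence ids appearing in the second column of the homology file are
    treated as pseudogenes; all other FASTA records are genes.  Without a
    homology file every record is a gene and pseudogene filtering is a no-op.
    """
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        if rec.id in seqs:
            raise PanelValidationError(f"duplicate FASTA id {rec.id!r} in {fasta_path}")
        seqs[rec.id] = str(rec.seq).upper()
    pairs: list[tuple[str, str]] = []
    if homology_path is not None:
        with open(homology_path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                parts = line.split("\t")
                if len(parts) != 2:
                    raise ManifestParseError(
                        f"{homology_path}: line {lineno}: expected 2 columns"
                    )
                pairs.append((parts[0], parts[1]))
    pseudo_ids = {p for _, p in pairs}
    unknown = {g for g, p in pairs} - set(seqs) | pseudo_ids - set(seqs)
    if unknown:
        raise PanelValidationError(
            f"homology pairs reference ids absent from FASTA: {sorted(unknown)}"
        )
    return ReferenceSet(
        gene_sequences={k: v for k, v in seqs.items() if k not in pseudo_ids},
        pseudogene_sequences={k: v for k, v in seqs.items() if k in pseudo_ids},
        homology_pairs=pairs,
    )


def write_references(refs: ReferenceSet, fasta_path: str | Path,
                     homology_path: str | Path) -> None:
    with open(fasta_path, "w") as fh:
        for name, seq in {**refs.gene_sequences, **refs.pseudogene_sequences}.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 80):
                fh.write(seq[i:i + 80] + "\n")
    with open(homology_path, "w") as fh:
        for g, p in refs.homology_pairs:
            fh.write(f"{g}\t{p}\n")


def load_sample_sheet(path: str | Path) -> SampleSheet:
    entries = []
    with open(path) as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader, None)
        if header != ["sample_id", "barcode", "batch_id"]:
            raise ManifestParseError(f"{path}: bad sample sheet header {header}")
        for row in reader:
            if row:
                entries.append(SampleEntry(*row))
    return SampleSheet(entries)


def write_sample_sheet(sheet: SampleSheet, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["sample_id", "barcode", "batch_id"])
        for e in sheet.entries:
            w.writerow([e.sample_id, e.barcode, e.batch_id])


# ---------------------------------------------------------------------------
# VCF

_VCF_HEADER_LINES = [
    '##fileformat=VCFv4.2',
    '##source=panelseq',
    '##FILTER=<ID=confirm,Description="Intermediate allele frequency '
    '(10-30% or 70-90%); flagged for orthogonal confirmation">',
    '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
    '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth at site">',
    '##FORMAT=<ID=VF,Number=1,Type=Float,Description="Non-wild-type allele frequency">',
    '##FORMAT=<ID=FD,Number=1,Type=Integer,Description="Forward-strand depth">',
    '##FORMAT=<ID=RD,Number=1,Type=Integer,Description="Reverse-strand depth">',
    '##FORMAT=<ID=AF,Number=1,Type=Integer,Description="Alt support, forward strand">',
    '##FORMAT=<ID=AR,Number=1,Type=Integer,Description="Alt support, reverse strand">',
]


def write_variant_calls(
    calls: Sequence[VariantCall],
    out_path: str | Path,
    references: ReferenceSet | None = None,
    contig_lengths: dict[str, int] | None = None,
) -> None:
    """Write calls as a multi-sample VCF 4.2 file.

    Zygosity is encoded in GT (0/1 het, 1/1 hom); calls flagged for
    confirmation carry FILTER ``confirm``.  Calls are sorted before writing.
    When ``references`` is given, every REF allele is checked against it.
    """
    if contig_lengths is None and references is not None:
        contig_lengths = {k: len(v) for k, v in references.gene_sequences.items()}
    if references is not None:
        for c in calls:
            seq = references.gene_sequences.get(c.contig)
            if seq is not None and seq[c.position:c.position + len(c.ref_allele)] != c.ref_allele:
                raise ValueError(
                    f"REF allele {c.ref_allele!r} at {c.contig}:{c.position} "
                    f"does not match the reference sequence"
                )
    samples = sorted({c.sample_id for c in calls})
    by_site: dict[tuple[str, int, str, str], dict[str, VariantCall]] = {}
    for c in calls:
        by_site.setdefault((c.contig, c.position, c.ref_allele, c.alt_allele), {})[
            c.sample_id
        ] = c
    contig_order = list(contig_lengths) if contig_lengths else sorted(
        {c.contig for c in calls}
    )
    rank = {c: i for i, c in enumerate(contig_order)}
    with open(out_path, "w") as fh:
        for line in _VCF_HEADER_LINES:
            fh.write(line + "\n")
        for contig in contig_order:
            length = (contig_lengths or {}).get(contig)
            if length:
                fh.write(f"##contig=<ID={contig},length={length}>\n")
            else:
                fh.write(f"##contig=<ID={contig}>\n")
        cols = ["#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER", "INFO"]
        if samples:  # FORMAT column is only legal with >=1 sample column
            cols.append("FORMAT")
        fh.write("\t".join(cols + samples) + "\n")
        for (contig, pos, ref, alt), per_sample in sorted(
            by_site.items(), key=lambda kv: (rank.get(kv[0][0], 1 << 30), kv[0][1], kv[0][2], kv[0][3])
        ):
            flagged = any(c.status == CallStatus.FLAGGED for c in per_sample.values())
            filt = "confirm" if flagged else "PASS"
            fields = [contig, str(pos + 1), MISSING, ref, alt, MISSING, filt,
                      MISSING, "GT:DP:VF:FD:RD:AF:AR"]
            for s in samples:
                c = per_sample.get(s)
                if c is None:
                    fields.append("./.")
                    continue
                gt = "1/1" if c.zygosity == Zygosity.HOMOZYGOUS else "0/1"
                fields.append(
                    f"{gt}:{c.depth}:{c.non_wt_frequency:.6f}:{c.forward_depth}:"
                    f"{c.reverse_depth}:{c.alt_forward}:{c.alt_reverse}"
                )
            fh.write("\t".join(fields) + "\n")


def read_variant_calls(path: str | Path) -> list[VariantCall]:
    """Re-parse a VCF written by :func:`write_variant_calls`."""
    calls: list[VariantCall] = []
    with pysam.VariantFile(str(path)) as vf:
        for rec in vf:
            flagged = "confirm" in rec.filter.keys()
            for sample_id, fmt in rec.samples.items():
                gt = fmt.get("GT")
                if gt is None or gt == (None, None):
                    continue
                zyg = Zygosity.HOMOZYGOUS if gt == (1, 1) else Zygosity.HETEROZYGOUS
                calls.append(
                    VariantCall(
                        sample_id=sample_id,
                        contig=rec.contig,
                        position=rec.pos - 1,
                        ref_allele=rec.ref,
                        alt_allele=rec.alts[0],
                        zygosity=zyg,
                        status=CallStatus.FLAGGED if flagged else CallStatus.CALLED,
                        depth=fmt.get("DP") or 0,
                        non_wt_frequency=float(fmt.get("VF") or 0.0),
                        forward_depth=fmt.get("FD") or 0,
                        reverse_depth=fmt.get("RD") or 0,
                        alt_forward=fmt.get("AF") or 0,
                        alt_reverse=fmt.get("AR") or 0,
                    )
                )
    return calls


# ---------------------------------------------------------------------------
# Tabular outputs

DOSAGE_COLUMNS = [
    "sample_id", "gene_name", "region_label", "contig",
    "dosage", "n_amplicons", "dispersion",
]


def write_dosage_table(dosages: pd.DataFrame, out_path: str | Path) -> None:
    """Write a region-dosage table (one row per sample x region).

    Missing dosages (failed samples / untestable regions) are written as
    the explicit null marker ``NA``.
    """
    df = dosages.loc[:, DOSAGE_COLUMNS].copy()
    df["dosage"] = df["dosage"].map(
        lambda v: NO_RESULT if pd.isna(v) else f"{v:.6f}"
    )
    df["dispersion"] = df["dispersion"].map(
        lambda v: NO_RESULT if pd.isna(v) else f"{v:.6f}"
    )
    df.to_csv(out_path, sep="\t", index=False)


def read_dosage_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(
        path, sep="\t", dtype={"sample_id": str, "gene_name": str,
                               "region_label": str, "contig": str},
        na_values=[NO_RESULT], keep_default_na=False,
    )
    if list(df.columns) != DOSAGE_COLUMNS:
        raise ManifestParseError(f"{path}: bad dosage table header {list(df.columns)}")
    return df


def write_count_matrix(counts: pd.DataFrame, out_path: str | Path) -> None:
    """Samples x amplicons read-count matrix as TSV (index column sample_id)."""
    counts.to_csv(out_path, sep="\t", index_label="sample_id")


def read_count_matrix(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col="sample_id")
    df.index = df.index.astype(str)
    if (df.values < 0).any():
        raise PanelValidationError(f"{path}: negative counts in matrix")
    return df


PROBE_COLUMNS = [
    "sample_id", "probe_id", "contig", "position", "gene_name", "region_label",
    "gc_fraction", "sample_signal", "reference_signal",
]


def write_probe_table(probes: pd.DataFrame, out_path: str | Path) -> None:
    probes.loc[:, PROBE_COLUMNS].to_csv(out_path, sep="\t", index=False)


def read_probe_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "probe_id": str,
                                            "contig": str, "gene_name": str,
                                            "region_label": str})
    missing = set(PROBE_COLUMNS) - set(df.columns)
    if missing:
        raise ManifestParseError(f"{path}: probe table missing columns {sorted(missing)}")
    return df


def load_panel_gene_table() -> pd.DataFrame:
    """Static metadata: the 25 genes (and transcripts) of the clinical panel.

    Shipped for reference only — all computation in this package is generic
    over :class:`~panelseq.model.PanelDefinition`.
    """
    from importlib.resources import files

    path = files("panelseq.data").joinpath("panel_genes.tsv")
    with path.open() as fh:
        return pd.read_csv(fh, sep="\t")


def iter_fastq(path: str | Path) -> Iterable[tuple[str, str, str]]:
    """Yield (read_id, sequence, quality) from an uncompressed FASTQ file."""
    from Bio.SeqIO.QualityIO import FastqGeneralIterator

    with open(path) as fh:
        yield from FastqGeneralIterator(fh)


def write_fastq(reads: Iterable[tuple[str, str, str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rid, seq, qual in reads:
            fh.write(f"@{rid}\n{seq}\n+\n{qual}\n")
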