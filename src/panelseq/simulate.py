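"""Synthetic panels, references, reads, count matrices and CGH arrays.

Everything the pipeline consumes can be generated here with known ground
truth: random gene models tiled by overlapping amplicons, pseudogene
homologs at a configurable identity, per-sample paired reads carrying
barcodes and primers, batch read-count matrices with "digital"
droplet-PCR-like consistency, and two-channel probe intensity tables.

The generator emulates the study conditions of a 96-sample amplicon batch
sequenced to a mean depth of ~1000x with 2x150 paired reads; both are
configurable so tests can run at desk scale.  All randomness flows from
``SimulationConfig.seed`` — identical seeds give byte-identical output.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .model import (
    AmpliconDef,
    PanelDefinition,
    PanelRegion,
    ReferenceSet,
    SampleEntry,
    SampleSheet,
)
from .reads import revcomp

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class VariantSpec:
    sample_id: str
    contig: str
    position: int  # 0-based, anchored & left-normalized
    ref: str
    alt: str
    zygosity: str  # "heterozygous" | "homozygous"


@dataclass(frozen=True)
class LREventSpec:
    sample_id: str
    gene_name: str
    region_labels: tuple[str, ...]
    copy_change: int  # -1 deletion, +1 duplication


@dataclass(frozen=True)
class DropoutSpec:
    sample_id: str
    amplicon_id: str


@dataclass
class SimulationConfig:
    seed: int = 0
    n_samples: int = 96
    mean_depth: float = 1000.0
    read_length: int = 150
    base_error_rate: float = 0.001
    n_genes: int = 3
    regions_per_gene: int = 4
    n_pseudogenes: int = 1
    pseudogene_identity: float = 0.97
    pseudogene_contamination: float = 0.03
    variant_spec: list[VariantSpec] = field(default_factory=list)
    lr_spec: list[LREventSpec] = field(default_factory=list)
    dropout_spec: list[DropoutSpec] = field(default_factory=list)
    amplicon_count_noise_cv: float = 0.08
    batch_id: str = "batch1"
    # panel geometry
    region_core_length: int = 100
    upstream_flank: int = 20
    downstream_flank: int = 10
    region_gap: int = 40
    gene_margin: int = 30
    amplicons_per_region: int = 5
    insert_length: int = 70
    primer_length: int = 20
    # read qualities
    base_quality: int = 38
    low_quality: int = 2
    low_quality_tail_fraction: float = 0.05
    # CGH
    probes_per_region: int = 27
    cgh_noise_sd_log2: float = 0.05
    cgh_gc_slope: float = 0.0
    cgh_probe_affinity_sd_log2: float = 0.2
    cgh_sample_shift_sd_log2: float = 0.1
    zero_copy_probes: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        for name in ("base_error_rate", "pseudogene_contamination",
                     "low_quality_tail_fraction"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be a probability, got {v}")


@dataclass
class TruthSet:
    """Ground truth accompanying a simulated dataset."""

    variants: list[VariantSpec] = field(default_factory=list)
    dosages: dict[tuple[str, str, str], int] = field(default_factory=dict)
    dropouts: list[DropoutSpec] = field(default_factory=list)

    def expected_dosage(self, sample_id: str, gene: str, region_label: str) -> int:
        return self.dosages.get((sample_id, gene, region_label), 2)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "variants": [asdict(v) for v in self.variants],
            "dosages": [
                {"sample_id": s, "gene_name": g, "region_label": r, "copies": c}
                for (s, g, r), c in self.dosages.items()
            ],
            "dropouts": [asdict(d) for d in self.dropouts],
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "TruthSet":
        payload = json.loads(Path(path).read_text())
        return cls(
            variants=[VariantSpec(**v) for v in payload["variants"]],
            dosages={
                (d["sample_id"], d["gene_name"], d["region_label"]): d["copies"]
                for d in payload["dosages"]
            },
            dropouts=[DropoutSpec(**d) for d in payload["dropouts"]],
        )


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, n)])


def sample_ids(config: SimulationConfig) -> list[str]:
    return [f"S{i:03d}" for i in range(config.n_samples)]


def make_sample_sheet(config: SimulationConfig) -> SampleSheet:
    """Deterministic unique 6-nt barcodes for the configured batch."""
    rng = np.random.default_rng([config.seed, 101])
    codes: list[str] = []
    seen: set[str] = set()
    while len(codes) < config.n_samples:
        bc = _random_seq(rng, 6)
        if bc not in seen:
            seen.add(bc)
            codes.append(bc)
    return SampleSheet([
        SampleEntry(sample_id=s, barcode=b, batch_id=config.batch_id)
        for s, b in zip(sample_ids(config), codes)
    ])


def simulate_panel(config: SimulationConfig) -> tuple[PanelDefinition, ReferenceSet]:
    """Random gene models, tiled amplicons, and pseudogene homologs.

    Each gene gets ``regions_per_gene`` exon-like regions (core plus
    intronic flanks) tiled by overlapping amplicons; the first
    ``n_pseudogenes`` genes receive a pseudogene copy at
    ``pseudogene_identity`` with every amplicon insert guaranteed to
    contain at least one recorded divergent position.
    """
    if config.pseudogene_identity >= 1.0:
        raise ValueError("pseudogene_identity must be < 1.0 to be distinguishable")
    if config.n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    rng = np.random.default_rng([config.seed, 11])
    span_len = (config.upstream_flank + config.region_core_length
                + config.downstream_flank)
    regions: list[PanelRegion] = []
    amplicons: list[AmpliconDef] = []
    genes: dict[str, str] = {}
    pseudos: dict[str, str] = {}
    pairs: list[tuple[str, str]] = []
    divergent: dict[str, list[int]] = {}
    amp_serial = 0
    for gi in range(config.n_genes):
        gene = f"GENE{gi:02d}"
        length = (2 * config.gene_margin + config.regions_per_gene * span_len
                  + (config.regions_per_gene - 1) * config.region_gap)
        seq = _random_seq(rng, length)
        genes[gene] = seq
        gene_inserts: list[tuple[int, int]] = []
        for ri in range(config.regions_per_gene):
            block = config.gene_margin + ri * (span_len + config.region_gap)
            start = block + config.upstream_flank
            regions.append(PanelRegion(
                gene_name=gene, region_label=f"exon {ri + 1}", contig=gene,
                start=start, end=start + config.region_core_length,
                upstream_flank=config.upstream_flank,
                downstream_flank=config.downstream_flank,
            ))
            n_amp = config.amplicons_per_region
            starts = np.linspace(
                block, block + span_len - config.insert_length, n_amp
            ).round().astype(int)
            for ai, ins_start in enumerate(starts):
                ins_end = int(ins_start) + config.insert_length
                gene_inserts.append((int(ins_start), ins_end))
                amplicons.append(AmpliconDef(
                    amplicon_id=f"{gene}_r{ri + 1}_a{ai + 1}",
                    contig=gene,
                    insert_start=int(ins_start), insert_end=ins_end,
                    forward_primer=seq[ins_start - config.primer_length:ins_start],
                    reverse_primer=revcomp(seq[ins_end:ins_end + config.primer_length]),
                    multiplex_group=f"mg{amp_serial // 5}",
                ))
                amp_serial += 1
        if gi < config.n_pseudogenes:
            pseudo = f"PSEUDO{gi:02d}"
            target = round((1.0 - config.pseudogene_identity) * length)
            chosen: set[int] = set()
            for ins_start, ins_end in gene_inserts:
                lo, hi = ins_start + 8, ins_end - 8
                if not any(lo <= p < hi for p in chosen):
                    chosen.add(int(rng.integers(lo, hi)))
            while len(chosen) < target:
                chosen.add(int(rng.integers(0, length)))
            pseq = list(seq)
            for p in sorted(chosen):
                alts = [b for b in "ACGT" if b != pseq[p]]
                pseq[p] = alts[rng.integers(0, 3)]
            pseudos[pseudo] = "".join(pseq)
            pairs.append((gene, pseudo))
            divergent[gene] = sorted(chosen)
    refs = ReferenceSet(
        gene_sequences=genes, pseudogene_sequences=pseudos,
        homology_pairs=pairs, divergent_positions=divergent,
    )
    return PanelDefinition(regions, amplicons), refs


def generate_variant_spec(
    config: SimulationConfig,
    panel: PanelDefinition,
    refs: ReferenceSet,
    n_variants: int,
    indel_fraction: float = 0.2,
    hom_fraction: float = 0.25,
    per_sample: bool = False,
) -> list[VariantSpec]:
    """Draw a random, well-separated variant spec with known zygosity.

    Positions are kept >= 10 bases from the edge of every amplicon insert
    containing them, away from pseudogene-divergent positions, and >= 10
    bases apart within a sample, so each injected variant is unambiguously
    observable.  ``n_variants`` are distributed round-robin over samples
    (or per sample when ``per_sample``).
    """
    rng = np.random.default_rng([config.seed, 23])
    samples = sample_ids(config)
    inserts_by_contig: dict[str, list[tuple[int, int]]] = {}
    for a in panel.amplicons:
        inserts_by_contig.setdefault(a.contig, []).append(
            (a.insert_start, a.insert_end))
    candidates: list[tuple[str, int]] = []
    for region in panel.regions:
        lo, hi = region.span
        div = set(refs.divergent_positions.get(region.gene_name, []))
        for pos in range(lo, hi):
            inserts = [iv for iv in inserts_by_contig[region.contig]
                       if iv[0] <= pos < iv[1]]
            # require >=3 covering amplicons so the sampling variance of the
            # allele fraction keeps het calls safely inside the 30-70% band
            if len(inserts) < 3:
                continue
            if any(pos - s < 10 or e - pos < 14 for s, e in inserts):
                continue
            if any(abs(pos - d) <= 3 for d in div):
                continue
            candidates.append((region.contig, pos))
    if not candidates:
        raise ValueError("panel has no usable variant positions")
    total = n_variants * len(samples) if per_sample else n_variants
    out: list[VariantSpec] = []
    used: dict[str, list[tuple[str, int]]] = {s: [] for s in samples}
    order = rng.permutation(len(candidates))
    ci = 0
    si = 0
    guard = 0
    while len(out) < total and guard < 50 * total:
        guard += 1
        sample = samples[si % len(samples)]
        contig, pos = candidates[order[ci % len(order)]]
        ci += 1
        if any(c == contig and abs(p - pos) < 10 for c, p in used[sample]):
            continue
        seq = refs.gene_sequences[contig]
        ref_base = seq[pos]
        if rng.random() < indel_fraction:
            if rng.random() < 0.5:  # deletion of 2 bases
                ref, alt = seq[pos:pos + 3], seq[pos]
            else:  # insertion of 2 bases
                ins = _random_seq(rng, 2)
                ref, alt = ref_base, ref_base + ins
            from .calling import left_normalize
            npos, nref, nalt = left_normalize(seq, pos, ref, alt)
            if npos != pos:  # normalization moved it; placement guarantees void
                continue
            ref, alt = nref, nalt
        else:
            alts = [b for b in "ACGT" if b != ref_base]
            ref, alt = ref_base, alts[rng.integers(0, 3)]
        zyg = "homozygous" if rng.random() < hom_fraction else "heterozygous"
        out.append(VariantSpec(sample, contig, pos, ref, alt, zyg))
        used[sample].append((contig, pos))
        si += 1
    if len(out) < total:
        raise ValueError(f"could only place {len(out)} of {total} variants")
    return out


def _apply_variants(seq: str, variants: list[VariantSpec]) -> str:
    for v in sorted(variants, key=lambda v: -v.position):
        seq = seq[:v.position] + v.alt + seq[v.position + len(v.ref):]
    return seq


def _insert_seq(ref_insert: str, ins_start: int,
                variants: list[VariantSpec]) -> str:
    out = ref_insert
    for v in sorted(variants, key=lambda v: -v.position):
        rel = v.position - ins_start
        out = out[:rel] + v.alt + out[rel + len(v.ref):]
    return out


def simulate_reads(
    config: SimulationConfig,
    panel: PanelDefinition,
    refs: ReferenceSet,
) -> tuple[dict[str, tuple[list, list]], TruthSet, SampleSheet]:
    """Paired reads per sample with barcodes, primers, and injected truth.

    Returns ``{sample_id: (r1_reads, r2_reads)}`` (each read a
    ``(id, sequence, quality)`` tuple), the :class:`TruthSet`, and the
    matching :class:`~panelseq.model.SampleSheet`.

    Reads carry the 6-nt sample barcode then the amplicon primer at their
    5' end; injected variants appear at allele fraction ~0.5 (het, binomial
    over read pairs) or ~1.0 (hom); a configurable fraction of reads from
    pseudogene-paired genes derives from the pseudogene body (mispriming);
    quality strings get a sub-Q30 tail on a configurable fraction of reads.
    """
    rng = np.random.default_rng([config.seed, 37])
    sheet = make_sample_sheet(config)
    barcode_of = {e.sample_id: e.barcode for e in sheet.entries}
    samples = sample_ids(config)

    inserts = {a.amplicon_id: a for a in panel.amplicons}
    for v in config.variant_spec:
        if not any(a.contig == v.contig and a.insert_start <= v.position
                   and v.position + len(v.ref) <= a.insert_end
                   for a in panel.amplicons):
            raise ValueError(
                f"variant at {v.contig}:{v.position} lies outside every "
                f"amplicon insert"
            )

    total_insert = sum(a.insert_end - a.insert_start for a in panel.amplicons)
    total_span = sum(r.span_length for r in panel.regions)
    multiplicity = total_insert / max(total_span, 1)
    pairs_mean = config.mean_depth / (2.0 * multiplicity)

    variants_by_sample_contig: dict[tuple[str, str], list[VariantSpec]] = {}
    for v in config.variant_spec:
        variants_by_sample_contig.setdefault((v.sample_id, v.contig), []).append(v)
    dropout_set = {(d.sample_id, d.amplicon_id) for d in config.dropout_spec}
    lr_by_sample: dict[str, list[LREventSpec]] = {}
    for e in config.lr_spec:
        lr_by_sample.setdefault(e.sample_id, []).append(e)
    paired_genes = {g for g, _ in refs.homology_pairs}
    pseudo_of = {g: p for g, p in refs.homology_pairs}

    qual_hi = chr(config.base_quality + 33)
    qual_lo = chr(config.low_quality + 33)

    def finish_read(seq: str) -> tuple[str, str]:
        seq = seq[:config.read_length]
        n = len(seq)
        n_err = rng.binomial(n, config.base_error_rate)
        if n_err:
            arr = list(seq)
            for p in rng.integers(0, n, n_err):
                alts = [b for b in "ACGT" if b != arr[p]]
                arr[p] = alts[rng.integers(0, 3)]
            seq = "".join(arr)
        qual = qual_hi * n
        if rng.random() < config.low_quality_tail_fraction:
            tail = min(int(rng.geometric(0.25)) + 4, n)
            qual = qual_hi * (n - tail) + qual_lo * tail
        return seq, qual

    out: dict[str, tuple[list, list]] = {}
    truth = TruthSet(variants=list(config.variant_spec),
                     dropouts=list(config.dropout_spec))
    for e in config.lr_spec:
        for label in e.region_labels:
            truth.dosages[(e.sample_id, e.gene_name, label)] = 2 + e.copy_change

    region_of = {}
    for a in panel.amplicons:
        region_of[a.amplicon_id] = panel.amplicon_to_regions[a.amplicon_id]

    for sample in samples:
        barcode = barcode_of[sample]
        r1: list[tuple[str, str, str]] = []
        r2: list[tuple[str, str, str]] = []
        for a in panel.amplicons:
            gene_seq = refs.gene_sequences[a.contig]
            ref_insert = gene_seq[a.insert_start:a.insert_end]
            local = [
                v for v in variants_by_sample_contig.get((sample, a.contig), [])
                if a.insert_start <= v.position
                and v.position + len(v.ref) <= a.insert_end
            ]
            hap0 = _insert_seq(ref_insert, a.insert_start,
                               [v for v in local if v.zygosity == "homozygous"])
            hap1 = _insert_seq(ref_insert, a.insert_start, local)
            factor = 1.0
            for e in lr_by_sample.get(sample, ()):
                if any(r.gene_name == e.gene_name and r.region_label in e.region_labels
                       for r in region_of[a.amplicon_id]):
                    factor *= (2 + e.copy_change) / 2.0
            dropout = (sample, a.amplicon_id) in dropout_set
            if dropout:
                factor *= 0.5
            mu = pairs_mean * factor
            if config.amplicon_count_noise_cv > 0:
                mu *= max(0.0, rng.normal(1.0, config.amplicon_count_noise_cv))
            n_pairs = int(rng.poisson(mu))
            for i in range(n_pairs):
                hap = 0 if dropout else int(rng.integers(0, 2))
                insert = hap1 if hap else hap0
                s1, q1 = finish_read(barcode + a.forward_primer + insert)
                s2, q2 = finish_read(barcode + a.reverse_primer + revcomp(insert))
                rid = f"{sample}:{a.amplicon_id}:{i}"
                r1.append((rid + "/1", s1, q1))
                r2.append((rid + "/2", s2, q2))
            if a.contig in paired_genes and config.pseudogene_contamination > 0:
                pseq = refs.pseudogene_sequences[pseudo_of[a.contig]]
                p_insert = pseq[a.insert_start:a.insert_end]
                n_cont = int(rng.poisson(pairs_mean * config.pseudogene_contamination))
                for i in range(n_cont):
                    s1, q1 = finish_read(barcode + a.forward_primer + p_insert)
                    s2, q2 = finish_read(barcode + a.reverse_primer
                                         + revcomp(p_insert))
                    rid = f"{sample}:{a.amplicon_id}:c{i}"
                    r1.append((rid + "/1", s1, q1))
                    r2.append((rid + "/2", s2, q2))
        out[sample] = (r1, r2)
    return out, truth, sheet


def simulate_count_matrix(
    config: SimulationConfig, panel: PanelDefinition
) -> tuple[pd.DataFrame, TruthSet]:
    """Samples x amplicons count matrix with injected LR and dropout events.

    counts = per-sample scale x per-amplicon efficiency x copy/2 x noise.
    Noise is negative binomial at the configured coefficient of variation
    (Poisson when the CV is at or below the Poisson floor); with
    ``amplicon_count_noise_cv == 0`` scales and efficiencies are drawn on
    integer grids so expected counts are exact.
    """
    if config.n_samples < 8:
        raise ValueError("batch statistics need >= 8 samples")
    rng = np.random.default_rng([config.seed, 53])
    samples = sample_ids(config)
    amps = panel.amplicons
    cv = config.amplicon_count_noise_cv
    if cv == 0:
        scale = 2 * rng.integers(250, 750, config.n_samples)
        eff = rng.integers(5, 21, len(amps)).astype(float)
    else:
        scale = rng.uniform(500.0, 1500.0, config.n_samples)
        eff = rng.uniform(0.5, 2.0, len(amps))
    copy_factor = np.full((config.n_samples, len(amps)), 1.0)
    truth = TruthSet(dropouts=list(config.dropout_spec))
    sample_index = {s: i for i, s in enumerate(samples)}
    amp_index = {a.amplicon_id: j for j, a in enumerate(amps)}
    for e in config.lr_spec:
        si = sample_index[e.sample_id]
        for label in e.region_labels:
            truth.dosages[(e.sample_id, e.gene_name, label)] = 2 + e.copy_change
        for j, a in enumerate(amps):
            if any(r.gene_name == e.gene_name and r.region_label in e.region_labels
                   for r in panel.amplicon_to_regions[a.amplicon_id]):
                copy_factor[si, j] *= (2 + e.copy_change) / 2.0
    for d in config.dropout_spec:
        copy_factor[sample_index[d.sample_id], amp_index[d.amplicon_id]] *= 0.5
    expected = np.outer(scale, eff) * copy_factor
    if cv == 0:
        counts = expected.astype(np.int64)
    else:
        mu = np.maximum(expected, 1e-9)
        var = (cv * mu) ** 2
        counts = np.empty_like(mu)
        over = var > mu
        # NB where overdispersed relative to Poisson, Poisson elsewhere
        r = np.where(over, mu ** 2 / np.maximum(var - mu, 1e-9), 1.0)
        p = r / (r + mu)
        counts[over] = rng.negative_binomial(r[over], p[over])
        counts[~over] = rng.poisson(mu[~over])
        counts = counts.astype(np.int64)
    df = pd.DataFrame(counts, index=pd.Index(samples, name="sample_id"),
                      columns=[a.amplicon_id for a in amps])
    return df, truth


def simulate_cgh(
    config: SimulationConfig, panel: PanelDefinition
) -> tuple[pd.DataFrame, TruthSet]:
    """Two-channel probe intensities per sample with injected copy changes.

    Each region receives ``probes_per_region`` probes.  The sample channel
    carries a multiplicative sample effect, the copy-number effect, an
    optional GC-dependent bias (slope ``cgh_gc_slope`` per unit GC on the
    log2 scale), and log-normal noise; both channels share a per-probe
    affinity.  Synthetic zero-copy controls (restriction-digest style) can
    be forced via ``zero_copy_probes``.
    """
    rng = np.random.default_rng([config.seed, 71])
    samples = sample_ids(config)
    probes = []
    for region in panel.regions:
        lo, hi = region.span
        pos = np.linspace(lo, hi - 1, config.probes_per_region).round().astype(int)
        for k, p in enumerate(pos):
            probes.append({
                "probe_id": f"{region.gene_name}_{region.region_label.replace(' ', '')}_p{k + 1}",
                "contig": region.contig, "position": int(p),
                "gene_name": region.gene_name, "region_label": region.region_label,
                "gc_fraction": float(rng.uniform(0.3, 0.7)),
            })
    pdf = pd.DataFrame(probes)
    n_probes = len(pdf)
    affinity = 2.0 ** rng.normal(0.0, config.cgh_probe_affinity_sd_log2, n_probes)
    base = 1000.0
    truth = TruthSet()
    copies = np.full((len(samples), n_probes), 2.0)
    for e in config.lr_spec:
        si = samples.index(e.sample_id)
        for label in e.region_labels:
            truth.dosages[(e.sample_id, e.gene_name, label)] = 2 + e.copy_change
        mask = ((pdf["gene_name"] == e.gene_name)
                & (pdf["region_label"].isin(e.region_labels))).to_numpy()
        copies[si, mask] = 2 + e.copy_change
    zero_mask = pdf["probe_id"].isin(config.zero_copy_probes).to_numpy()
    frames = []
    gc = pdf["gc_fraction"].to_numpy()
    for si, sample in enumerate(samples):
        shift = 2.0 ** rng.normal(0.0, config.cgh_sample_shift_sd_log2)
        c = copies[si].copy()
        c[zero_mask] = 0.04  # residual signal of a digested site
        noise_s = 2.0 ** rng.normal(0.0, config.cgh_noise_sd_log2, n_probes)
        noise_r = 2.0 ** rng.normal(0.0, config.cgh_noise_sd_log2, n_probes)
        gc_bias = 2.0 ** (config.cgh_gc_slope * (gc - 0.5))
        frame = pdf.copy()
        frame.insert(0, "sample_id", sample)
        frame["sample_signal"] = base * affinity * shift * (c / 2.0) * gc_bias * noise_s
        frame["reference_signal"] = base * affinity * noise_r
        frames.append(frame)
    return pd.concat(frames, ignore_index=True), truth
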