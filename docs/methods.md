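# Methods

`panelseq` re-creates the dry-lab core of a multiplexed amplicon panel for
germline testing: many small PCR amplicons tiled over the exons (plus short
intronic flanks) of a gene panel, sequenced deeply as barcoded paired-end
reads, with copy-number inference riding on the "digital" consistency of
droplet PCR read counts. This note records the models, the parameters that
matter, and the design decisions taken where the procedure was genuinely
open.

## Panel model

A `PanelRegion` is an exon-like interval `[start, end)` extended by at most
20 upstream and 10 downstream intronic bases (the flanks cover proximal
splice elements; the caps are enforced as invariants). An `AmpliconDef`
holds the primer pair and the genomic insert between the primers, 0-based
half-open; conversion to 1-based coordinates happens only when writing VCF.
Regions are tiled by overlapping amplicons (≥5 per region in the
simulator), so most interior bases are covered by several independent
amplicons — the redundancy that makes both variant calling and
allele-dropout detection robust to a variant under any single primer.

The clinical 25-gene list ships only as a metadata table
(`panelseq/data/panel_genes.tsv`); every algorithm is generic over
`PanelDefinition`.

## Read processing

1. **Demultiplexing** is an exact match on the 6-nt barcode prefix.
   Six bases leave no safe Hamming margin for error correction, so a
   mismatched barcode sends the read to the unassigned bin (counted;
   conservation `routed + unassigned == input` is asserted in tests).
2. **Trimming** strips a primer prefix (exact match first, then a ≤1
   mismatch scan) and then removes the maximal 3′ suffix over which a
   5-base sliding mean quality stays below Q30, refined so the first
   trimmed base itself fails Q30. Interior bases are never reordered; a
   read may trim to length 0.
3. **Assignment** aligns each read locally (Smith-Waterman: match +2,
   mismatch −3, gap open −5, gap extend −2) against *all* gene and
   pseudogene references. A read is kept only if its best gene score is
   strictly greater than its best pseudogene score — ties are discarded,
   the conservative choice for genes with near-identical pseudogene
   copies. Reads scoring below 0.6× the maximum achievable score are
   unmapped.

   For speed, a 15-mer seed index nominates candidate references and a
   diagonal (gap-free) evaluation handles the common case. The gap-free
   score is only a lower bound on the SW optimum — an indel inside a short
   tandem repeat can masquerade as a few mismatches — so the shortcut is
   trusted only when it is provably optimal (a perfect match) or when a
   score-only SW pass over the seeded window returns the same value;
   otherwise the full alignment is computed. Homology partners of every
   seeded candidate are always scored, so the pseudogene competitor is
   never skipped.
4. **Pileup**: every assigned read contributes exactly one allele per
   covered reference position (the reference base unless it carries a
   mismatch or an indel anchored there), split by strand, so depth always
   equals the sum of allele counts. Indels are left-normalized against the
   reference at extraction time, so identical events always share a key.

## Variant calling

Calling is purely threshold-based — the assay's review logic, not a
genotype-likelihood model; implementing likelihoods would misrepresent the
procedure. Per base, the most frequent non-reference allele's frequency
falls into lower-inclusive half-open bands:

| band | frequency | action |
|---|---|---|
| noise | [0, 0.10) | no output |
| flagged low | [0.10, 0.30) | reported, flagged for confirmation |
| heterozygous | [0.30, 0.70) | called het |
| flagged high | [0.70, 0.90) | reported, flagged for confirmation |
| homozygous | [0.90, 1.00] | called hom |

The published bands touch at 10/30/70/90%; whether the production
boundaries were inclusive is not documented, so the boundary convention
here is lower-inclusive (0.30 → heterozygous, 0.90 → homozygous) and is
stated prominently because it is a genuine choice. Bases below the 50×
depth floor are never called — the region is emitted as a `CoverageFlag`
(keyed by its minimum depth) for orthogonal repetition instead. This also
prevents artifacts at homozygous deletions, where the few reads spanning
the deleted bases in an alternative representation would otherwise be
called against a near-zero denominator. Strand imbalance (alt support
below 3 reads on either strand by default) is an advisory annotation only.

Only the single most frequent non-reference allele per position is
classified; any residual multi-allelic signal surfaces through the flagged
bands.

## Large rearrangements from amplicon dosage

The batch (up to 96 samples) is its own reference population:

1. ratio(s,a) = count(s,a) / mean over amplicons of count(s,·) — removes
   library size; an all-zero sample is a failed library, reported as
   "No Result" and excluded (≥8 samples must remain);
2. adjusted(s,a) = ratio(s,a) / median over samples of ratio(·,a) —
   removes per-amplicon PCR efficiency; the median tolerates a mutant
   sample in the batch (a mean would not);
3. region summary = mean of adjusted ratios over the amplicons overlapping
   the region;
4. dosage(s,r) = 2 × summary(s,r) / median over samples of summary(·,r),
   so diploid wild type sits at 2.0.

Deletion/duplication thresholds are 1.5 and 2.5 — the midpoints between
integer copy states — turning what is a reviewer scatter-plot judgement in
production into a deterministic rule. Maximal runs of adjacent aberrant
regions (genomic order within a contig) merge into one event, so a
contiguous multi-exon deletion is a single call. Regions can opt out via
`tested_by_lr` (e.g. regions carried only for normalization).

**Allele dropout**: an amplicon whose adjusted ratio sits within ±0.15 of
the single-allele level 0.5 *and* at least 4 batch standard deviations
from the amplicon's batch mean is flagged, unless its region is already an
LR call for that sample (whole-region events take precedence). A 10⁻⁶
floor on the batch SD keeps noise-free synthetic batches well-defined.
The chain is idempotent (normalizing twice changes nothing) and invariant
to scaling any sample's counts — both are tested properties.

## Microarray CGH

Two-channel intensities become log2(sample/reference) per probe, then four
stages are subtracted in order, each stage's adjustment recorded so that
`raw − normalized` equals their sum exactly:

1. **sample dosage** — the array-wide median (global scaling between
   channels);
2. **LOWESS** (frac 0.3) of ratio vs the *reference-channel* log
   intensity. The reference channel was chosen deliberately: a
   copy-number change shifts a probe's own mean intensity, so an MA-style
   fit against mean intensity absorbs part of a real deletion/duplication
   signal (measured here as ~0.2 of a +0.585 duplication), whereas the
   reference channel is copy-number independent;
3. **historic probe** — each probe's median over ≥10 prior wild-type
   arrays (probe affinity artifacts); probes without history get a zero
   adjustment and a flag;
4. **GC** — a LOWESS trend of ratio vs probe GC fraction.

A region is called deleted below −0.5 or duplicated above +0.4 (between 0
and the theoretical heterozygous levels −1 and +0.585) when at least 3
probes individually cross the threshold; adjacent aberrant regions merge.
Synthetic zero-copy controls (restriction-digest style) are supported by
forcing probes to near-zero copy in the simulator.

## Validation statistics

Sensitivity is TP/(TP+FN), specificity TN/(TN+FP), over a base-complete
site accounting: per (sample, position), a variant present in both sets
with matching allele and zygosity is a TP; a zygosity mismatch is counted
most conservatively as one FN plus one FP and itemized. Lower one-sided
confidence limits use the Clopper-Pearson exact method — the beta quantile
`Beta(α; x, n−x+1)`, which for x = n reduces to `α^(1/n)`; the
closed form and the binomial tail (`P(X ≥ x | n, p) = α` at the returned
p) are both asserted in tests as independent oracles. Reported
percentages are truncated, never rounded (a bound of 0.999237 prints as
">99.92%"); full precision is kept on the objects.

## Synthetic data

The generator emulates the study conditions rather than any particular
instrument: 96-sample batches (configurable), 2×150 paired reads, mean
depth ~1000× in production and 200–400× in desk-scale tests, base error
rate ~0.1–0.2%, amplicon count noise as negative binomial with CV 0.08
(falling back to Poisson when the CV is at the Poisson floor, and to exact
integer expectations when CV = 0 so identity cases hold to machine
precision). Reads carry barcode, then primer, then the insert of one
parental haplotype (het variants ride one haplotype, hom both), so allele
fractions are binomial over read pairs. Quality strings are flat Q38 with
a sub-Q30 tail on 5% of reads (geometric length), exercising the trimmer.

Pseudogene homologs are generated at a configurable identity (default
0.97) with one guarantee: every amplicon insert of a paired gene contains
at least one divergent position. Without it, amplicons falling in fully
shared segments would lose *all* reads to the tie-discard rule — a real
limitation of such assays (production panels use long-range PCR around
PMS2/CHEK2 for this reason) but one that would make 100%-recall test
conditions unattainable by construction. Contaminant reads are generated
with the gene's primers but the pseudogene's insert body (a mispriming
model), so they demultiplex and trim normally and are removed solely by
the alignment discard rule.

Injected variants are placed ≥10 bases from the edge of every covering
insert, at positions covered by ≥3 amplicons, away from pseudogene
divergent sites, and ≥10 bases apart: each constraint exists so that an
injected truth variant is unambiguously observable (edge placement risks
local-alignment clipping; low multiplicity inflates binomial variance of
the het fraction; divergent-site collisions confound the discard rule).
LR events scale all amplicons of the spanned regions by copy/2; dropout
events halve exactly one amplicon and restrict it to one haplotype.

What the simulator does **not** model: instrument-specific error profiles
(errors are uniform substitutions), PCR chimeras and polymerase slippage,
droplet occupancy statistics, GC-dependent amplification bias in
sequencing counts, mosaicism, and structural variants other than
whole-region deletion/duplication and single-amplicon dropout. Passing
tests therefore demonstrate the *algorithms* are correct under controlled
conditions, not that the pipeline would achieve the same figures on real
instrument data.

## Problem sizes in tests

The test suite and the acceptance script run desk-scale versions of the
validation studies, chosen as the smallest sizes at which the batch
statistics are meaningful: a 10-sample batch over a 20-region panel with
60 injected variants at depth ~200 for the sequencing study; ten
96-sample × 100-amplicon count matrices with 20 injected LR events; nine
read sets (three replicates in each of three batches) for
reproducibility; 10–12 sample CGH batches at 27 probes per region.

## Known limitations

- Mates are aligned independently; no fragment-level rescue.
- Multi-allelic positions are reduced to the dominant non-reference
  allele.
- The dosage caller reports region-level events only; breakpoints and
  inversions are out of scope.
- Historic CGH probe statistics assume the prior arrays are wild type at
  every probe; a recurrent CNV in the history would bias stage 3.
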