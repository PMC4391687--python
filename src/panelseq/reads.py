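"""Demultiplexing, trimming, pseudogene-aware alignment, and pileup building.

Reads are routed to samples by exact 6-nt barcode match, stripped of their
primer prefix, quality-trimmed at the 3' end, and locally aligned against
the full reference set (genes *and* their homologous pseudogenes).  A read
matching a pseudogene as well as or better than any gene is discarded —
ties go to the pseudogene, the conservative choice for a germline assay.

Alignment uses classic local (Smith-Waterman) scoring: match +2,
mismatch -3, gap open -5, gap extend -2, with a minimum accepted score of
0.6x the read's maximum achievable score.  A k-mer seed index restricts
full dynamic programming to candidate reference windows, and gap-free
reads take an exact/diagonal shortcut that yields the identical score.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import numpy as np
from Bio import Align

from .calling import left_normalize
from .model import BARCODE_LENGTH, PanelDefinition, ReferenceSet, SampleSheet

MATCH = 2
MISMATCH = -3
GAP_OPEN = -5
GAP_EXTEND = -2
SCORE_FLOOR_FRACTION = 0.6
Q_THRESHOLD = 30
TRIM_WINDOW = 5
SEED_K = 15
SEED_STRIDE = 12
WINDOW_PAD = 16
MAX_DIAGONAL_MISMATCHES = 5

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# Demultiplexing

@dataclass
class DemuxResult:
    by_sample: dict[str, list[tuple[str, str, str]]]
    unassigned: int
    total: int

    def conserves_reads(self) -> bool:
        routed = sum(len(v) for v in self.by_sample.values())
        return routed + self.unassigned == self.total


def demultiplex(
    reads: Iterable[tuple[str, str, str]],
    sheet: SampleSheet,
    batch_id: str | None = None,
) -> DemuxResult:
    """Route reads to samples by exact barcode prefix match; strip the barcode."""
    barcode_map = sheet.barcode_map(batch_id)
    by_sample: dict[str, list[tuple[str, str, str]]] = {
        s: [] for s in barcode_map.values()
    }
    unassigned = 0
    total = 0
    for rid, seq, qual in reads:
        total += 1
        sample = barcode_map.get(seq[:BARCODE_LENGTH])
        if sample is None:
            unassigned += 1
            continue
        by_sample[sample].append((rid, seq[BARCODE_LENGTH:], qual[BARCODE_LENGTH:]))
    return DemuxResult(by_sample=by_sample, unassigned=unassigned, total=total)


# ---------------------------------------------------------------------------
# Trimming

@dataclass(frozen=True)
class TrimmedRead:
    read_id: str
    sample_id: str
    sequence: str
    qualities: str  # Phred+33
    primer_removed: bool
    bases_trimmed: int
    amplicon_hint: str | None = None  # which primer matched
    primer_direction: str | None = None  # "fwd" | "rev"


class PrimerSet:
    """Primer lookup for prefix trimming: exact hash first, <=1-mismatch scan after."""

    def __init__(self, primers: Sequence[tuple[str, str, str]]):
        # entries: (amplicon_id, direction, primer_sequence)
        self.entries = [(a, d, p.upper()) for a, d, p in primers]
        self._exact: dict[str, tuple[str, str, int]] = {}
        self._lengths: list[int] = sorted({len(p) for _, _, p in self.entries},
                                          reverse=True)
        for a, d, p in self.entries:
            self._exact.setdefault(p, (a, d, len(p)))

    @classmethod
    def from_panel(cls, panel: PanelDefinition) -> "PrimerSet":
        entries = []
        for a in panel.amplicons:
            entries.append((a.amplicon_id, "fwd", a.forward_primer))
            entries.append((a.amplicon_id, "rev", a.reverse_primer))
        return cls(entries)

    def match_prefix(self, seq: str) -> tuple[str, str, int] | None:
        for length in self._lengths:
            hit = self._exact.get(seq[:length])
            if hit is not None:
                return hit
        # near-exact: a single mismatch anywhere in the primer
        for a, d, p in self.entries:
            if len(seq) < len(p):
                continue
            mism = sum(1 for x, y in zip(p, seq) if x != y)
            if mism <= 1:
                return (a, d, len(p))
        return None


def _quality_cut(quals: list[int], q_threshold: int) -> int:
    """3' cut point: maximal terminal run of failing sliding-window means,
    refined so the first trimmed base is itself below threshold."""
    n = len(quals)
    if n == 0:
        return 0
    if n < TRIM_WINDOW:
        cut = n
        while cut > 0 and quals[cut - 1] < q_threshold:
            cut -= 1
        return cut
    cut = n
    for i in range(n - TRIM_WINDOW, -1, -1):
        if sum(quals[i:i + TRIM_WINDOW]) / TRIM_WINDOW < q_threshold:
            cut = i
        else:
            break
    while cut < n and quals[cut] >= q_threshold:
        cut += 1
    return cut


def trim_read(
    read: tuple[str, str, str],
    sample_id: str = "",
    q_threshold: int = Q_THRESHOLD,
    primers: PrimerSet | None = None,
) -> TrimmedRead:
    """Strip a matching primer prefix, then quality-trim the 3' end.

    The 3' rule removes the maximal terminal suffix over which a sliding
    mean quality (window 5) stays below ``q_threshold``, never reordering
    interior bases.  A read may be trimmed to length 0.
    """
    rid, seq, qual = read
    if len(seq) != len(qual):
        raise ValueError(f"read {rid}: sequence/quality length mismatch")
    primer_removed = False
    amplicon_hint = None
    direction = None
    if primers is not None:
        hit = primers.match_prefix(seq)
        if hit is not None:
            amplicon_hint, direction, plen = hit
            seq, qual = seq[plen:], qual[plen:]
            primer_removed = True
    quals = [ord(c) - 33 for c in qual]
    cut = _quality_cut(quals, q_threshold)
    trimmed = len(quals) - cut
    return TrimmedRead(
        read_id=rid, sample_id=sample_id,
        sequence=seq[:cut], qualities=qual[:cut],
        primer_removed=primer_removed,
        bases_trimmed=trimmed + (len(read[1]) - len(seq)),
        amplicon_hint=amplicon_hint, primer_direction=direction,
    )


# ---------------------------------------------------------------------------
# Alignment / assignment

@dataclass
class ReadAssignment:
    read_id: str
    sample_id: str
    best_gene: str | None
    gene_score: float
    best_pseudogene: str | None
    best_pseudogene_score: float | None
    status: str  # "assigned" | "discarded_pseudogene" | "unmapped"
    strand: str = "+"
    aligned_blocks: tuple[tuple[int, int], ...] = ()  # reference intervals
    events: tuple[tuple[int, str, str], ...] = ()  # (pos, ref, alt), normalized
    multi_mapping: bool = False

    @property
    def aligned_interval(self) -> tuple[int, int] | None:
        if not self.aligned_blocks:
            return None
        return (self.aligned_blocks[0][0], self.aligned_blocks[-1][1])


class ReferenceIndex:
    """Seeded Smith-Waterman assignment against genes + pseudogenes."""

    def __init__(self, refs: ReferenceSet, k: int = SEED_K):
        self.refs = refs
        self.k = k
        self.sequences: dict[str, str] = {
            **refs.gene_sequences, **refs.pseudogene_sequences
        }
        self.is_pseudo = {name: name in refs.pseudogene_sequences
                          for name in self.sequences}
        self.partners: dict[str, list[str]] = {}
        for g, p in refs.homology_pairs:
            self.partners.setdefault(g, []).append(p)
            self.partners.setdefault(p, []).append(g)
        self._kmers: dict[str, list[tuple[str, int]]] = {}
        for name, seq in self.sequences.items():
            for i in range(0, len(seq) - k + 1):
                self._kmers.setdefault(seq[i:i + k], []).append((name, i))
        self.aligner = Align.PairwiseAligner(
            mode="local", match_score=MATCH, mismatch_score=MISMATCH,
            open_gap_score=GAP_OPEN, extend_gap_score=GAP_EXTEND,
        )

    def _candidates(self, seq: str) -> dict[str, int]:
        """Candidate references with the best-voted diagonal offset each."""
        votes: dict[str, dict[int, int]] = {}
        n = len(seq)
        positions = list(range(0, max(n - self.k, 0) + 1, SEED_STRIDE))
        if positions and positions[-1] != n - self.k and n >= self.k:
            positions.append(n - self.k)
        for qpos in positions:
            for name, rpos in self._kmers.get(seq[qpos:qpos + self.k], ()):
                diag = rpos - qpos
                votes.setdefault(name, {})[diag] = votes.get(name, {}).get(diag, 0) + 1
        return {
            name: max(diags, key=lambda d: (diags[d], -abs(d)))
            for name, diags in votes.items()
        }

    def _diagonal_score(self, ref_name: str, diag: int, seq: str):
        """Gap-free local score on a fixed diagonal (identical to SW when the
        optimum is gap-free); returns None when too divergent for the shortcut."""
        ref = self.sequences[ref_name]
        n = len(seq)
        if diag < 0 or diag + n > len(ref):
            return None
        sub = ref[diag:diag + n]
        mism = [i for i in range(n) if sub[i] != seq[i]]
        if len(mism) > MAX_DIAGONAL_MISMATCHES:
            return None
        # Kadane on +MATCH / MISMATCH values, tracking the best interval
        best = cur = 0
        best_lo = best_hi = cur_lo = 0
        for i in range(n):
            v = MATCH if sub[i] == seq[i] else MISMATCH
            if cur <= 0:
                cur, cur_lo = v, i
            else:
                cur += v
            if cur > best:
                best, best_lo, best_hi = cur, cur_lo, i + 1
        events = tuple(
            (diag + i, sub[i], seq[i]) for i in mism if best_lo <= i < best_hi
        )
        blocks = ((diag + best_lo, diag + best_hi),)
        return float(best), blocks, events

    def _window(self, ref_name: str, diag: int, read_len: int) -> tuple[int, str]:
        ref = self.sequences[ref_name]
        lo = max(0, diag - WINDOW_PAD)
        hi = min(len(ref), diag + read_len + WINDOW_PAD)
        return lo, ref[lo:hi]

    def _score_candidate(self, ref_name: str, diag: int, seq: str) -> float:
        # only a perfect diagonal match is provably the SW optimum; anything
        # else gets a score-only SW pass (the diagonal value is a lower bound)
        fast = self._diagonal_score(ref_name, diag, seq)
        if fast is not None and fast[0] == MATCH * len(seq):
            return fast[0]
        lo, window = self._window(ref_name, diag, len(seq))
        return float(self.aligner.score(window, seq))

    def _traceback(self, ref_name: str, diag: int, seq: str):
        # The diagonal score is a lower bound on the SW optimum: a gapped
        # alignment can beat it when an indel falls in a short tandem repeat
        # (the shifted copy mimics a few mismatches).  Trust the gap-free
        # representation only when it is provably optimal — a perfect match,
        # or equal to a score-only SW pass over the window.
        fast = self._diagonal_score(ref_name, diag, seq)
        if fast is not None and fast[0] == MATCH * len(seq):
            return fast
        lo, window = self._window(ref_name, diag, len(seq))
        if fast is not None and fast[0] == float(self.aligner.score(window, seq)):
            return fast
        aln = self.aligner.align(window, seq)[0]
        ref_seq = self.sequences[ref_name]
        t_blocks, q_blocks = aln.aligned
        blocks = []
        events: list[tuple[int, str, str]] = []
        for bi, ((ts, te), (qs, qe)) in enumerate(zip(t_blocks, q_blocks)):
            blocks.append((lo + int(ts), lo + int(te)))
            for off in range(te - ts):
                if window[ts + off] != seq[qs + off]:
                    events.append((lo + ts + off, window[ts + off], seq[qs + off]))
            if bi + 1 < len(t_blocks):
                nts = int(t_blocks[bi + 1][0])
                nqs = int(q_blocks[bi + 1][0])
                if nts > te and nqs == qe:  # deletion in read
                    anchor = lo + te - 1
                    if anchor >= 0:
                        ref_al = ref_seq[anchor:lo + nts]
                        events.append(left_normalize(ref_seq, anchor, ref_al,
                                                     ref_al[0]))
                elif nqs > qe and nts == te:  # insertion in read
                    anchor = lo + te - 1
                    if anchor >= 0:
                        ins = seq[qe:nqs]
                        ref_al = ref_seq[anchor]
                        events.append(left_normalize(ref_seq, anchor, ref_al,
                                                     ref_al + ins))
        return float(aln.score), tuple(blocks), tuple(events)

    def assign(self, read: TrimmedRead, strand: str = "+") -> ReadAssignment:
        """Assign one oriented read; ``strand="both"`` tries both orientations."""
        if strand == "both":
            fwd = self.assign(read, "+")
            rev = self.assign(
                TrimmedRead(read.read_id, read.sample_id, revcomp(read.sequence),
                            read.qualities[::-1], read.primer_removed,
                            read.bases_trimmed), "-",
            )
            if fwd.status == "unmapped":
                return rev
            if rev.status == "unmapped":
                return fwd
            return fwd if fwd.gene_score >= rev.gene_score else rev
        seq = read.sequence
        floor = SCORE_FLOOR_FRACTION * MATCH * len(seq)
        if not seq:
            return ReadAssignment(read.read_id, read.sample_id, None, 0.0, None,
                                  None, "unmapped", strand)
        cands = self._candidates(seq)
        # always evaluate homology partners of seeded candidates
        for name in list(cands):
            for partner in self.partners.get(name, ()):
                if partner not in cands:
                    cands[partner] = cands[name]
        scores = {name: self._score_candidate(name, diag, seq)
                  for name, diag in cands.items()}
        gene_hits = sorted(
            (n for n in scores if not self.is_pseudo[n]),
            key=lambda n: (-scores[n], n),
        )
        pseudo_hits = sorted(
            (n for n in scores if self.is_pseudo[n]),
            key=lambda n: (-scores[n], n),
        )
        best_gene = gene_hits[0] if gene_hits else None
        best_pseudo = pseudo_hits[0] if pseudo_hits else None
        pseudo_score = scores[best_pseudo] if best_pseudo else None
        gene_score = scores[best_gene] if best_gene else 0.0
        blocks: tuple = ()
        events: tuple = ()
        if best_gene is not None:
            # candidate scores may under-estimate (diagonal bound); settle
            # the winner's score exactly before applying floor/discard rules
            gene_score, blocks, events = self._traceback(
                best_gene, cands[best_gene], seq)
        if (gene_score < floor) and (pseudo_score is None or pseudo_score < floor):
            return ReadAssignment(read.read_id, read.sample_id, None, gene_score,
                                  best_pseudo, pseudo_score, "unmapped", strand)
        if pseudo_score is not None and pseudo_score >= gene_score:
            return ReadAssignment(read.read_id, read.sample_id, best_gene,
                                  gene_score, best_pseudo, pseudo_score,
                                  "discarded_pseudogene", strand)
        if gene_score < floor:
            return ReadAssignment(read.read_id, read.sample_id, None, gene_score,
                                  best_pseudo, pseudo_score, "unmapped", strand)
        multi = (len(gene_hits) > 1
                 and scores[gene_hits[1]] == scores[gene_hits[0]])
        return ReadAssignment(
            read.read_id, read.sample_id, best_gene, gene_score, best_pseudo,
            pseudo_score, "assigned", strand, blocks, events, multi,
        )


def assign_read(
    read: TrimmedRead,
    refs: ReferenceSet,
    index: ReferenceIndex | None = None,
    strand: str = "both",
) -> ReadAssignment:
    """Convenience wrapper; builds a throwaway index when none is supplied."""
    if index is None:
        index = ReferenceIndex(refs)
    return index.assign(read, strand)


# ---------------------------------------------------------------------------
# Pileup

class Pileup:
    """Per-sample, per-contig allele counts with strand split.

    Depth at a position equals the number of assigned reads whose alignment
    covers it; every read contributes exactly one allele per covered
    position (the reference base unless it carries an event there), so
    depth always equals the sum of allele counts.
    """

    def __init__(self, references: ReferenceSet):
        self.references = references
        self._depth: dict[tuple[str, str], tuple[np.ndarray, np.ndarray]] = {}
        self._events: dict[tuple[str, str], dict[int, dict]] = {}
        self.ignored_outside_panel = 0

    def samples(self) -> list[str]:
        return sorted({s for s, _ in self._depth})

    def reference_base(self, contig: str, pos: int) -> str:
        return self.references.gene_sequences[contig][pos]

    def _arrays(self, sample: str, contig: str):
        key = (sample, contig)
        if key not in self._depth:
            n = len(self.references.gene_sequences[contig])
            self._depth[key] = (np.zeros(n, dtype=np.int32),
                                np.zeros(n, dtype=np.int32))
            self._events[key] = {}
        return self._depth[key], self._events[key]

    def add(self, assignment: ReadAssignment) -> None:
        if assignment.status != "assigned" or assignment.best_gene is None:
            return
        (fwd, rev), events = self._arrays(assignment.sample_id, assignment.best_gene)
        arr = fwd if assignment.strand == "+" else rev
        si = 0 if assignment.strand == "+" else 1
        for lo, hi in assignment.aligned_blocks:
            arr[lo:hi] += 1
        for pos, ref, alt in assignment.events:
            allele = alt if len(ref) == 1 and len(alt) == 1 else (pos, ref, alt)
            slot = events.setdefault(pos, {})
            cnt = slot.setdefault(allele, [0, 0])
            cnt[si] += 1

    def depth(self, sample: str, contig: str, pos: int) -> tuple[int, int]:
        key = (sample, contig)
        if key not in self._depth:
            return (0, 0)
        fwd, rev = self._depth[key]
        if not (0 <= pos < len(fwd)):
            return (0, 0)
        return int(fwd[pos]), int(rev[pos])

    def alleles(self, sample: str, contig: str, pos: int) -> dict:
        """Allele -> (fwd, rev) counts at a position, reference included.

        SNV alleles are single-base strings; indel alleles are normalized
        (pos, ref, alt) tuples anchored at this position.
        """
        f, r = self.depth(sample, contig, pos)
        out: dict = {}
        alt_f = alt_r = 0
        slot = self._events.get((sample, contig), {}).get(pos, {})
        for allele, (af, ar) in slot.items():
            out[allele] = (af, ar)
            alt_f += af
            alt_r += ar
        ref_base = self.reference_base(contig, pos)
        ref_f = max(f - alt_f, 0)
        ref_r = max(r - alt_r, 0)
        prev = out.get(ref_base, (0, 0))
        out[ref_base] = (prev[0] + ref_f, prev[1] + ref_r)
        return out

    def non_wt_frequency(self, sample: str, contig: str, pos: int) -> float:
        f, r = self.depth(sample, contig, pos)
        depth = f + r
        if depth == 0:
            return 0.0
        ref_base = self.reference_base(contig, pos)
        alleles = self.alleles(sample, contig, pos)
        non_wt = sum(af + ar for a, (af, ar) in alleles.items() if a != ref_base)
        return non_wt / depth


def build_pileup(
    assignments: Iterable[ReadAssignment],
    panel: PanelDefinition,
    references: ReferenceSet,
) -> Pileup:
    """Accumulate assigned reads into a pileup, counting off-panel alignments."""
    pileup = Pileup(references)
    spans: dict[str, list[tuple[int, int]]] = {}
    for region in panel.regions:
        spans.setdefault(region.contig, []).append(region.span)
    for a in assignments:
        if a.status != "assigned":
            continue
        interval = a.aligned_interval
        contig_spans = spans.get(a.best_gene, [])
        if interval is None or not any(
            interval[0] < hi and lo < interval[1] for lo, hi in contig_spans
        ):
            pileup.ignored_outside_panel += 1
            continue
        pileup.add(a)
    return pileup


def iter_oriented(
    r1: Iterable[tuple[str, str, str]],
    r2: Iterable[tuple[str, str, str]],
) -> Iterator[tuple[tuple[str, str, str], str]]:
    """Yield (read, strand) with R2 reads marked reverse."""
    for read in r1:
        yield read, "+"
    for read in r2:
        yield read, "-"
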