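"""Core data model for amplicon panels, references, and samples.

Coordinates are 0-based half-open throughout; conversion to 1-based
happens only at the VCF boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator

MAX_UPSTREAM_FLANK = 20
MAX_DOWNSTREAM_FLANK = 10
BARCODE_LENGTH = 6

_VALID_BASES = frozenset("ACGTN")


class PanelValidationError(ValueError):
    """Raised when a panel, reference set, or sample sheet violates an invariant."""


def _check_nucleotides(seq: str, what: str) -> str:
    seq = seq.upper()
    if not seq:
        raise PanelValidationError(f"{what} is empty")
    bad = set(seq) - _VALID_BASES
    if bad:
        raise PanelValidationError(f"{what} contains non-nucleotide characters: {sorted(bad)}")
    return seq


@dataclass(frozen=True)
class PanelRegion:
    """A tested region of interest: typically one exon plus short intronic flanks.

    ``start``/``end`` delimit the core (exonic) interval; ``upstream_flank``
    and ``downstream_flank`` extend it by at most 20 and 10 intronic bases
    respectively.  ``span`` is the full tested interval.
    """

    gene_name: str
    region_label: str
    contig: str
    start: int
    end: int
    upstream_flank: int = 0
    downstream_flank: int = 0
    tested_by_lr: bool = True

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise PanelValidationError(
                f"region {self.gene_name}/{self.region_label}: start {self.start} >= end {self.end}"
            )
        if not (0 <= self.upstream_flank <= MAX_UPSTREAM_FLANK):
            raise PanelValidationError(
                f"region {self.gene_name}/{self.region_label}: upstream flank "
                f"{self.upstream_flank} exceeds maximum {MAX_UPSTREAM_FLANK}"
            )
        if not (0 <= self.downstream_flank <= MAX_DOWNSTREAM_FLANK):
            raise PanelValidationError(
                f"region {self.gene_name}/{self.region_label}: downstream flank "
                f"{self.downstream_flank} exceeds maximum {MAX_DOWNSTREAM_FLANK}"
            )

    @property
    def span(self) -> tuple[int, int]:
        """Full tested interval including flanks (half-open)."""
        return (self.start - self.upstream_flank, self.end + self.downstream_flank)

    @property
    def span_length(self) -> int:
        lo, hi = self.span
        return hi - lo

    @property
    def key(self) -> tuple[str, str]:
        return (self.gene_name, self.region_label)


@dataclass(frozen=True)
class AmpliconDef:
    """One PCR amplicon: primer pair plus the genomic insert between them."""

    amplicon_id: str
    contig: str
    insert_start: int
    insert_end: int
    forward_primer: str
    reverse_primer: str
    multiplex_group: str = ""

    def __post_init__(self) -> None:
        if self.insert_start >= self.insert_end:
            raise PanelValidationError(
                f"amplicon {self.amplicon_id}: empty insert "
                f"[{self.insert_start}, {self.insert_end})"
            )
        object.__setattr__(self, "forward_primer", _check_nucleotides(
            self.forward_primer, f"amplicon {self.amplicon_id} forward primer"))
        object.__setattr__(self, "reverse_primer", _check_nucleotides(
            self.reverse_primer, f"amplicon {self.amplicon_id} reverse primer"))

    def overlaps(self, region: PanelRegion) -> bool:
        if self.contig != region.contig:
            return False
        lo, hi = region.span
        return self.insert_start < hi and lo < self.insert_end


class PanelDefinition:
    """Validated collection of regions and amplicons with an overlap index."""

    def __init__(self, regions: Iterable[PanelRegion], amplicons: Iterable[AmpliconDef]):
        self.regions: list[PanelRegion] = list(regions)
        self.amplicons: list[AmpliconDef] = list(amplicons)
        seen: set[tuple[str, str]] = set()
        for r in self.regions:
            if r.key in seen:
                raise PanelValidationError(
                    f"duplicate region label {r.region_label!r} in gene {r.gene_name}"
                )
            seen.add(r.key)
        ids = [a.amplicon_id for a in self.amplicons]
        if len(ids) != len(set(ids)):
            raise PanelValidationError("duplicate amplicon ids in panel")
        # overlap index, both directions
        self.region_to_amplicons: dict[tuple[str, str], list[AmpliconDef]] = {
            r.key: [] for r in self.regions
        }
        self.amplicon_to_regions: dict[str, list[PanelRegion]] = {
            a.amplicon_id: [] for a in self.amplicons
        }
        for a in self.amplicons:
            for r in self.regions:
                if a.overlaps(r):
                    self.region_to_amplicons[r.key].append(a)
                    self.amplicon_to_regions[a.amplicon_id].append(r)

    def __eq__(self, other: object) -> bool:
        return (
            isinstance(other, PanelDefinition)
            and self.regions == other.regions
            and self.amplicons == other.amplicons
        )

    @property
    def contigs(self) -> list[str]:
        out: list[str] = []
        for r in self.regions:
            if r.contig not in out:
                out.append(r.contig)
        return out

    def regions_on(self, contig: str) -> list[PanelRegion]:
        """Regions on a contig, ordered by span start."""
        return sorted(
            (r for r in self.regions if r.contig == contig), key=lambda r: r.span[0]
        )

    def region_for_position(self, contig: str, pos: int) -> PanelRegion | None:
        for r in self.regions:
            lo, hi = r.span
            if r.contig == contig and lo <= pos < hi:
                return r
        return None

    def total_bases(self) -> int:
        """Total tested bases (union of region spans per contig)."""
        total = 0
        for contig in self.contigs:
            covered: set[int] = set()
            for r in self.regions_on(contig):
                lo, hi = r.span
                covered.update(range(lo, hi))
            total += len(covered)
        return total

    def iter_positions(self) -> Iterator[tuple[str, int]]:
        """All tested (contig, position) pairs, deduplicated, sorted."""
        for contig in self.contigs:
            covered: set[int] = set()
            for r in self.regions_on(contig):
                lo, hi = r.span
                covered.update(range(lo, hi))
            for pos in sorted(covered):
                yield contig, pos


@dataclass
class ReferenceSet:
    """Gene and pseudogene reference sequences with homology pairing.

    ``divergent_positions`` (optional, filled by the simulator) records, per
    paired gene, the positions where gene and pseudogene differ.
    """

    gene_sequences: dict[str, str]
    pseudogene_sequences: dict[str, str] = field(default_factory=dict)
    homology_pairs: list[tuple[str, str]] = field(default_factory=list)
    divergent_positions: dict[str, list[int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        overlap = set(self.gene_sequences) & set(self.pseudogene_sequences)
        if overlap:
            raise PanelValidationError(
                f"identifiers present as both gene and pseudogene: {sorted(overlap)}"
            )
        self.gene_sequences = {
            k: _check_nucleotides(v, f"gene {k}") for k, v in self.gene_sequences.items()
        }
        self.pseudogene_sequences = {
            k: _check_nucleotides(v, f"pseudogene {k}")
            for k, v in self.pseudogene_sequences.items()
        }
        for gene, pseudo in self.homology_pairs:
            if gene not in self.gene_sequences:
                raise PanelValidationError(f"homology pair references unknown gene {gene!r}")
            if pseudo not in self.pseudogene_sequences:
                raise PanelValidationError(
                    f"homology pair references unknown pseudogene {pseudo!r}"
                )

    def pseudogenes_for(self, gene: str) -> list[str]:
        return [p for g, p in self.homology_pairs if g == gene]


@dataclass(frozen=True)
class SampleEntry:
    sample_id: str
    barcode: str
    batch_id: str

    def __post_init__(self) -> None:
        if len(self.barcode) != BARCODE_LENGTH:
            raise PanelValidationError(
                f"sample {self.sample_id}: barcode {self.barcode!r} is not "
                f"{BARCODE_LENGTH} nt"
            )
        object.__setattr__(
            self, "barcode", _check_nucleotides(self.barcode, f"barcode of {self.sample_id}")
        )


class SampleSheet:
    """Sample-to-barcode assignments; barcodes must be unique within a batch."""

    def __init__(self, entries: Iterable[SampleEntry]):
        self.entries: list[SampleEntry] = list(entries)
        seen: dict[tuple[str, str], str] = {}
        for e in self.entries:
            key = (e.batch_id, e.barcode)
            if key in seen:
                raise PanelValidationError(
                    f"barcode {e.barcode} duplicated in batch {e.batch_id} "
                    f"(samples {seen[key]} and {e.sample_id})"
                )
            seen[key] = e.sample_id

    def __len__(self) -> int:
        return len(self.entries)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, SampleSheet) and self.entries == other.entries

    def barcode_map(self, batch_id: str | None = None) -> dict[str, str]:
        """barcode -> sample_id, optionally restricted to one batch."""
        return {
            e.barcode: e.sample_id
            for e in self.entries
            if batch_id is None or e.batch_id == batch_id
        }
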