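"""Threshold-based germline variant calling from pileup allele frequencies.

The caller is deliberately non-probabilistic: zygosity is assigned from the
non-wild-type allele frequency through fixed bands, mirroring a
review-software workflow in which intermediate frequencies are not called
but flagged for orthogonal (Sanger) confirmation.

Frequency bands (lower-inclusive, half-open; the top band is closed):

    [0.00, 0.10)  noise          — attributed to sequencing error, no output
    [0.10, 0.30)  flagged_low    — flagged for confirmation
    [0.30, 0.70)  heterozygous   — called het
    [0.70, 0.90)  flagged_high   — flagged for confirmation
    [0.90, 1.00]  homozygous     — called hom
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import TYPE_CHECKING

if TYPE_CHECKING:  # pragma: no cover
    from .model import PanelDefinition
    from .reads import Pileup

DEFAULT_MIN_DEPTH = 50

NOISE_MAX = 0.10
HET_MIN = 0.30
HET_MAX = 0.70
HOM_MIN = 0.90


class FrequencyBand(str, Enum):
    NOISE = "noise"
    FLAGGED_LOW = "flagged_low"
    HETEROZYGOUS = "heterozygous"
    FLAGGED_HIGH = "flagged_high"
    HOMOZYGOUS = "homozygous"


class Zygosity(str, Enum):
    HETEROZYGOUS = "heterozygous"
    HOMOZYGOUS = "homozygous"


class CallStatus(str, Enum):
    CALLED = "called"
    FLAGGED = "flagged_for_confirmation"


_BAND_ORDER = [
    FrequencyBand.NOISE,
    FrequencyBand.FLAGGED_LOW,
    FrequencyBand.HETEROZYGOUS,
    FrequencyBand.FLAGGED_HIGH,
    FrequencyBand.HOMOZYGOUS,
]


def classify_frequency(non_wt_frequency: float) -> FrequencyBand:
    """Classify a non-wild-type allele frequency into its zygosity band."""
    f = float(non_wt_frequency)
    if not (0.0 <= f <= 1.0):
        raise ValueError(f"non-wild-type frequency {f} outside [0, 1]")
    if f < NOISE_MAX:
        return FrequencyBand.NOISE
    if f < HET_MIN:
        return FrequencyBand.FLAGGED_LOW
    if f < HET_MAX:
        return FrequencyBand.HETEROZYGOUS
    if f < HOM_MIN:
        return FrequencyBand.FLAGGED_HIGH
    return FrequencyBand.HOMOZYGOUS


def band_index(band: FrequencyBand) -> int:
    return _BAND_ORDER.index(band)


@dataclass(frozen=True)
class BaseCallSummary:
    sample_id: str
    contig: str
    position: int  # 0-based
    ref_allele: str
    alt_allele: str | None
    depth: int
    non_wt_frequency: float
    forward_depth: int
    reverse_depth: int

    def __post_init__(self) -> None:
        if not (0.0 <= self.non_wt_frequency <= 1.0):
            raise ValueError("non_wt_frequency outside [0, 1]")
        if self.depth != self.forward_depth + self.reverse_depth:
            raise ValueError("depth must equal forward_depth + reverse_depth")


@dataclass(frozen=True)
class VariantCall:
    sample_id: str
    contig: str
    position: int  # 0-based; VCF conversion happens at write time
    ref_allele: str
    alt_allele: str
    zygosity: Zygosity
    status: CallStatus
    depth: int
    non_wt_frequency: float
    forward_depth: int = 0
    reverse_depth: int = 0
    alt_forward: int = 0
    alt_reverse: int = 0

    @property
    def key(self) -> tuple[str, str, int, str, str]:
        return (self.sample_id, self.contig, self.position, self.ref_allele, self.alt_allele)


@dataclass(frozen=True)
class CoverageFlag:
    """A region whose minimum per-base depth fell below the calling threshold."""

    sample_id: str
    gene_name: str
    region_label: str
    contig: str
    span_start: int
    span_end: int
    min_depth: int


def left_normalize(
    contig_seq: str, pos: int, ref: str, alt: str
) -> tuple[int, str, str]:
    """Left-align and parsimony-trim an indel against its contig sequence.

    Standard VCF normalization: trim shared trailing bases (extending left
    through the reference when one allele would empty), then trim shared
    leading bases while both alleles keep an anchor base.
    """
    ref = ref.upper()
    alt = alt.upper()
    if len(ref) == 1 and len(alt) == 1:
        return pos, ref, alt
    while True:
        if len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
            ref, alt = ref[:-1], alt[:-1]
        elif ref and alt and ref[-1] == alt[-1] and pos > 0:
            prev = contig_seq[pos - 1].upper()
            ref = prev + ref[:-1]
            alt = prev + alt[:-1]
            pos -= 1
        else:
            break
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    return pos, ref, alt


def call_variants(
    pileup: "Pileup",
    panel: "PanelDefinition",
    min_depth: int = DEFAULT_MIN_DEPTH,
) -> tuple[list[VariantCall], list[CoverageFlag]]:
    """Classify every tested base of every sample; emit calls and coverage flags.

    Per position the single most frequent non-reference allele is classified
    through :func:`classify_frequency`; het/hom bands yield called variants,
    intermediate bands yield variants flagged for confirmation, and the noise
    band yields nothing.  Any region containing a base below ``min_depth``
    (including uncovered bases, depth 0) produces one :class:`CoverageFlag`
    keyed by the region's minimum depth.
    """
    calls: list[VariantCall] = []
    flags: list[CoverageFlag] = []
    for sample_id in pileup.samples():
        for region in panel.regions:
            lo, hi = region.span
            region_min = None
            for pos in range(lo, hi):
                fwd, rev = pileup.depth(sample_id, region.contig, pos)
                depth = fwd + rev
                region_min = depth if region_min is None else min(region_min, depth)
                if depth < min_depth:
                    # below the calling floor the base is not callable; the
                    # region is flagged and repeated orthogonally instead
                    continue
                alleles = pileup.alleles(sample_id, region.contig, pos)
                ref_base = pileup.reference_base(region.contig, pos)
                best = None
                for allele, (af, ar) in alleles.items():
                    if allele == ref_base:
                        continue
                    if best is None or af + ar > best[1]:
                        best = (allele, af + ar, af, ar)
                if best is None:
                    continue
                allele, alt_count, alt_f, alt_r = best
                freq = alt_count / depth
                band = classify_frequency(freq)
                if band == FrequencyBand.NOISE:
                    continue
                if band == FrequencyBand.HETEROZYGOUS:
                    zyg, status = Zygosity.HETEROZYGOUS, CallStatus.CALLED
                elif band == FrequencyBand.HOMOZYGOUS:
                    zyg, status = Zygosity.HOMOZYGOUS, CallStatus.CALLED
                elif band == FrequencyBand.FLAGGED_LOW:
                    zyg, status = Zygosity.HETEROZYGOUS, CallStatus.FLAGGED
                else:  # FLAGGED_HIGH
                    zyg, status = Zygosity.HOMOZYGOUS, CallStatus.FLAGGED
                if isinstance(allele, tuple):
                    v_pos, v_ref, v_alt = allele
                else:
                    v_pos, v_ref, v_alt = pos, ref_base, allele
                calls.append(
                    VariantCall(
                        sample_id=sample_id,
                        contig=region.contig,
                        position=v_pos,
                        ref_allele=v_ref,
                        alt_allele=v_alt,
                        zygosity=zyg,
                        status=status,
                        depth=depth,
                        non_wt_frequency=freq,
                        forward_depth=fwd,
                        reverse_depth=rev,
                        alt_forward=alt_f,
                        alt_reverse=alt_r,
                    )
                )
            if region_min is not None and region_min < min_depth:
                flags.append(
                    CoverageFlag(
                        sample_id=sample_id,
                        gene_name=region.gene_name,
                        region_label=region.region_label,
                        contig=region.contig,
                        span_start=lo,
                        span_end=hi,
                        min_depth=region_min,
                    )
                )
    # dedupe: an indel allele may be attributed to several pileup anchor
    # positions only if representations differ; keys are already normalized,
    # so identical (sample, contig, pos, ref, alt) can only arise once.
    calls.sort(key=lambda c: (c.sample_id, c.contig, c.position, c.ref_allele, c.alt_allele))
    return calls, flags


def flag_strand_imbalance(call: VariantCall, min_per_strand: int = 3) -> bool:
    """Advisory flag: alt allele supported by too few reads on either strand."""
    return call.alt_forward < min_per_strand or call.alt_reverse < min_per_strand
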