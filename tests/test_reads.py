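"""Demultiplexing, trimming, pseudogene-aware assignment, and pileups."""

import numpy as np
import pytest

from panelseq.model import ReferenceSet
from panelseq.reads import (
    Pileup,
    PrimerSet,
    ReadAssignment,
    ReferenceIndex,
    assign_read,
    build_pileup,
    demultiplex,
    revcomp,
    trim_read,
    TrimmedRead,
)

Q40 = chr(40 + 33)
Q2 = chr(2 + 33)


class TestDemultiplex:
    def test_exact_match_routes_and_strips(self, tiny_sheet):
        reads = [("r1", "ACGTAC" + "GGGG", Q40 * 10)]
        res = demultiplex(reads, tiny_sheet)
        assert res.by_sample["S1"] == [("r1", "GGGG", Q40 * 4)]
        assert res.unassigned == 0

    def test_one_mismatch_goes_to_unassigned(self, tiny_sheet):
        res = demultiplex([("r1", "ACGTAA" + "GGGG", Q40 * 10)], tiny_sheet)
        assert res.unassigned == 1
        assert all(not v for v in res.by_sample.values())

    def test_empty_input_conserves_zero(self, tiny_sheet):
        res = demultiplex([], tiny_sheet)
        assert res.total == 0 and res.unassigned == 0
        assert res.conserves_reads()

    def test_read_conservation(self, tiny_sheet):
        reads = [("a", "ACGTAC" + "AAAA", Q40 * 10),
                 ("b", "TTGGCC" + "AAAA", Q40 * 10),
                 ("c", "NNNNNN" + "AAAA", Q40 * 10)]
        res = demultiplex(reads, tiny_sheet)
        assert res.conserves_reads()
        assert res.total == 3 and res.unassigned == 1


class TestTrim:
    def test_high_quality_read_untouched(self):
        tr = trim_read(("r", "ACGTACGTAC", Q40 * 10))
        assert tr.sequence == "ACGTACGTAC"
        assert tr.bases_trimmed == 0

    def test_low_quality_tail_removed_exactly(self):
        seq = "A" * 30
        qual = Q40 * 20 + Q2 * 10
        tr = trim_read(("r", seq, qual))
        assert len(tr.sequence) == 20
        assert tr.bases_trimmed == 10

    def test_primer_prefix_stripped(self):
        primers = PrimerSet([("amp1", "fwd", "ACGTACGTACGTACGTACGT")])
        seq = "ACGTACGTACGTACGTACGT" + "TTTTCCCC"
        tr = trim_read(("r", seq, Q40 * len(seq)), primers=primers)
        assert tr.primer_removed
        assert tr.sequence == "TTTTCCCC"
        assert tr.amplicon_hint == "amp1"

    def test_primer_with_single_mismatch_still_stripped(self):
        primers = PrimerSet([("amp1", "fwd", "ACGTACGTACGTACGTACGT")])
        seq = "ACGTACGTACCTACGTACGT" + "TTTT"
        tr = trim_read(("r", seq, Q40 * len(seq)), primers=primers)
        assert tr.primer_removed

    def test_read_equal_to_primer_trims_to_empty(self):
        primers = PrimerSet([("amp1", "fwd", "ACGTACGTACGTACGTACGT")])
        tr = trim_read(("r", "ACGTACGTACGTACGTACGT", Q40 * 20), primers=primers)
        assert tr.primer_removed
        assert tr.sequence == ""

    def test_interior_order_never_altered(self):
        seq = "ACGTGGTTCA"
        tr = trim_read(("r", seq, Q40 * 7 + Q2 * 3))
        assert seq.startswith(tr.sequence)


class TestAssignment:
    def test_read_matching_gene_better_is_assigned(self, tiny_refs):
        # 150 nt around divergent position 150: pseudogene differs there
        seq = tiny_refs.gene_sequences["GENE_A"][100:250]
        tr = TrimmedRead("r", "S1", seq, Q40 * len(seq), True, 0)
        a = assign_read(tr, tiny_refs, strand="+")
        assert a.status == "assigned"
        assert a.best_gene == "GENE_A"
        assert a.gene_score > a.best_pseudogene_score

    def test_tie_on_shared_segment_discarded(self, tiny_refs):
        # positions 96..149 contain no divergent site: exact tie
        seq = tiny_refs.gene_sequences["GENE_A"][96:146]
        assert seq == tiny_refs.pseudogene_sequences["PSEUDO_A"][96:146]
        tr = TrimmedRead("r", "S1", seq, Q40 * len(seq), True, 0)
        a = assign_read(tr, tiny_refs, strand="+")
        assert a.status == "discarded_pseudogene"

    def test_pseudogene_origin_read_discarded(self, tiny_refs):
        seq = tiny_refs.pseudogene_sequences["PSEUDO_A"][100:250]
        tr = TrimmedRead("r", "S1", seq, Q40 * len(seq), True, 0)
        a = assign_read(tr, tiny_refs, strand="+")
        assert a.status == "discarded_pseudogene"
        assert a.best_pseudogene_score > a.gene_score

    def test_empty_and_garbage_reads_unmapped(self, tiny_refs):
        idx = ReferenceIndex(tiny_refs)
        empty = TrimmedRead("r", "S1", "", "", False, 0)
        assert idx.assign(empty).status == "unmapped"
        junk = TrimmedRead("r", "S1", "AT" * 40, Q40 * 80, False, 0)
        assert idx.assign(junk).status == "unmapped"

    def test_reverse_orientation_found_with_both_strands(self, tiny_refs):
        seq = revcomp(tiny_refs.gene_sequences["GENE_A"][100:250])
        tr = TrimmedRead("r", "S1", seq, Q40 * len(seq), True, 0)
        a = assign_read(tr, tiny_refs, strand="both")
        assert a.status == "assigned"
        assert a.strand == "-"

    def test_diagonal_fast_path_matches_full_aligner(self, tiny_refs):
        # a read with 3 scattered mismatches takes the Kadane shortcut;
        # oracle: unrestricted PairwiseAligner score on the full gene
        from Bio import Align

        idx = ReferenceIndex(tiny_refs)
        gene = tiny_refs.gene_sequences["GENE_A"]
        read = list(gene[60:210])
        for rel in (40, 80, 120):
            read[rel] = {"A": "G", "G": "A", "C": "T", "T": "C"}[read[rel]]
        read = "".join(read)
        tr = TrimmedRead("r", "S1", read, Q40 * len(read), True, 0)
        a = idx.assign(tr, "+")
        full = Align.PairwiseAligner(mode="local", match_score=2,
                                     mismatch_score=-3, open_gap_score=-5,
                                     extend_gap_score=-2)
        assert a.gene_score == full.score(gene, read)
        assert {e[0] for e in a.events} == {100, 140, 180}

    def test_indel_read_yields_normalized_event(self, tiny_refs):
        gene = tiny_refs.gene_sequences["GENE_A"]
        # delete 2 bases at position 130
        read = gene[60:130] + gene[132:210]
        tr = TrimmedRead("r", "S1", read, Q40 * len(read), True, 0)
        a = assign_read(tr, tiny_refs, strand="+")
        assert a.status == "assigned"
        dels = [e for e in a.events if len(e[1]) > len(e[2])]
        assert len(dels) == 1
        pos, ref, alt = dels[0]
        # left-normalized: re-normalizing is a no-op
        from panelseq.calling import left_normalize
        assert left_normalize(gene, pos, ref, alt) == (pos, ref, alt)
        # the deletion removes gene[130:132] up to left-shift equivalence
        rebuilt = gene[:pos] + alt + gene[pos + len(ref):]
        assert rebuilt == gene[:130] + gene[132:]


class TestPileup:
    def _assignment(self, sample, pos_lo, pos_hi, events=(), strand="+"):
        return ReadAssignment(
            read_id="r", sample_id=sample, best_gene="GENE_A", gene_score=100,
            best_pseudogene=None, best_pseudogene_score=None, status="assigned",
            strand=strand, aligned_blocks=((pos_lo, pos_hi),),
            events=tuple(events),
        )

    def test_depth_and_ref_counts(self, tiny_panel, tiny_refs):
        asg = [self._assignment("S1", 100, 200) for _ in range(100)]
        pile = build_pileup(asg, tiny_panel, tiny_refs)
        ref = tiny_refs.gene_sequences["GENE_A"][150]
        assert pile.depth("S1", "GENE_A", 150) == (100, 0)
        assert pile.alleles("S1", "GENE_A", 150)[ref] == (100, 0)

    def test_non_wt_frequency(self, tiny_panel, tiny_refs):
        ref = tiny_refs.gene_sequences["GENE_A"][150]
        alt = "A" if ref != "A" else "C"
        asg = [self._assignment("S1", 100, 200) for _ in range(60)]
        asg += [self._assignment("S1", 100, 200, events=[(150, ref, alt)])
                for _ in range(40)]
        pile = build_pileup(asg, tiny_panel, tiny_refs)
        assert pile.non_wt_frequency("S1", "GENE_A", 150) == pytest.approx(0.40)
        assert pile.alleles("S1", "GENE_A", 150)[alt] == (40, 0)

    def test_depth_equals_sum_of_allele_counts(self, tiny_panel, tiny_refs):
        ref = tiny_refs.gene_sequences["GENE_A"][150]
        alt = "A" if ref != "A" else "C"
        asg = [self._assignment("S1", 100, 200, strand=s) for s in "+-+"]
        asg.append(self._assignment("S1", 100, 200, events=[(150, ref, alt)],
                                    strand="-"))
        pile = build_pileup(asg, tiny_panel, tiny_refs)
        f, r = pile.depth("S1", "GENE_A", 150)
        total = sum(af + ar for af, ar in
                    pile.alleles("S1", "GENE_A", 150).values())
        assert f + r == total == 4

    def test_depth_bounded_by_overlapping_reads_brute_force(
            self, tiny_panel, tiny_refs):
        rng = np.random.default_rng(0)
        asg = []
        for _ in range(50):
            lo = int(rng.integers(80, 180))
            asg.append(self._assignment("S1", lo, lo + 40))
        pile = build_pileup(asg, tiny_panel, tiny_refs)
        for pos in range(80, 210):
            brute = sum(1 for a in asg
                        if a.aligned_blocks[0][0] <= pos < a.aligned_blocks[0][1])
            f, r = pile.depth("S1", "GENE_A", pos)
            assert f + r == brute

    def test_off_panel_assignment_counted_not_piled(self, tiny_panel, tiny_refs):
        # tiny_panel spans [80, 210); an alignment at [0, 40) is off-panel
        asg = [self._assignment("S1", 0, 40)]
        pile = build_pileup(asg, tiny_panel, tiny_refs)
        assert pile.ignored_outside_panel == 1
        assert pile.depth("S1", "GENE_A", 20) == (0, 0)


class TestContaminationSurvival:
    def test_contaminant_reads_never_survive_assignment(self):
        """Every pseudogene-origin read overlapping a divergent site is
        discarded; with divergence guaranteed per insert, contamination
        cannot leak into pileups."""
        from panelseq.simulate import SimulationConfig, simulate_panel
        cfg = SimulationConfig(seed=11, n_genes=2, regions_per_gene=2,
                               n_pseudogenes=2)
        panel, refs = simulate_panel(cfg)
        idx = ReferenceIndex(refs)
        rng = np.random.default_rng(1)
        for gene, pseudo in refs.homology_pairs:
            pseq = refs.pseudogene_sequences[pseudo]
            div = refs.divergent_positions[gene]
            for _ in range(25):
                lo = int(rng.integers(0, len(pseq) - 80))
                if not any(lo <= d < lo + 80 for d in div):
                    continue  # shared segment: tie-discard covered elsewhere
                tr = TrimmedRead("r", "S1", pseq[lo:lo + 80], Q40 * 80, True, 0)
                a = idx.assign(tr, "+")
                assert a.status == "discarded_pseudogene"
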