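import pytest
from hypothesis import settings

from panelseq.model import (
    AmpliconDef,
    PanelDefinition,
    PanelRegion,
    ReferenceSet,
    SampleEntry,
    SampleSheet,
)

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture
def tiny_panel() -> PanelDefinition:
    """One gene, one region [100, 200) + flanks, five tiled amplicons."""
    region = PanelRegion(
        gene_name="GENE_A", region_label="exon 1", contig="GENE_A",
        start=100, end=200, upstream_flank=20, downstream_flank=10,
    )
    amplicons = [
        AmpliconDef(
            amplicon_id=f"amp{i}", contig="GENE_A",
            insert_start=80 + i * 15, insert_end=80 + i * 15 + 70,
            forward_primer="ACGTACGTACGTACGTACGT",
            reverse_primer="TGCATGCATGCATGCATGCA",
            multiplex_group="mg0",
        )
        for i in range(5)
    ]
    return PanelDefinition([region], amplicons)


@pytest.fixture
def tiny_refs() -> ReferenceSet:
    import numpy as np

    rng = np.random.default_rng(7)
    seq = "".join("ACGT"[i] for i in rng.integers(0, 4, 300))
    pseudo = list(seq)
    for p in (40, 95, 150, 205, 260):
        pseudo[p] = {"A": "C", "C": "G", "G": "T", "T": "A"}[pseudo[p]]
    return ReferenceSet(
        gene_sequences={"GENE_A": seq},
        pseudogene_sequences={"PSEUDO_A": "".join(pseudo)},
        homology_pairs=[("GENE_A", "PSEUDO_A")],
        divergent_positions={"GENE_A": [40, 95, 150, 205, 260]},
    )


@pytest.fixture
def tiny_sheet() -> SampleSheet:
    return SampleSheet([
        SampleEntry("S1", "ACGTAC", "b1"),
        SampleEntry("S2", "TTGGCC", "b1"),
    ])
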