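import pytest

from splicepep import (
    GenomeSequence,
    TranscriptModel,
    build_coding_transcripts,
    enumerate_junctions,
)
from splicepep.simulate import SyntheticConfig, generate_genome

# hand-built two-exon gene: CDS ATGAA|GTAA -> protein MK, junction phase 2,
# boundary codon AAG (K) split 2+1 across the junction
TWOEXON_SEQ = "ATGAA" + "GTCCCAG" + "GTAA"


@pytest.fixture
def twoexon_plus():
    genome = GenomeSequence({"chr1": TWOEXON_SEQ})
    model = TranscriptModel("t1", "g1", "chr1", "+", [(0, 5), (12, 16)], 0, 16)
    return genome, model


@pytest.fixture
def twoexon_minus():
    from splicepep import revcomp

    seq = revcomp(TWOEXON_SEQ)
    # mirrored coordinates over length 16
    genome = GenomeSequence({"chr1": seq})
    model = TranscriptModel("t1", "g1", "chr1", "-", [(0, 4), (11, 16)], 0, 16)
    return genome, model


def make_pipeline(config: SyntheticConfig):
    """Generate a genome and run it through annotation parsing."""
    syn = generate_genome(config)
    cts = build_coding_transcripts(syn.models, syn.genome)
    jcts = enumerate_junctions(cts)
    return syn, cts, jcts


@pytest.fixture(scope="session")
def syn_mid():
    """Medium synthetic genome shared across read-only tests."""
    return make_pipeline(SyntheticConfig(n_genes=200, p_boundary_kr=0.5,
                                         seed=11, p_extra_isoform=0.25))


@pytest.fixture(scope="session")
def syn_unbiased():
    """No boundary bias: boundary codons drawn at the background K/R rate
    (8/61 under uniform sense-codon usage), ~10k junctions."""
    return make_pipeline(SyntheticConfig(n_genes=2300, p_boundary_kr=8 / 61,
                                         phase_weights=(1 / 3, 1 / 3, 1 / 3),
                                         seed=23))
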