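import pytest
from hypothesis import settings

import ltspop as lp
from ltspop.pipeline import analyze_clones

settings.register_profile("suite", deadline=None, derandomize=True,
                          max_examples=50)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def sim_default():
    """One default-config simulated panel, shared across tests."""
    return lp.simulate_ltsp(seed=11)


@pytest.fixture(scope="session")
def sim_analysis(sim_default):
    """Full pipeline run on the shared simulated panel."""
    return analyze_clones(sim_default.clones)


@pytest.fixture()
def tiny_reference():
    """60 bp genome, one + strand gene [10, 27], one - strand gene [40, 48].

    Plus-strand gene codons: ATG AAA TCT GGC CTG TAA
    Minus-strand gene (its own frame): ATG CCC TAA
    """
    plus_gene = "ATGAAATCTGGCCTGTAA"
    minus_gene_rc = "TTAGGGCAT"  # revcomp of ATG CCC TAA
    seq = ("T" * 9 + plus_gene + "ACGTACGTACGT"[:12]
           + minus_gene_rc + "A" * (60 - 9 - 18 - 12 - 9))
    genes = [lp.Gene("plusA", 10, 27, "+"),
             lp.Gene("minusB", 40, 48, "-")]
    return lp.ReferenceModel(60, genes, sequence=seq)
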