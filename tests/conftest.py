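import pytest

import tcrweave as tw

#: fixed seeds so every run regenerates identical synthetic data
REF_SEED = 0
SIM_SEED = 11


@pytest.fixture(scope="session")
def ref():
    return tw.fixture_reference(REF_SEED)


@pytest.fixture(scope="session")
def tag_index(ref):
    return tw.build_tag_index(ref)


@pytest.fixture(scope="session")
def sims(ref):
    """A medium simulated beta-chain repertoire shared across tests."""
    return tw.simulate_repertoire(ref, tw.SimParams(n=300, seed=SIM_SEED))


@pytest.fixture(scope="session")
def mini_ref():
    """Tiny hand-checkable reference with known junction arithmetic.

    The V translates to MVYFCASS (conserved Cys at residue 4) and the J to
    NYGYTFGQGT (conserved Phe at residue 5), so junction attribution for
    e.g. CASSLNYGYTF can be verified by hand.
    """
    records = [
        tw.SegmentRecord(tw.GeneIdentifier("TRBV9", "01"),
                         tw.SegmentType.VARIABLE, "F",
                         "ATGGTGTATTTCTGTGCCAGCAGC"),   # MVYFCASS
        tw.SegmentRecord(tw.GeneIdentifier("TRBV9", "01"),
                         tw.SegmentType.LEADER, "F", "ATGGCC"),
        tw.SegmentRecord(tw.GeneIdentifier("TRBJ2-7", "01"),
                         tw.SegmentType.JOINING, "F",
                         "AACTATGGCTACACCTTCGGGCAAGGGACC"),  # NYGYTFGQGT
        tw.SegmentRecord(tw.GeneIdentifier("TRBC1", "01"),
                         tw.SegmentType.CONSTANT, "F", "GAAGATCTGTAA"),
        tw.SegmentRecord(tw.GeneIdentifier("TRBC2", "01"),
                         tw.SegmentType.CONSTANT, "F", "GAAGACCTGTAA"),
    ]
    return tw.ReferenceSet("human", records, tw.packaged_codon_table())
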