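"""Shared fixtures: a hand-built toy plastome and simulator outputs."""

import pytest

from plastedit.plastome import ANTISENSE, SENSE, GeneModel, Plastome, revcomp


def _spacer(n, motif="ACGT"):
    return (motif * (n // len(motif) + 1))[:n]


@pytest.fixture(scope="session")
def toy_plastome():
    """Three genes: sense atpA (101–109), antisense ndhB (201–209, genomic
    TTACGCCAT so its CDS is ATGGCGTAA), and a two-exon antisense rps16
    (CDS ATGTCAGGCCGATAA split by a 12-base intron at 301–334)."""
    atpA = "ATGGCATAA"
    ndhB_genomic = "TTACGCCAT"  # revcomp -> ATGGCGTAA
    rps16_cds = "ATGTCAGGCCGATAA"
    rps16_block = revcomp(rps16_cds)  # genomic orientation, 15 nt
    intron = "ACGTACGTACGT"
    seq = (_spacer(100) + atpA + _spacer(91) + ndhB_genomic + _spacer(91)
           + rps16_block[:8] + intron + rps16_block[8:] + _spacer(66))
    genes = [
        GeneModel("atpA", SENSE, ((101, 109),)),
        GeneModel("ndhB", ANTISENSE, ((201, 209),)),
        GeneModel("rps16", ANTISENSE, ((301, 308), (321, 327))),
    ]
    return Plastome("toy", seq, len(seq), genes)


@pytest.fixture(scope="session")
def sim_plastome():
    from plastedit.simulate import make_plastome

    return make_plastome(seed=11)


@pytest.fixture(scope="session")
def sim_counts(sim_plastome):
    from plastedit.simulate import make_plan, simulate_counts

    plan = make_plan(sim_plastome, 8, ["Leaf", "Seed"], efficiency=(20.0, 95.0),
                     seed=7)
    tables, ledger = simulate_counts(
        sim_plastome, plan, depth=100, error_rate=0.0,
        replicates={"Leaf": 2, "Seed": 2}, seed=5)
    return plan, tables, ledger
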