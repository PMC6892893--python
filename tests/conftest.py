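import pytest

from casforge import (
    Msa,
    ParentRecord,
    SimFamilyConfig,
    conservation_profile,
    select_junctions,
    simulate_parent_family,
)


@pytest.fixture(scope="session")
def toy_parents():
    """Three short parents with identical residues at segment boundaries."""
    # conserved 'W' and 'Y' columns make clean junction points
    proteins = {
        "A": "MAAAWAAAYAAA",
        "B": "MCCCWCCCYCCC",
        "C": "MDDDWDDDYDDD",
    }
    codon = {
        "M": "ATG", "A": "GCT", "C": "TGT", "D": "GAT", "W": "TGG", "Y": "TAT",
    }
    return [
        ParentRecord(
            id=pid,
            protein_seq=seq,
            cds_seq="".join(codon[a] for a in seq),
        )
        for pid, seq in proteins.items()
    ]


@pytest.fixture(scope="session")
def toy_msa(toy_parents):
    return Msa(rows=tuple((p.id, p.protein_seq) for p in toy_parents))


@pytest.fixture(scope="session")
def toy_junctions(toy_msa):
    """Two junctions at the conserved W (residue 4) and Y (residue 8)."""
    profile = conservation_profile(toy_msa, window=1)
    js = select_junctions(profile, toy_msa, min_segment_nt=9, max_junctions=2)
    assert [j.aln_column for j in js] == [5, 9]
    return js


@pytest.fixture(scope="session")
def small_family():
    """A compact simulated ortholog family shared across tests."""
    return simulate_parent_family(
        SimFamilyConfig(
            n_parents=5,
            protein_length=300,
            n_conserved_blocks=3,
            block_length=15,
            seed=11,
        )
    )
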