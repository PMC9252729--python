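import numpy as np
import pytest

from omegafeat.fixtures import (
    build_peptide,
    generate_fixtures,
    peptide_to_pdb,
)
from omegafeat.records import SequenceRecord, SequenceSet


@pytest.fixture(scope="session")
def fixtures():
    return generate_fixtures(seed=1, n_seq=6, seq_len=50)


@pytest.fixture(scope="session")
def protein_set(fixtures):
    return fixtures["protein"]


@pytest.fixture(scope="session")
def dna_set(fixtures):
    return fixtures["dna"]


@pytest.fixture(scope="session")
def rna_set(fixtures):
    return fixtures["rna"]


@pytest.fixture(scope="session")
def toy_model(fixtures):
    from omegafeat.structure import parse_structure

    return parse_structure(fixtures["structure_pdb"])


@pytest.fixture(scope="session")
def molecules(fixtures):
    from omegafeat.ligand import parse_molecules

    return parse_molecules(fixtures["smiles"])


@pytest.fixture(scope="session")
def helix_model():
    from omegafeat.structure import parse_structure

    return parse_structure(peptide_to_pdb(build_peptide("A" * 20, -57, -47)))


@pytest.fixture(scope="session")
def extended_model():
    from omegafeat.structure import parse_structure

    return parse_structure(peptide_to_pdb(build_peptide("A" * 20, -139, 135)))


def random_protein(rng: np.random.Generator, length: int) -> str:
    from omegafeat.tables import AA

    return "".join(rng.choice(list(AA), size=length))


def random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=length))


def make_set(seqs, kind: str, labels=None) -> SequenceSet:
    records = [
        SequenceRecord(
            f"s{i + 1}", kind, s,
            None if labels is None else labels[i],
        )
        for i, s in enumerate(seqs)
    ]
    return SequenceSet(records, kind)
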