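import numpy as np
import pytest

from metabotree import (
    OrgMatrix,
    ReactionCatalog,
    generate_clade_matrix,
    table5_fixture,
    two_clade_spec,
)


@pytest.fixture
def toy_pair():
    """The two-organism, eleven-reaction worked example with its score row."""
    return table5_fixture()


@pytest.fixture
def toy_matrix(toy_pair):
    return toy_pair[0]


@pytest.fixture
def toy_matrix_file(toy_matrix, tmp_path):
    from metabotree import write_org_matrix

    path = tmp_path / "toy.tsv"
    write_org_matrix(toy_matrix, path)
    return path


@pytest.fixture
def clade_matrix():
    """Seeded 20-organism two-clade matrix (balanced clades of 10)."""
    spec = two_clade_spec(n_per_clade=10, seed=11)
    return generate_clade_matrix(spec), spec


def random_org_matrix(rng: np.random.Generator, n_org: int, n_rxn: int) -> OrgMatrix:
    """Random binary matrix with every organism carrying >= 1 reaction."""
    presence = (rng.random((n_org, n_rxn)) < 0.4).astype(np.uint8)
    for i in range(n_org):
        if presence[i].sum() == 0:
            presence[i, rng.integers(n_rxn)] = 1
    orgs = [f"org{i}" for i in range(n_org)]
    rxns = [f"R{j:03d}" for j in range(n_rxn)]
    return OrgMatrix(orgs, ReactionCatalog(rxns), presence)
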