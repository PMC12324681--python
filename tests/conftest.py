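import numpy as np
import pytest

from pocketome.model import PocketRecord, ProteinRecord, ResidueRef
from pocketome.synthetic import (
    SyntheticConfig,
    generate_ontology,
    generate_pockets_and_sites,
    generate_proteome,
    write_fixture_tree,
)


@pytest.fixture(scope="session")
def small_cfg() -> SyntheticConfig:
    return SyntheticConfig(seed=11, n_species=3, proteins_per_species=8, mean_protein_length=120)


@pytest.fixture(scope="session")
def proteome(small_cfg):
    return generate_proteome(small_cfg, "SYN00")


@pytest.fixture(scope="session")
def pockets_and_sites(small_cfg, proteome):
    return generate_pockets_and_sites(small_cfg, proteome)


@pytest.fixture(scope="session")
def ontology(small_cfg):
    return generate_ontology(small_cfg)


@pytest.fixture(scope="session")
def fixture_tree(tmp_path_factory, small_cfg):
    root = tmp_path_factory.mktemp("tree")
    manifest = write_fixture_tree(small_cfg, root)
    return root, manifest


def make_protein(
    protein_id="P1",
    species="SYN00",
    length=10,
    plddt=None,
    pae=None,
    seed=0,
    **kwargs,
) -> ProteinRecord:
    """Hand-rolled protein with a straight-line Cα trace."""
    rng = np.random.default_rng(seed)
    sequence = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=length))
    ca = np.column_stack([3.8 * np.arange(length), np.zeros(length), np.zeros(length)])
    return ProteinRecord(
        protein_id=protein_id,
        species=species,
        sequence=sequence,
        ca_coords=ca,
        plddt=np.full(length, 80.0) if plddt is None else np.asarray(plddt, float),
        pae=pae,
        **kwargs,
    )


def make_pocket(indices, protein_id="P1", pocket_id="P1:p1", probability=0.8, rank=1):
    return PocketRecord(
        pocket_id=pocket_id,
        protein_id=protein_id,
        rank=rank,
        probability=probability,
        residues=frozenset(ResidueRef("A", i) for i in indices),
    )
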