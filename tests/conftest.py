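import numpy as np
import pytest

from ligdyn.synthetic_data import (
    LigandSpec,
    PlantedInteraction,
    make_toy_complex,
    plant_interaction_snapshot,
)


def dense_contact_interactions():
    """Final-snapshot contact set of the tighter-binding complex: three
    H-bonds, two guanidine-carboxylate salt bridges, one pi-stack."""
    return [
        PlantedInteraction(type="hbond", geometry={"h_a": 2.96, "d_a": 3.94},
                           donor_side="protein", residue_name="GLY", residue_seq=74),
        PlantedInteraction(type="hbond", geometry={"h_a": 1.79, "d_a": 2.72},
                           donor_side="ligand", residue_name="PHE", residue_seq=108),
        PlantedInteraction(type="hbond", geometry={"h_a": 2.33, "d_a": 3.22},
                           donor_side="ligand", residue_name="PHE", residue_seq=109),
        PlantedInteraction(type="salt_bridge", geometry={"min_distance": 4.19},
                           residue_name="ASP", residue_seq=32),
        PlantedInteraction(type="salt_bridge", geometry={"min_distance": 5.26},
                           residue_name="ASP", residue_seq=228),
        PlantedInteraction(type="pi_stacking",
                           geometry={"centroid_distance": 5.37, "offset": 0.63},
                           residue_name="TRP", residue_seq=115),
    ]


def sparse_contact_interactions():
    """Final-snapshot contact set of the reference complex: two H-bonds only."""
    return [
        PlantedInteraction(type="hbond", geometry={"h_a": 2.03, "d_a": 2.97},
                           donor_side="ligand", residue_name="SER", residue_seq=10),
        PlantedInteraction(type="hbond", geometry={"h_a": 2.52, "d_a": 3.49},
                           donor_side="protein", residue_name="GLN", residue_seq=73),
    ]


@pytest.fixture(scope="session")
def dense_snapshot():
    return plant_interaction_snapshot(None, dense_contact_interactions())


@pytest.fixture(scope="session")
def sparse_snapshot():
    return plant_interaction_snapshot(None, sparse_contact_interactions())


@pytest.fixture(scope="session")
def toy_complex():
    return make_toy_complex(
        20,
        LigandSpec(n_rings=1, n_donors=1, n_acceptors=1, n_cation_groups=1, n_apolar=2),
        seed=11,
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
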