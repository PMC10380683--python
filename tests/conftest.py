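import numpy as np
import pytest

import dualaav as da
from dualaav.constructs import FIVE_PRIME, THREE_PRIME
from dualaav.molecules import (
    HEAD_TO_HEAD,
    HEAD_TO_TAIL,
    TAIL_TO_TAIL,
    MoleculeSpecies,
    SamplePopulation,
)


@pytest.fixture(scope="session")
def constructs():
    return da.build_default_constructs()


@pytest.fixture(scope="session")
def panel(constructs):
    return da.default_assay_panel(*constructs)


@pytest.fixture(scope="session")
def hr_species():
    return MoleculeSpecies.hr_product()


@pytest.fixture(scope="session")
def ht_dimer():
    """Head-to-tail 5'→3' dimer: the concatemer the REC assay confuses with HR."""
    return MoleculeSpecies(((FIVE_PRIME, 1), (THREE_PRIME, 1)), (HEAD_TO_TAIL,))


def make_pop(species_counts, host_genomes=0):
    return SamplePopulation(dict(species_counts), host_genomes=host_genomes)


#: every ITR-junction dimer class the simulator can generate:
#: (left unit, right unit, junction type)
ALL_ITR_DIMERS = [
    ((FIVE_PRIME, 1), (THREE_PRIME, 1), HEAD_TO_TAIL),
    ((THREE_PRIME, 1), (FIVE_PRIME, 1), HEAD_TO_TAIL),
    ((FIVE_PRIME, 1), (FIVE_PRIME, 1), HEAD_TO_TAIL),
    ((THREE_PRIME, 1), (THREE_PRIME, 1), HEAD_TO_TAIL),
    ((FIVE_PRIME, 1), (THREE_PRIME, -1), HEAD_TO_HEAD),
    ((FIVE_PRIME, 1), (FIVE_PRIME, -1), HEAD_TO_HEAD),
    ((THREE_PRIME, 1), (THREE_PRIME, -1), HEAD_TO_HEAD),
    ((FIVE_PRIME, -1), (THREE_PRIME, 1), TAIL_TO_TAIL),
    ((FIVE_PRIME, -1), (FIVE_PRIME, 1), TAIL_TO_TAIL),
    ((THREE_PRIME, -1), (THREE_PRIME, 1), TAIL_TO_TAIL),
]


def random_sim_params(rng: np.random.Generator, host_max=20, u_max=5.0):
    """Small random study conditions for property sweeps."""
    return da.SimParams(
        u5=float(rng.uniform(0.0, u_max)),
        u3=float(rng.uniform(0.0, u_max)),
        hr_fraction=float(rng.uniform(0, 1)),
        concat_fraction=float(rng.uniform(0, 0.5)),
        chain_length_p=float(rng.uniform(0.2, 1.0)),
        orientation_weights=tuple(rng.dirichlet([1, 1, 1])),
        host_genomes=int(rng.integers(1, host_max + 1)),
        circular_fraction=float(rng.choice([0.0, 0.0, 0.3])),
        seed=int(rng.integers(0, 2**31 - 1)),
    )
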