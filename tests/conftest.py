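import numpy as np
import pytest

from seedburial.core import BagRecord
from seedburial.phylo import newick_from_string
from seedburial.simulate import SimulationConfig, simulate_dataset

DESIGN_YEARS = (1.5, 2.5, 3.5, 4.5, 5.5, 6.5, 7.5)


def make_bag(
    species="spA",
    replicate=1,
    years=1.5,
    buried=100,
    spont=40,
    ga=10,
    stained=20,
    row_number=1,
    row_sequence=1,
):
    """BagRecord with n_dead filled in to satisfy the count invariant."""
    return BagRecord(
        species_id=species,
        replicate_id=replicate,
        years_since_burial=years,
        row_number=row_number,
        row_sequence=row_sequence,
        n_buried=buried,
        n_germ_spont=spont,
        n_germ_ga=ga,
        n_viable_stained=stained,
        n_dead=buried - spont - ga - stained,
    )


@pytest.fixture
def three_tip_tree():
    return newick_from_string("((A:1,B:1):1,C:2);")


@pytest.fixture(scope="session")
def small_dataset():
    """10-species synthetic dataset reused by slow-ish integration tests."""
    config = SimulationConfig(
        n_invasive=4,
        n_naturalized=6,
        sd_phylo=0.8,
        sd_bag=0.4,
        lambda_true=0.5,
        rng_seed=42,
    )
    return simulate_dataset(config)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
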