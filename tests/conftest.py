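import numpy as np
import pytest

from paleodup import cornus, synthetic_data, wgd_placement


@pytest.fixture(scope="session")
def species_tree():
    return wgd_placement.SpeciesTree.cornus_default()


@pytest.fixture(scope="session")
def small_config():
    """A one-species simulation config with a single planted WGD."""
    return synthetic_data.SimulationConfig(
        species_clocks={"CAL": 2.7e-3},
        wgd_events=((74.0, 0.4, 5.0),),
        ssd_rate=0.05,
        n_pairs=400,
        seed=123,
    )


@pytest.fixture(scope="session")
def gene_tree_set():
    """98 dated gene trees with a duplication planted at 76.1 +- 2.7 myr."""
    return synthetic_data.simulate_gene_trees(
        cornus.SPECIES_TREE_NEWICK,
        dup_age=76.1,
        n_trees=98,
        seed=20,
        age_sd=2.7,
        dropout=0.2,
    )


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(0)
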