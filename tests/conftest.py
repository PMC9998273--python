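import numpy as np
import pandas as pd
import pytest

from fusemap.karyotype import ELEMENT_NAMES, GeneticMapModel, build_species_pair
from fusemap.simulate import simulate_cross_panel


@pytest.fixture(scope="session")
def small_lengths():
    return {e: 2_000_000 for e in ELEMENT_NAMES}


@pytest.fixture(scope="session")
def small_map(small_lengths):
    return GeneticMapModel.uniform(small_lengths, 50.0)


@pytest.fixture(scope="session")
def species_pair(small_lengths):
    return build_species_pair(element_lengths=small_lengths, snp_density=1 / 5000.0, seed=7)


@pytest.fixture(scope="session")
def bc1_panel(small_map, small_lengths):
    return simulate_cross_panel("bc1_to_P", 25, small_map, small_lengths, seed=11)


@pytest.fixture()
def rng():
    return np.random.default_rng(123)


@pytest.fixture()
def call_matrix():
    """Tiny hand-made introgression call matrix (2 chromosomes x 4 windows)."""
    cols = pd.MultiIndex.from_tuples(
        [("c1", 1), ("c1", 100001), ("c1", 200001), ("c1", 300001), ("c2", 1), ("c2", 100001)],
        names=["chrom", "start"],
    )
    data = [
        ["present", "present", "absent", "absent", "absent", "absent"],
        ["present", "present", "present", "absent", "absent", "missing"],
        ["absent", "absent", "absent", "absent", "present", "present"],
        ["absent", "absent", "absent", "absent", "present", "present"],
        ["present", "absent", "absent", "absent", "absent", "absent"],
        ["absent", "absent", "present", "present", "missing", "absent"],
    ]
    return pd.DataFrame(data, index=[f"i{k}" for k in range(6)], columns=cols)
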