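import warnings

import numpy as np
import pandas as pd
import pytest

from carabidfa import synthetic as syn

warnings.filterwarnings("ignore", category=FutureWarning, module="arviz")


@pytest.fixture(scope="session")
def small_individuals():
    return syn.simulate_individuals(2, seed=101)  # 72 individuals


@pytest.fixture(scope="session")
def small_dataset():
    return syn.simulate_dataset(seed=202, n_per_cell=1)


@pytest.fixture(scope="session")
def community_tables():
    return syn.simulate_community(syn.CommunitySpec(), seed=303)


@pytest.fixture
def toy_community():
    """5 x 4 abundance matrix small enough for brute-force oracles."""
    rng = np.random.default_rng(7)
    Y = pd.DataFrame(rng.poisson(5, (5, 4)).astype(float) + 1.0,
                     index=[f"s{i}" for i in range(5)],
                     columns=[f"sp{j}" for j in range(4)])
    return Y


def one_species_cohort(spec: syn.TraitSpec, n: int = 60, seed: int = 0):
    """Individuals + bilateral measurements for one archetype cohort."""
    n_cell = max(1, int(np.ceil(n / 36)))
    ind = syn.simulate_individuals(n_cell, seed=seed).iloc[:n].reset_index(drop=True)
    meas = syn.simulate_bilateral(ind, spec, seed=seed)
    return ind, meas
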