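import numpy as np
import pandas as pd
import pytest

from seedtol import SimulationConfig, simulate_study

DEMO_SEED = 20109


@pytest.fixture(scope="session")
def demo21():
    """One full synthetic study at the default design (21 sites, 3 reps)."""
    return simulate_study(SimulationConfig(random_seed=DEMO_SEED))


@pytest.fixture(scope="session")
def demo21_sites(demo21):
    return demo21[0]


@pytest.fixture(scope="session")
def demo21_traits(demo21):
    return demo21[1]


@pytest.fixture(scope="session")
def demo21_trials(demo21):
    return demo21[2]


@pytest.fixture(scope="session")
def demo21_indices(demo21_trials):
    from seedtol import compute_indices, indices_to_frame

    return indices_to_frame(compute_indices(demo21_trials))


@pytest.fixture(scope="session")
def demo21_trait_table(demo21_traits, demo21_indices):
    """Traits joined with the computed tolerance indices."""
    return demo21_traits.merge(demo21_indices, on=["population_id", "replicate"])
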