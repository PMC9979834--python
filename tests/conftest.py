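import warnings

import numpy as np
import pytest

from panelcomp.experiment_data import dynamics_dataset
from panelcomp.synthetic_data import (DesignSpec, generate_dynamics_experiment,
                                      generate_manova_dataset, load_preset)

warnings.filterwarnings("ignore", category=RuntimeWarning)
warnings.filterwarnings("ignore", category=FutureWarning)
warnings.filterwarnings("ignore", category=UserWarning)


@pytest.fixture(scope="session")
def preset():
    return load_preset()


@pytest.fixture(scope="session")
def small_design():
    return DesignSpec(n_blocks=2)


@pytest.fixture(scope="session")
def dyn_table(preset, small_design):
    """Small synthetic experiment (12 panels) with retained truth."""
    return generate_dynamics_experiment("overgrowth", preset, small_design, seed=11)


@pytest.fixture(scope="session")
def dyn_ds(dyn_table):
    return dynamics_dataset(dyn_table[0])


@pytest.fixture(scope="session")
def manova_data(preset):
    """Synthetic five-part counts from the hierarchical model (4 blocks)."""
    return generate_manova_dataset(preset, DesignSpec(n_blocks=4), seed=21)


@pytest.fixture(scope="session")
def manova_post(manova_data):
    from panelcomp import comp_manova
    data, _ = manova_data
    return comp_manova.fit(data, "no_interaction", seed=5, n_chains=2,
                           n_warmup=600, n_draws=300, check_diagnostics=False)


@pytest.fixture(scope="session")
def dyn_post(dyn_ds):
    from panelcomp.dyn_inference import fit_dynamics
    return fit_dynamics("overgrowth", dyn_ds, seed=9, n_warmup=400,
                        n_steps=300, thin=3)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
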