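import numpy as np
import pytest

from methylscape.synthetic_cohort import SimConfig, make_study


@pytest.fixture(scope="session")
def default_study():
    """One default synthetic study shared across tests (seed 1)."""
    return make_study(SimConfig(seed=1))


@pytest.fixture(scope="session")
def small_config():
    """A reduced study for fast end-to-end CLI runs."""
    return dict(
        chrom_length=1_000_000,
        n_islands=40,
        n_genes=60,
        background_cpg_rate=0.005,
        n_patients=80,
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
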