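import numpy as np
import pytest

from famstates.simulate import SimConfig, default_true_params, simulate_population


@pytest.fixture(scope="session")
def fixture_data():
    from famstates.simulate import make_fixture

    return make_fixture()


@pytest.fixture(scope="session")
def fixture_panel(fixture_data):
    return fixture_data.build_panel()


@pytest.fixture(scope="session")
def small_population():
    """~120 simulated children with outcomes, shared across tests."""
    cfg = SimConfig(n_children=120, seed=42)
    records, spells, vitals, panel = simulate_population(cfg, default_true_params())
    return {
        "config": cfg,
        "records": records,
        "spells": spells,
        "vitals": vitals,
        "panel": panel,
        "true_params": default_true_params(),
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(20240901)
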