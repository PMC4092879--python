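import numpy as np
import pytest

import debench as db


@pytest.fixture(scope="session")
def small_experiment():
    """One scenario-I-like dataset at reduced size, shared across tests."""
    cfg = db.scenario_config("I", n_genes=400, n_datasets=1, seed=0)
    return db.simulate_scenario(cfg)[0]


@pytest.fixture(scope="session")
def fixed_panel():
    spec = db.PanelSpec(n_genes=400, seed=0)
    return db.truncate_panel_at_depth(
        db.make_standin_panel(spec), 5.0, spec=spec, seed=1
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
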