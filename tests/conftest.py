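import numpy as np
import pytest

import spreadwait as sw
from spreadwait.scenarios import run_recovery


@pytest.fixture(scope="session")
def small_sim():
    """Default-condition 20x20 simulated dataset shared across tests."""
    cfg = sw.SimConfig(seed=7)
    landscape, truth, traps, treatments = sw.simulate_all(cfg)
    grid = sw.GridSpec(cell_size=cfg.cell_m, n_rows=cfg.n_rows, n_cols=cfg.n_cols)
    return {
        "cfg": cfg,
        "landscape": landscape,
        "truth": truth,
        "traps": traps,
        "treatments": treatments,
        "grid": grid,
    }


@pytest.fixture(scope="session")
def recovery():
    """Full trap-to-waiting-time run under the high-detection scenario."""
    return run_recovery(seed=1)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
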