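import numpy as np
import pytest

from burrowtrack import ColonyConfig, default_layout, process_colony, simulate_colony


@pytest.fixture(scope="session")
def layout():
    return default_layout()


@pytest.fixture(scope="session")
def colony_day(layout):
    """A 20-individual, 1-day noise-free colony with planted disturbances."""
    cfg = ColonyConfig(
        n_individuals=20, duration_s=86400.0, miss_rate=0.0,
        disturbance_rate_per_day=3.0, seed=7,
    )
    log, truth = simulate_colony(cfg, layout)
    return cfg, log, truth


@pytest.fixture(scope="session")
def colony_day_dataset(layout, colony_day):
    cfg, log, truth = colony_day
    return process_colony(
        log, layout, cfg.duration_s, range(cfg.n_individuals),
        toilet=cfg.toilet_cell, garbage=cfg.garbage_cell,
    )
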