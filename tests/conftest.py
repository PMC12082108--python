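import numpy as np
import pytest

from clonesplice.synth import (
    SimulationConfig,
    simulate_clonal_trajectories,
    simulate_junction_counts,
)


@pytest.fixture(scope="session")
def patient1_series():
    """Two-clone fixture shaped like the printed long-term follow-up:
    a founder clone falling 43% -> ~0% VAF while its competitor rises
    4.6% -> ~41% over 168 months, observed with 10,000-droplet ddPCR noise.
    """
    cfg = SimulationConfig(seed=11)
    series, _ = simulate_clonal_trajectories(cfg)
    return series


@pytest.fixture(scope="session")
def small_sim_config():
    """Scaled-down generative config for fast unit tests: fewer colonies
    and a lower mutation rate so matrices stay small."""
    return SimulationConfig(
        seed=7,
        colonies_per_compartment=30,
        mutation_rate_per_year=2.0,
        donor_ages=(40.0,),
        cells_per_clone=30,
    )


@pytest.fixture(scope="session")
def default_junction_run():
    """One study-scale junction simulation (100 cells/clone, coverage 50)."""
    cfg = SimulationConfig(seed=3)
    table, annotation, truth = simulate_junction_counts(cfg)
    return cfg, table, annotation, truth
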