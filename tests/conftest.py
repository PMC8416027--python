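import numpy as np
import pytest

from pppflux import (
    NetworkConfig,
    NoiseModel,
    PAPER_TIME_GRID_S,
    TracerSpec,
    default_scenarios,
    generate_experiment,
)

TIME_GRID = np.asarray(PAPER_TIME_GRID_S)


@pytest.fixture(scope="session")
def tracer():
    return TracerSpec(tracer_fraction=0.5, purity=1.0)


@pytest.fixture(scope="session")
def base_config():
    return NetworkConfig()


@pytest.fixture(scope="session")
def demo_table(tracer):
    """Small simulated experiment shared across tests (control + knockdowns)."""
    return generate_experiment(
        default_scenarios(),
        tracer,
        TIME_GRID,
        replicates=3,
        noise=NoiseModel(sd_fraction=0.01, seed=42),
    )
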