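import numpy as np
import pandas as pd
import pytest

from icespec import (
    DropletAssay,
    SimulationConfig,
    compute_frozen_fraction,
    simulate_assay,
)
from icespec.simulate import fresh_population


def make_assay(temps, cycle=1, **kwargs) -> DropletAssay:
    """Tiny assay from explicit freezing temperatures (one cycle)."""
    events = pd.DataFrame(
        {
            "droplet_id": np.arange(len(temps)),
            "cycle": cycle,
            "freezing_temp_C": temps,
            "frozen": 1,
        }
    )
    return DropletAssay(events=events, **kwargs)


@pytest.fixture(scope="session")
def fresh_assay() -> tuple[SimulationConfig, DropletAssay]:
    """A reference 768-droplet assay from the fresh bimodal population."""
    config = SimulationConfig(seed=101)
    return config, simulate_assay(config)


@pytest.fixture(scope="session")
def fresh_curve(fresh_assay):
    _, assay = fresh_assay
    return compute_frozen_fraction(assay, 1)


@pytest.fixture()
def bimodal_population():
    return fresh_population()
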