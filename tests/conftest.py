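import numpy as np
import pandas as pd
import pytest

from nichegradient import (
    OccurrenceTable,
    SpeciesVariableSample,
    generate_sample,
    scenario_spec,
)


@pytest.fixture
def toy_table() -> OccurrenceTable:
    frame = pd.DataFrame(
        {
            "species": ["alpha"] * 5 + ["beta"] * 3,
            "site_id": [f"s{i}" for i in range(8)],
            "longitude": np.linspace(-100, -95, 8),
            "latitude": np.linspace(16, 20, 8),
            "rainfall": [100.0, 150.0, 200.0, 250.0, 300.0, 400.0, 500.0, 600.0],
            "temperature": [20.0, 21.0, 22.0, 23.0, 24.0, 18.0, 19.0, 20.5],
        }
    )
    return OccurrenceTable(frame)


@pytest.fixture(scope="session")
def skewed_sample() -> tuple[SpeciesVariableSample, dict]:
    spec = scenario_spec("skewed_interior", "sp", "rain", n=300, seed=11)
    return generate_sample(spec)


@pytest.fixture(scope="session")
def gaussian_sample() -> tuple[SpeciesVariableSample, dict]:
    spec = scenario_spec("symmetric_interior", "sp", "temp", n=300, seed=5)
    return generate_sample(spec)
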