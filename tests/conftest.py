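import numpy as np
import pandas as pd
import pytest

from bioind.simulate import SimulationConfig, simulate_experiment
from bioind.tables import AbundanceTable, SampleMetadata, METADATA_COLUMNS


@pytest.fixture(scope="session")
def default_bundle():
    """One default synthetic experiment, shared across tests."""
    return simulate_experiment(SimulationConfig(seed=11))


@pytest.fixture
def toy_counts():
    return AbundanceTable(
        pd.DataFrame(
            [[3, 1], [0, 4]], index=["s1", "s2"], columns=["a1", "a2"]
        ),
        "counts",
    )


def make_metadata(rows):
    """Build a SampleMetadata from (sample_id, reactor, day, hrt) tuples."""
    frame = pd.DataFrame(
        [
            {
                "sample_id": sid, "reactor": reactor, "day": day, "hrt": hrt,
                **{c: 0.0 for c in METADATA_COLUMNS if c.startswith(("conc", "prod", "yield"))},
            }
            for sid, reactor, day, hrt in rows
        ]
    )
    return SampleMetadata(frame)


@pytest.fixture
def rng():
    return np.random.default_rng(7)
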