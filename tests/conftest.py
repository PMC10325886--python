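import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

sys.path.insert(0, str(Path(__file__).parent))

settings.register_profile(
    "repro",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("repro")


@pytest.fixture
def three_species_table() -> pd.DataFrame:
    """s1 and s2 share a family but not a genus; s3 sits in a different order."""
    return pd.DataFrame(
        {
            "genus": ["Ga", "Gb", "Gc"],
            "family": ["F1", "F1", "F2"],
            "order": ["O1", "O1", "O2"],
            "cod_latitude": [20.0, 30.0, 25.0],
        },
        index=pd.Index(["s1", "s2", "s3"], name="species"),
    )


@pytest.fixture
def small_community(three_species_table) -> pd.DataFrame:
    dates = pd.date_range("2015-01-01", periods=6, freq="MS")
    counts = np.array(
        [[2, 1, 1], [3, 1, 0], [0, 4, 2], [1, 1, 1], [5, 0, 0], [2, 2, 2]]
    )
    return pd.DataFrame(counts, index=dates, columns=three_species_table.index)
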