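import numpy as np
import pandas as pd
import pytest

from carriermod.incidence import IncidenceCurve


@pytest.fixture(scope="session")
def flat_curve():
    """Constant hazard 0.01/yr on ages 20-80 (closed forms available)."""
    return IncidenceCurve(np.arange(20, 80), np.full(60, 0.01))


@pytest.fixture(scope="session")
def five_carrier_records():
    """Tiny printed phenotype fixture for likelihood oracle checks."""
    return pd.DataFrame(
        {
            "sample_id": ["c1", "c2", "c3", "c4", "c5"],
            "censor_age": [35.0, 42.5, 55.0, 61.2, 78.9],
            "breast_event": [1, 0, 1, 0, 0],
        }
    )


@pytest.fixture(scope="session")
def five_carrier_dosages():
    return np.array([0.0, 1.0, 2.0, 1.0, 0.0])
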