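import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import lenassess as la

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


def make_records(lengths, weights, ages=None, group="g1", sex="unknown"):
    """Assemble a canonical record frame from arrays."""
    lengths = np.asarray(lengths, dtype=float)
    weights = np.asarray(weights, dtype=float)
    if ages is None:
        ages = np.ones(lengths.size, dtype=int)
    return pd.DataFrame({
        "group_id": group,
        "sex": sex,
        "age": np.asarray(ages),
        "length_mm": lengths,
        "weight_g": weights,
    })


@pytest.fixture(scope="session")
def tributaries():
    """Published four-tributary coefficient table (with derived L_inf, W_inf)."""
    return la.yarlung_tributaries()


@pytest.fixture(scope="session")
def dx_vbgf():
    """Duoxiong Zangbo growth parameters (highest-elevation tributary)."""
    return la.tributary_vbgf("Duoxiong Zangbo")
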