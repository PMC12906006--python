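import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

sys.path.insert(0, str(Path(__file__).parent))  # make tests/oracles importable

from dpbench.io import ProportionMatrix

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=60,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def make_pm(values: dict, conditions: dict, source: str = "deconvolution:test") -> ProportionMatrix:
    """ProportionMatrix from {sample: [fractions...]} plus cell-type order
    inferred as ct1..ctK."""
    df = pd.DataFrame.from_dict(values, orient="index")
    df.columns = [f"ct{i+1}" for i in range(df.shape[1])]
    return ProportionMatrix(df, conditions, source=source)


@pytest.fixture
def two_condition_pm() -> ProportionMatrix:
    """Six samples, three cell types, two conditions, rows sum to 1."""
    values = {
        "s1": [0.5, 0.3, 0.2],
        "s2": [0.6, 0.25, 0.15],
        "s3": [0.55, 0.27, 0.18],
        "s4": [0.2, 0.5, 0.3],
        "s5": [0.25, 0.45, 0.3],
        "s6": [0.15, 0.55, 0.3],
    }
    cond = {s: ("A" if s in ("s1", "s2", "s3") else "B") for s in values}
    return make_pm(values, cond)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
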