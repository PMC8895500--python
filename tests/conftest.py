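import numpy as np
import pandas as pd
import pytest

from imprintkit.presets import study_design
from imprintkit.synthetic import simulate_cross


@pytest.fixture(scope="session")
def study_samples() -> pd.DataFrame:
    """Sample metadata at the study's embryo layout (F 6/3/4, M 4/3/3)."""
    return simulate_cross(study_design(seed=0))


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20260924)
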