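import numpy as np
import pandas as pd
import pytest

from lfqtobit.config import SimConfig
from lfqtobit.simulate import simulate_design
from lfqtobit.tobit import build_design_matrix


@pytest.fixture(scope="session")
def pellet_config() -> SimConfig:
    """Single-fraction 2 x 2 x 3 layout used by most model-level tests."""
    return SimConfig(n_proteins=4, seed=1, fractions=("pellet",), qualitative_fraction=0.0)


@pytest.fixture(scope="session")
def pellet_design(pellet_config) -> pd.DataFrame:
    return simulate_design(pellet_config)


@pytest.fixture(scope="session")
def design_matrix(pellet_design) -> np.ndarray:
    return build_design_matrix(pellet_design)
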