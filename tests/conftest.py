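import numpy as np
import pytest

from groovebind import (
    EQUILIBRIUM_PRESETS,
    KINETIC_PRESETS,
    StepwiseConstants,
)


@pytest.fixture
def db1003_ttaa() -> StepwiseConstants:
    """Published cooperative-dimer constants for DB1003 at -TTAA-."""
    return EQUILIBRIUM_PRESETS["DB1003-TTAA"]


@pytest.fixture
def db1992_ttaa() -> StepwiseConstants:
    return EQUILIBRIUM_PRESETS["DB1992-TTAA"]


@pytest.fixture
def db2009_kinetics():
    """Published 1:1 rates for DB2009 at -AATT-."""
    return KINETIC_PRESETS["DB2009-AATT"]


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)
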