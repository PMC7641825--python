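import numpy as np
import pytest

from qolmap.synthcohort import SyntheticConfig, generate
from qolmap.valueset import ValueSet, japan_synthetic_tariff


@pytest.fixture(scope="session")
def tariff():
    return japan_synthetic_tariff()


@pytest.fixture(scope="session")
def toy_tariff():
    """Every non-level-1 decrement equals 0.1 (so state (2,1,1,1,1) -> 0.9)."""
    dec = np.zeros((5, 5))
    dec[:, 1:] = 0.1
    return ValueSet(decrements=dec, label="toy")


@pytest.fixture(scope="session")
def eortc_cohort():
    return generate(SyntheticConfig(n=903, seed=7, source="eortc",
                                    generator="ordinal_truth"))


@pytest.fixture(scope="session")
def factg_cohort():
    return generate(SyntheticConfig(n=903, seed=7, source="factg",
                                    generator="ordinal_truth"))


@pytest.fixture(scope="session")
def eortc_twopart_cohort():
    return generate(SyntheticConfig(n=2000, seed=11, source="eortc",
                                    generator="twopart_truth"))
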