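import numpy as np
import pytest

from hemakin.fitting import GAConfig
from hemakin.model import apply_balance
from hemakin import presets
from hemakin.scenarios import default_scenario, generate


@pytest.fixture(scope="session")
def tissue_spec():
    return presets.tissue_spec("pb_coupled")


@pytest.fixture(scope="session")
def tissue_truth(tissue_spec):
    """Balance-resolved generating parameters of the default scenario."""
    return apply_balance(tissue_spec, presets.tissue_truth(),
                         presets.tissue_x0(tissue_spec))


@pytest.fixture(scope="session")
def tissue_x0(tissue_spec):
    return presets.tissue_x0(tissue_spec)


@pytest.fixture(scope="session")
def noisy_dataset():
    """One noisy realization of the default scenario (CV 15 %, n = 3)."""
    return generate(default_scenario(cv=0.15), seed=0)


@pytest.fixture(scope="session")
def ga_tiny():
    """A GA budget small enough for sub-second unit-test fits."""
    return GAConfig(population=12, generations=8, refine_starts=1)
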