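import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from cd177conv import (
    ConversionGenotype,
    SimulationConfig,
    default_probe_panel,
    load_builtin_cd177_model,
)
from cd177conv.simulate import ECTOPIC_EXON7, INTACT, TRACT_EXON5_7


@pytest.fixture(scope="session")
def model():
    return load_builtin_cd177_model()


@pytest.fixture(scope="session")
def panel():
    return default_probe_panel()


@pytest.fixture
def cfg():
    return SimulationConfig(n_samples=200, seed=7)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def genotypes_by_class():
    return {
        "ref_hom": ConversionGenotype(INTACT, INTACT),
        "ectopic_het": ConversionGenotype(INTACT, ECTOPIC_EXON7),
        "null": ConversionGenotype(ECTOPIC_EXON7, ECTOPIC_EXON7),
        "null_5_7": ConversionGenotype(TRACT_EXON5_7, TRACT_EXON5_7),
    }
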