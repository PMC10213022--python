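import numpy as np
import pytest

from desqspr import (
    BondDipoleTable,
    SynthSpec,
    load_default_structures,
    reference_eeig02d,
    synth_generate,
)


@pytest.fixture(scope="session")
def structures():
    return load_default_structures()


@pytest.fixture(scope="session")
def dipoles():
    return BondDipoleTable.default()


@pytest.fixture(scope="session")
def calibration_reference():
    """Text-consistent EEig02d reference rows (conflicted donors excluded)."""
    return reference_eeig02d(calibration_only=True)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260920)


@pytest.fixture()
def noiseless_dataset():
    """Synthetic study-design dataset with sigma = 0 (exactly ln-linear)."""
    return synth_generate(SynthSpec(sigma=0.0, seed=7))


@pytest.fixture()
def noisy_dataset():
    """Synthetic study-design dataset at the default noise level."""
    return synth_generate(SynthSpec(seed=7))
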