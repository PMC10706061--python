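import dataclasses

import numpy as np
import pytest

from graperipe import synthio


@pytest.fixture(scope="session")
def default_config() -> synthio.SynthConfig:
    return synthio.SynthConfig(seed=0)


@pytest.fixture(scope="session")
def default_dataset(default_config):
    """Chemistry + true labels + replicate spectra at the default settings."""
    chem, labels = synthio.generate_chemistry(default_config)
    reps = synthio.generate_spectra(chem, labels, default_config)
    return chem, labels, reps


@pytest.fixture(scope="session")
def noiseless_chemistry_config() -> synthio.SynthConfig:
    """All indicator SDs forced to zero: every sample sits on its stage mean."""
    models = [
        dataclasses.replace(m, sd_ssc=0.0, sd_ta=0.0, sd_tp=0.0, sd_tn=0.0)
        for m in synthio.default_chemistry_models()
    ]
    return synthio.SynthConfig(chemistry_models=models, seed=0)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
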