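import numpy as np
import pytest

from limnodigest import synth


@pytest.fixture(scope="session")
def digestome():
    """Default digestome preset with its generated evidence (seed 0)."""
    preset = synth.digestome_preset(seed=0)
    evidence, sequences = synth.gen_proteome_evidence(preset)
    return preset, evidence, sequences


@pytest.fixture(scope="session")
def control_decay():
    """One control-preset CPMG decay (test-sized acquisition, seed 0)."""
    return synth.gen_cpmg_decay(
        synth.pore_population_preset("control"),
        synth.acquisition_preset("control", seed=0),
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
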