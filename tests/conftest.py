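import pytest

from brainpk.simulate import NoiseModel, default_truth


@pytest.fixture
def zero_noise_truth():
    """Default study scenario with every assay noise-free."""
    return default_truth(seed=7, noise=NoiseModel(0, 0, 0, 0))


@pytest.fixture
def loq_table(zero_noise_truth):
    return {f"{m}|{g}": v for (m, g), v in zero_noise_truth.loq.items()}
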