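import warnings

import pytest

from synaptome import EncodingProfile, GeneratorConfig, generate


@pytest.fixture(scope="session")
def human_profile():
    """Human-scale neuron-terminal profile: 5/2/4/4 byte widths."""
    return EncodingProfile()


@pytest.fixture(scope="session")
def small_synaptome():
    """Seed-42 chemical synaptome: 10 neurons x 4 terminals -> 20 synapses."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return generate(GeneratorConfig(n_neurons=10, syn_per_neuron=4, seed=42))


@pytest.fixture(scope="session")
def medium_synaptome():
    """Seed-42 synaptome of 50 synapses for round-trip checks."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return generate(GeneratorConfig(n_neurons=10, syn_per_neuron=10, seed=42))


def generate_quiet(cfg: GeneratorConfig):
    """Generate while suppressing the (expected) autapse warning."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return generate(cfg)
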