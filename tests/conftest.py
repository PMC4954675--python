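import numpy as np
import pytest

from convotrace import synthgen


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def default_config():
    return synthgen.GeneratorConfig(seed=7)


@pytest.fixture
def small_config():
    """Study-structured but desk-sized: short conversations, few people."""
    return synthgen.with_overrides(
        synthgen.GeneratorConfig(seed=7),
        n_participants=6,
        conversations_per_participant=synthgen.DistributionSpec(5, 2, 3, 10),
        conversation_length_min=synthgen.DistributionSpec(2.0, 1.0, 0.75, 4.0),
    )


@pytest.fixture
def profile(default_config, rng):
    return synthgen.sample_participant_profile(default_config, rng, "p000")
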