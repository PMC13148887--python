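import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

from agestereo.embeddings import SyntheticBackend, SyntheticEmbeddingSpec
from agestereo.lexicon import builtin_lexicon
from agestereo.synthetic import GeneratorConfig, default_profiles, generate_corpus


@pytest.fixture(scope="session")
def lexicon():
    return builtin_lexicon()


@pytest.fixture(scope="session")
def noise_free_backend(lexicon):
    return SyntheticBackend(SyntheticEmbeddingSpec(noise_sd=0.0, seed=0), lexicon)


@pytest.fixture(scope="session")
def small_corpus(lexicon):
    """20 responses per age, all nine ages, fixed seed."""
    cfg = GeneratorConfig(
        profiles=tuple(default_profiles()), responses_per_age=20, seed=11
    )
    return generate_corpus(cfg, lexicon)
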