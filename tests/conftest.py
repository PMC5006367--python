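import pytest

from diseasesim.synthetic import SyntheticScenario, generate_scenario


@pytest.fixture(scope="session")
def small_scenario():
    """Desk-sized scenario used across module tests (fast to generate)."""
    return SyntheticScenario(
        n_genes=120, n_modules=4, p_within=0.3, p_between=0.02,
        n_diseases=12, genes_per_disease=6, module_purity=0.8,
        n_topics=4, words_per_topic=30, docs_per_disease=8,
        topic_purity=0.7, words_per_abstract=30, n_background_words=60,
        n_benchmark_pairs=6, rng_seed=7,
    )


@pytest.fixture(scope="session")
def small_data(small_scenario):
    return generate_scenario(small_scenario)


@pytest.fixture(scope="session")
def default_data():
    """The reference scenario (the package's stated default conditions)."""
    return generate_scenario(SyntheticScenario())
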