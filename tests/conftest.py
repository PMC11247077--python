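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

from xfakesci import Article, Corpus, Label
from xfakesci.synthetic import SynthConfig, generate_paired_corpora


@pytest.fixture(scope="session")
def small_pair():
    """Paired synthetic corpora at reduced size: 100 train + 1 fold + 50 test."""
    cfg = SynthConfig(n_docs_per_class=250, seed=13)
    return generate_paired_corpora(cfg)


@pytest.fixture
def toy_corpus():
    return Corpus(
        (
            Article("a1", "Title one", "Mental health conditions worsen over time.",
                    Label.PUBMED, period="2010-2014"),
            Article("a2", "Title two", "Depression is a mental health condition.",
                    Label.PUBMED, period="2015-2019"),
            Article("a3", "Title three", "Cancer treatment improves survival.",
                    Label.GPT, period="2010-2014"),
        ),
        source_tag="toy",
    )
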