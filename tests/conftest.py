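import numpy as np
import pytest

import topictrends as tt


@pytest.fixture(scope="session")
def block_corpus():
    """Well-separated 4-topic corpus with planted truth (shared, read-only)."""
    spec = tt.SyntheticCorpusSpec(
        n_topics=4, vocab_size=100, n_docs=200, doc_length=50.0, seed=123
    )
    return tt.generate_corpus(spec)


@pytest.fixture(scope="session")
def block_model(block_corpus):
    """A fitted model on the block corpus (shared, read-only)."""
    return tt.fit_lda(
        block_corpus.dtm, 4, alpha=0.1, sweeps=300, burn_in=150, seed=123
    )


@pytest.fixture
def toy_records():
    return [
        tt.BibRecord("r1", "First paper", "Biodiversity supports ecosystem services.",
                     2005, 10, "article", "english"),
        tt.BibRecord("r2", "Second paper", "Soil carbon and forestry management.",
                     2006, 30, "review", "english"),
        tt.BibRecord("r3", "Third paper", None, 2007, 0, "article", "english"),
    ]


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)
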