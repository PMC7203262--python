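import numpy as np
import pytest

from igreader.infogain import (
    Corpus, LanguageModelConfig, split_high_low, word_statistics,
)
from igreader.simulate import EffectConfig, generate_corpus, generate_epochs, generate_session


@pytest.fixture(scope="session")
def tiny_corpus() -> Corpus:
    """Three hand-tokenized documents small enough for by-hand arithmetic."""
    return Corpus.from_token_lists(
        [
            ("geology", "the tectonic plates shift under the crust near hot magma".split()),
            ("cats", "the cat is a furry mammal and the cat purrs".split()),
            ("rome", "rome is a city and the tiber flows in rome".split()),
        ]
    )


@pytest.fixture(scope="session")
def zipf_corpus() -> Corpus:
    """The default Zipfian synthetic corpus."""
    return generate_corpus(seed=7)


@pytest.fixture(scope="session")
def zipf_stats(zipf_corpus):
    stats = word_statistics(zipf_corpus, LanguageModelConfig())
    weights = {w: zipf_corpus.corpus_count(w) for w in stats["word"]}
    return split_high_low(stats, weights=weights)


@pytest.fixture(scope="session")
def default_session(zipf_corpus):
    return generate_session(
        zipf_corpus, "sub00", n_blocks=8, sentences_per_doc=3,
        words_per_sentence=10, seed=1,
    )


@pytest.fixture(scope="session")
def default_epochs(default_session, zipf_stats):
    """One subject of epochs at the default effect configuration."""
    epochs, truth = generate_epochs(default_session, zipf_stats, EffectConfig(seed=3))
    return epochs, truth


@pytest.fixture(scope="session")
def clean_epochs(default_epochs):
    from igreader.preprocess import run_preprocessing

    epochs, _ = default_epochs
    return run_preprocessing(epochs)


def brute_force_information_gain(corpus, word, cfg) -> float:
    """Independent first-principles IG: explicit posterior + entropy sums."""
    n = corpus.n_documents
    priors = [1.0 / n] * n
    likelihoods = []
    for doc_id in corpus.doc_ids:
        c = corpus.count(word, doc_id)
        length = len(corpus.documents[doc_id])
        if cfg.smoothing == "none":
            lik = c / length
        elif cfg.smoothing == "dirichlet":
            p_c = corpus.corpus_count(word) / corpus.total_tokens
            lik = (c + cfg.mu * p_c) / (length + cfg.mu)
        else:
            p_c = corpus.corpus_count(word) / corpus.total_tokens
            lik = (1 - cfg.lam) * c / length + cfg.lam * p_c
        likelihoods.append(lik)
    joint = [l * p for l, p in zip(likelihoods, priors)]
    z = sum(joint)
    posterior = [j / z for j in joint]
    log = lambda x: np.log(x) / np.log(cfg.log_base)
    h_prior = -sum(p * log(p) for p in priors)
    h_post = -sum(p * log(p) for p in posterior if p > 0)
    return h_prior - h_post
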