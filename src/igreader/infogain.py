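"""Information gain of words over a document collection.

A word's information gain is the reduction in entropy over a document
collection obtained by observing the word:

    IG(D | w) = H(D) - H(D | w)

where ``H(D)`` is the entropy of a prior over documents (uniform here, so
``log N`` for ``N`` documents) and ``H(D | w)`` is the entropy of the
posterior ``P(d | w) ∝ P(w | d) P(d)``.  The per-document likelihoods
``P(w | d)`` come from smoothed unigram language models estimated from the
document's word counts (the query-likelihood model of ad-hoc retrieval).

Words that concentrate in few documents collapse the posterior and carry
high gain; words spread evenly across the collection leave the posterior
near uniform and carry none.  Alongside the gain this module computes the
classical lexical covariates (length, corpus log-frequency, functional vs
content class), the high/low gain split, and the measure-comparison report.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .stopwords import FUNCTIONAL_WORDS

__all__ = [
    "Corpus",
    "LanguageModelConfig",
    "tokenize",
    "build_corpus",
    "load_corpus_jsonl",
    "word_given_doc_probability",
    "document_posterior",
    "entropy",
    "information_gain",
    "word_statistics",
    "split_high_low",
    "measure_report",
]

# lowercase alphanumeric runs, keeping intra-word hyphens ("e-mail", "well-known")
_TOKEN_RE = re.compile(r"[a-z0-9]+(?:-[a-z0-9]+)*")


def tokenize(text: str) -> list[str]:
    """Lowercase ``text`` and split it into alphanumeric tokens.

    Punctuation is stripped; hyphens inside a word are kept so hyphenated
    compounds survive as single tokens.
    """
    return _TOKEN_RE.findall(text.lower())


@dataclass
class Corpus:
    """A tokenized document collection with cached count structures.

    Attributes
    ----------
    doc_ids : ordered document identifiers.
    documents : per-document token lists (lowercased).
    vocabulary : sorted array of distinct words.
    counts : ``(n_documents, vocab_size)`` integer matrix of word counts.
    """

    doc_ids: list[str]
    documents: dict[str, list[str]]
    vocabulary: np.ndarray = field(repr=False)
    counts: np.ndarray = field(repr=False)
    _word_index: dict[str, int] = field(repr=False)

    @classmethod
    def from_token_lists(cls, records: Sequence[tuple[str, Sequence[str]]]) -> "Corpus":
        doc_ids = [doc_id for doc_id, _ in records]
        if len(set(doc_ids)) != len(doc_ids):
            dupes = sorted({d for d in doc_ids if doc_ids.count(d) > 1})
            raise ValueError(f"duplicate doc_id(s): {dupes}")
        documents: dict[str, list[str]] = {}
        for doc_id, tokens in records:
            tokens = list(tokens)
            if not tokens:
                raise ValueError(f"document {doc_id!r} is empty after tokenization")
            documents[doc_id] = tokens
        vocabulary = np.array(sorted({w for toks in documents.values() for w in toks}))
        word_index = {w: i for i, w in enumerate(vocabulary)}
        counts = np.zeros((len(doc_ids), len(vocabulary)), dtype=np.int64)
        for row, doc_id in enumerate(doc_ids):
            for w in documents[doc_id]:
                counts[row, word_index[w]] += 1
        return cls(doc_ids, documents, vocabulary, counts, word_index)

    # -- count accessors ---------------------------------------------------
    @property
    def n_documents(self) -> int:
        return len(self.doc_ids)

    @property
    def doc_lengths(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @property
    def corpus_counts(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    @property
    def total_tokens(self) -> int:
        return int(self.counts.sum())

    def doc_row(self, doc_id: str) -> int:
        try:
            return self.doc_ids.index(doc_id)
        except ValueError:
            raise KeyError(f"unknown doc_id {doc_id!r}") from None

    def count(self, word: str, doc_id: str) -> int:
        col = self._word_index.get(word)
        if col is None:
            return 0
        return int(self.counts[self.doc_row(doc_id), col])

    def corpus_count(self, word: str) -> int:
        col = self._word_index.get(word)
        return 0 if col is None else int(self.corpus_counts[col])


def build_corpus(records: Iterable[tuple[str, str]]) -> Corpus:
    """Tokenize raw document texts into a :class:`Corpus`.

    Parameters
    ----------
    records : iterable of ``(doc_id, raw_text)`` pairs with unique ids.

    Raises
    ------
    ValueError : on duplicate ids or a document that tokenizes to nothing.
    """
    return Corpus.from_token_lists([(doc_id, tokenize(text)) for doc_id, text in records])


def load_corpus_jsonl(path: str | Path) -> Corpus:
    """Read a JSON-lines corpus (one ``{"id":…, "text":…}`` object per line)."""
    records = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            obj = json.loads(line)
            records.append((str(obj["id"]), str(obj["text"])))
    return build_corpus(records)


def load_corpus_dir(path: str | Path) -> Corpus:
    """Read a corpus from a directory of ``<doc_id>.txt`` files."""
    files = sorted(Path(path).glob("*.txt"))
    if not files:
        raise ValueError(f"no .txt documents found under {path}")
    return build_corpus([(f.stem, f.read_text()) for f in files])


def save_corpus_jsonl(corpus: Corpus, path: str | Path) -> None:
    with open(path, "w") as fh:
        for doc_id in corpus.doc_ids:
            fh.write(json.dumps({"id": doc_id, "text": " ".join(corpus.documents[doc_id])}) + "\n")


@dataclass(frozen=True)
class LanguageModelConfig:
    """Unigram language-model settings for the query-likelihood posterior.

    smoothing
        ``"dirichlet"`` (default): ``P(w|d) = (c(w,d) + mu·P(w|C)) / (|d| + mu)``
        with the corpus-wide unigram ``P(w|C)`` as the prior and ``mu`` in
        pseudo-token units. ``"jelinek_mercer"``: linear interpolation with
        weight ``lam`` on the corpus model. ``"none"``: maximum likelihood,
        zero probabilities allowed.
    log_base
        Base of every logarithm; 2 gives results in bits.
    """

    smoothing: str = "dirichlet"
    mu: float = 100.0
    lam: float = 0.5
    log_base: float = 2.0
    document_prior: str = "uniform"

    def __post_init__(self) -> None:
        if self.smoothing not in ("none", "dirichlet", "jelinek_mercer"):
            raise ValueError(f"unknown smoothing {self.smoothing!r}")
        if self.smoothing == "dirichlet" and not self.mu > 0:
            raise ValueError("dirichlet smoothing requires mu > 0")
        if self.smoothing == "jelinek_mercer" and not 0 < self.lam < 1:
            raise ValueError("jelinek_mercer smoothing requires 0 < lam < 1")
        if not self.log_base > 1:
            raise ValueError("log_base must exceed 1")
        if self.document_prior != "uniform":
            raise ValueError("only the uniform document prior is supported")


def _likelihood_matrix(corpus: Corpus, cfg: LanguageModelConfig) -> np.ndarray:
    """``P(w|d)`` for every (word, document), shape (vocab, n_documents)."""
    c = corpus.counts.T.astype(float)  # (V, D)
    lengths = corpus.doc_lengths.astype(float)
    if cfg.smoothing == "none":
        return c / lengths
    p_corpus = corpus.corpus_counts / corpus.total_tokens  # (V,)
    if cfg.smoothing == "dirichlet":
        return (c + cfg.mu * p_corpus[:, None]) / (lengths + cfg.mu)
    # jelinek_mercer
    return (1.0 - cfg.lam) * (c / lengths) + cfg.lam * p_corpus[:, None]


def _word_likelihoods(corpus: Corpus, word: str, cfg: LanguageModelConfig) -> np.ndarray:
    col = corpus._word_index.get(word)
    counts = corpus.counts[:, col].astype(float) if col is not None else np.zeros(corpus.n_documents)
    lengths = corpus.doc_lengths.astype(float)
    if cfg.smoothing == "none":
        if corpus.corpus_count(word) == 0:
            raise ValueError(
                f"word {word!r} is absent from the corpus; its probability is "
                "undefined without smoothing"
            )
        return counts / lengths
    p_c = corpus.corpus_count(word) / corpus.total_tokens
    if cfg.smoothing == "dirichlet":
        return (counts + cfg.mu * p_c) / (lengths + cfg.mu)
    return (1.0 - cfg.lam) * (counts / lengths) + cfg.lam * p_c


def word_given_doc_probability(
    corpus: Corpus, word: str, doc_id: str, cfg: LanguageModelConfig | None = None
) -> float:
    """Smoothed unigram probability ``P(word | doc_id)``."""
    cfg = cfg or LanguageModelConfig()
    row = corpus.doc_row(doc_id)
    return float(_word_likelihoods(corpus, word, cfg)[row])


def document_posterior(
    corpus: Corpus, word: str, cfg: LanguageModelConfig | None = None
) -> pd.Series:
    """Posterior ``P(d | word)`` over documents under the uniform prior."""
    cfg = cfg or LanguageModelConfig()
    lik = _word_likelihoods(corpus, word, cfg)
    total = lik.sum()  # uniform prior cancels in the normalisation
    if total <= 0:
        raise ValueError(f"word {word!r} has zero likelihood in every document")
    return pd.Series(lik / total, index=corpus.doc_ids, name=word)


def entropy(dist: Sequence[float] | pd.Series, log_base: float = 2.0) -> float:
    """Shannon entropy of a probability vector, with ``0·log 0 := 0``."""
    p = np.asarray(dist, dtype=float)
    if np.any(p < 0):
        raise ValueError("distribution has negative mass")
    if abs(p.sum() - 1.0) > 1e-6:
        raise ValueError(f"distribution sums to {p.sum()!r}, not 1")
    return float(sps.entropy(p, base=log_base))


def information_gain(
    corpus: Corpus, word: str, cfg: LanguageModelConfig | None = None
) -> float:
    """``IG(D|word) = H(D) − H(D|word)`` in units of ``log_base``."""
    cfg = cfg or LanguageModelConfig()
    posterior = document_posterior(corpus, word, cfg)
    prior_h = np.log(corpus.n_documents) / np.log(cfg.log_base)
    gain = prior_h - entropy(posterior.to_numpy(), cfg.log_base)
    # posterior entropy ≤ log N analytically; guard the floating-point floor
    return max(gain, 0.0)


def _all_information_gains(corpus: Corpus, cfg: LanguageModelConfig) -> np.ndarray:
    """Vectorised IG for every vocabulary word (rows of the likelihood matrix)."""
    lik = _likelihood_matrix(corpus, cfg)
    totals = lik.sum(axis=1, keepdims=True)
    if np.any(totals <= 0):
        bad = corpus.vocabulary[np.nonzero(totals.ravel() <= 0)[0][0]]
        raise ValueError(f"word {bad!r} has zero likelihood in every document")
    post = lik / totals
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(post > 0, post * np.log(post), 0.0)
    post_h = -plogp.sum(axis=1) / np.log(cfg.log_base)
    prior_h = np.log(corpus.n_documents) / np.log(cfg.log_base)
    return np.maximum(prior_h - post_h, 0.0)


def word_statistics(
    corpus: Corpus,
    cfg: LanguageModelConfig | None = None,
    functional_word_list: frozenset[str] | set[str] = FUNCTIONAL_WORDS,
) -> pd.DataFrame:
    """Per-word table of information gain and lexical covariates.

    One row per vocabulary type with columns ``word``, ``information_gain``
    (bits by default), ``log_frequency`` (log of the corpus-wide count),
    ``length`` (characters) and ``word_class`` (functional/content).  The
    ``ig_label`` column is added by :func:`split_high_low`.
    """
    cfg = cfg or LanguageModelConfig()
    words = corpus.vocabulary
    gains = _all_information_gains(corpus, cfg)
    counts = corpus.corpus_counts
    return pd.DataFrame(
        {
            "word": words,
            "information_gain": gains,
            "log_frequency": np.log(counts) / np.log(cfg.log_base),
            "length": [len(w) for w in words],
            "word_class": [
                "functional" if w in functional_word_list else "content" for w in words
            ],
        }
    )


def split_high_low(
    stats: pd.DataFrame,
    weights: Mapping[str, int] | None = None,
    criterion: str = "median",
) -> pd.DataFrame:
    """Label each word ``high`` or ``low`` by a median split on information gain.

    ``weights`` (word → presentation count) makes the median token-weighted,
    matching a split over presented tokens rather than types.  Values at the
    median are labelled ``low``.
    """
    if criterion != "median":
        raise ValueError(f"unknown split criterion {criterion!r}")
    values = stats["information_gain"].to_numpy(float)
    if len(stats) < 2 or np.unique(values).size < 2:
        raise ValueError("cannot split: fewer than 2 distinct information gain values")
    if weights is None:
        cutoff = float(np.median(values))
    else:
        w = stats["word"].map(weights).fillna(0).to_numpy(float)
        order = np.argsort(values, kind="stable")
        cum = np.cumsum(w[order])
        cutoff = float(values[order][np.searchsorted(cum, cum[-1] / 2.0)])
    out = stats.copy()
    out["ig_label"] = np.where(values > cutoff, "high", "low")
    out.attrs["split_cutoff"] = cutoff
    return out


def measure_report(stats: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Correlations and per-measure rankings of the lexical measures.

    Returns
    -------
    corr : 3×3 symmetric Pearson correlation matrix over word length,
        log-frequency and information gain (unit diagonal).
    ranks : words sorted descending under each measure, one column per
        measure, rows indexed by rank (1-based).
    """
    if len(stats) < 3:
        raise ValueError("measure report requires at least 3 words")
    measures = ["length", "log_frequency", "information_gain"]
    for m in measures:
        if np.std(stats[m].to_numpy(float)) == 0:
            raise ValueError(f"measure {m!r} has zero variance; correlation undefined")
    corr = stats[measures].astype(float).corr(method="pearson")
    np.fill_diagonal(corr.to_numpy(), 1.0)
    ranks = pd.DataFrame(
        {
            m: stats.sort_values(m, ascending=False, kind="stable")["word"].to_numpy()
            for m in measures
        },
        index=pd.RangeIndex(1, len(stats) + 1, name="rank"),
    )
    return corr, ranks
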