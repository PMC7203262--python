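"""Simulation studies that validate the statistical machinery.

These run the generator → statistics path many times at reduced problem
sizes to measure operating characteristics: type-I error and power of the
mixed-model likelihood-ratio test, and the chance level of the decoder
under permuted labels.  The reduced sizes (few subjects, two blocks, a
small montage) keep hundreds of replicates affordable on one CPU while
preserving the crossed subject/word structure the models assume.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import decode, erpstats, simulate
from .infogain import Corpus, split_high_low, word_statistics
from .preprocess import baseline_correct

#: montage for repeated simulations: the two component channels plus midline
SMALL_MONTAGE = ["Fz", "Cz", "Pz", "Oz"]

NULL_EFFECT = dict(eps_slope=0.0, p200_slope=0.0, artifact_fraction=0.0)

#: session geometry for power studies: longer than the null-calibration
#: session because the word-level gain effect is identified across types
POWER_SESSION = {"n_blocks": 3, "sentences_per_doc": 3, "words_per_sentence": 10}


def small_corpus_and_stats(seed: int = 7) -> tuple[Corpus, pd.DataFrame]:
    """A compact scored corpus reused across simulation replicates."""
    corpus = simulate.generate_corpus(
        n_documents=8, n_topic_words_per_doc=15, n_shared_words=80,
        doc_length=200, seed=seed,
    )
    stats = word_statistics(corpus)
    stats = split_high_low(stats, weights={w: corpus.corpus_count(w) for w in stats["word"]})
    return corpus, stats


def _replicate_table(
    corpus: Corpus,
    stats: pd.DataFrame,
    n_subjects: int,
    effect: simulate.EffectConfig,
    seed: int,
    session: dict | None = None,
) -> pd.DataFrame:
    """One simulated study reduced to its standardized component table."""
    session = session or {}
    study = simulate.generate_study(
        corpus, stats, n_subjects=n_subjects, effect=effect, seed=seed,
        channel_names=SMALL_MONTAGE,
        n_blocks=session.get("n_blocks", 2),
        sentences_per_doc=session.get("sentences_per_doc", 3),
        words_per_sentence=session.get("words_per_sentence", 8),
    )
    tables = [
        erpstats.component_means(baseline_correct(ep), stats=stats)
        for _, ep, _ in study
    ]
    return erpstats.standardize(pd.concat(tables, ignore_index=True))


def lrt_rejection_rate(
    n_replicates: int,
    eps_slope: float,
    n_subjects: int,
    seed: int = 0,
    alpha: float = 0.05,
    dependent: str = "EPS",
    session: dict | None = None,
) -> tuple[float, list[float]]:
    """Fraction of replicates whose information-gain LRT rejects at *alpha*.

    ``eps_slope=0`` measures type-I error; a nonzero slope measures power.
    Artifacts are disabled (the rejection stage is validated separately)
    and the random structure is the crossed subject/word intercepts.
    *session* overrides the replicate session geometry (blocks, sentences,
    words per sentence); power studies use a longer session than the null
    calibration because the gain effect is identified across word types.
    Returns the rate and the raw p-values.
    """
    corpus, stats = small_corpus_and_stats()
    rng = np.random.default_rng(seed)
    pvals = []
    for _ in range(n_replicates):
        effect = simulate.EffectConfig(
            eps_slope=eps_slope, p200_slope=0.0, artifact_fraction=0.0,
            seed=int(rng.integers(2**31 - 1)),
        )
        table = _replicate_table(corpus, stats, n_subjects, effect,
                                 seed=int(rng.integers(2**31 - 1)),
                                 session=session)
        comparison = erpstats.lrt_information_gain(
            table, dependent, random_terms=["subject", "word"]
        )
        pvals.append(comparison.p_raw)
    rate = float(np.mean(np.asarray(pvals) < alpha))
    return rate, pvals


def null_decoding_auc(
    n_seeds: int = 20,
    seed: int = 1,
    epochs_per_block: int = 100,
    window_ms: float = 50.0,
) -> tuple[float, list[float]]:
    """Mean leave-one-block-out AUC on signal-free epochs with permuted labels.

    One synthetic subject per seed: 8 blocks of *epochs_per_block* epochs
    (balanced median-split labels), a flat effect configuration, labels
    permuted before the full cross-validated evaluation.  The grand mean
    over seeds estimates the decoder's chance level.
    """
    corpus = simulate.generate_corpus(seed=7)
    stats = word_statistics(corpus)
    stats = split_high_low(stats, weights={w: corpus.corpus_count(w) for w in stats["word"]})
    sentences = epochs_per_block // 20  # 2 docs x sentences x 10 words = epochs_per_block
    rng = np.random.default_rng(seed)
    aucs = []
    for _ in range(n_seeds):
        s = int(rng.integers(2**31 - 1))
        plan = simulate.generate_session(
            corpus, "sub00", n_blocks=8,
            sentences_per_doc=sentences, words_per_sentence=10, seed=s,
        )
        effect = simulate.EffectConfig(**NULL_EFFECT, seed=s + 1)
        epochs, _ = simulate.generate_epochs(plan, stats, effect)
        feat = decode.featurize(epochs, window_ms=window_ms)
        feat.y = np.random.default_rng(s + 2).permutation(feat.y)
        aucs.append(decode.leave_one_block_out(feat).auc_mean)
    return float(np.mean(aucs)), aucs
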