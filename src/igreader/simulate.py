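"""Synthetic corpora, RSVP reading sessions and multi-channel EEG epochs.

The generator stands in for the study conditions the analysis expects:

* a topical document collection whose shared vocabulary follows a Zipfian
  rank–frequency law (so information gain and corpus log-frequency are
  strongly inversely related) with document-specific topic words;
* a reading session of 8 blocks, each a pair of documents whose sentences
  are presented in alternating order, one word every 700 ms, with a binary
  per-block document preference;
* 32-channel epochs spanning −200..1000 ms around each word containing
  coloured noise, subject and word random intercepts, a parietal positive
  shift (250–700 ms, Pz-centred) whose amplitude is linear in standardized
  information gain, a frontal P200 template (100–250 ms, Fz-centred), and a
  planted fraction of high-voltage artifact epochs.

Everything is deterministic given its seed, and every injected quantity
(artifact indices, per-epoch component amplitudes, random intercepts) is
returned as ground truth so recovery can be measured.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from . import montage as mont
from .epochs import EpochArray, default_times
from .infogain import Corpus
from .stopwords import FUNCTIONAL_WORD_LIST

__all__ = [
    "EffectConfig",
    "SessionPlan",
    "generate_corpus",
    "generate_session",
    "generate_epochs",
    "generate_study",
]


@dataclass(frozen=True)
class EffectConfig:
    """Amplitudes, noise and nuisance structure of the injected EEG signal.

    All amplitudes are in microvolts; slopes are microvolts per standard
    deviation of information gain across the presented epochs.  The default
    effect sign is positive for the parietal shift (higher gain, larger
    positivity) and negative for the frontal P200 (low-gain words drive the
    early frontal positivity).
    """

    eps_slope: float = 1.5
    eps_window: tuple[float, float] = (250.0, 700.0)
    p200_slope: float = -0.5
    p200_window: tuple[float, float] = (100.0, 250.0)
    noise_model: str = "ar1"  # white | ar1 | one_over_f
    noise_scale: float = 8.0
    ar1_phi: float = 0.7
    subject_intercept_sd: float = 2.0
    word_intercept_sd: float = 1.0
    artifact_fraction: float = 0.05
    artifact_amplitude: float = 500.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.noise_scale > 0:
            raise ValueError("noise_scale must be positive")
        if not 0 <= self.artifact_fraction < 1:
            raise ValueError("artifact_fraction must be in [0, 1)")
        if self.subject_intercept_sd < 0 or self.word_intercept_sd < 0:
            raise ValueError("intercept SDs must be nonnegative")
        if self.noise_model not in ("white", "ar1", "one_over_f"):
            raise ValueError(f"unknown noise model {self.noise_model!r}")


@dataclass
class SessionPlan:
    """One subject's reading session: blocks of document pairs plus the
    ordered word presentations at a fixed stimulus-onset asynchrony."""

    subject_id: str
    blocks: list[dict]  # {"block", "doc_ids": [a, b], "preferred": doc_id}
    presentations: pd.DataFrame  # word, doc_id, block, onset_ms, preference

    @property
    def n_presentations(self) -> int:
        return len(self.presentations)


def generate_corpus(
    n_documents: int = 20,
    n_topic_words_per_doc: int = 30,
    n_shared_words: int = 150,
    zipf_exponent: float = 1.2,
    doc_length: int = 400,
    seed: int = 0,
) -> Corpus:
    """Zipfian topical corpus: shared words drawn corpus-wide, topic words
    unique to one document each.

    The most frequent shared ranks reuse real English function words so the
    functional/content covariate varies; remaining shared ranks and all
    topic words are synthetic content strings.  Deterministic given *seed*.
    """
    if n_documents < 1:
        raise ValueError("need at least one document")
    n_topic_tokens = 3 * n_topic_words_per_doc
    if doc_length < n_topic_tokens:
        raise ValueError(
            f"doc_length={doc_length} cannot hold {n_topic_words_per_doc} topic "
            f"words at ~3 tokens each (needs ≥ {n_topic_tokens})"
        )
    rng = np.random.default_rng(seed)
    shared_vocab = [
        FUNCTIONAL_WORD_LIST[i] if i < len(FUNCTIONAL_WORD_LIST) else f"lemma{i:03d}"
        for i in range(n_shared_words)
    ]
    ranks = np.arange(1, n_shared_words + 1, dtype=float)
    zipf_p = ranks ** -zipf_exponent
    zipf_p /= zipf_p.sum()

    records = []
    for d in range(n_documents):
        topic_words = [f"topic{d:02d}w{i:02d}" for i in range(n_topic_words_per_doc)]
        topic_tokens: list[str] = []
        for w in topic_words:
            topic_tokens.extend([w] * (1 + rng.poisson(2.0)))
        topic_tokens = topic_tokens[:doc_length]
        n_shared_tokens = doc_length - len(topic_tokens)
        shared_idx = rng.choice(n_shared_words, size=n_shared_tokens, p=zipf_p)
        tokens = topic_tokens + [shared_vocab[i] for i in shared_idx]
        rng.shuffle(tokens)
        records.append((f"doc{d:02d}", tokens))
    return Corpus.from_token_lists(records)


def generate_session(
    corpus: Corpus,
    subject_id: str,
    n_blocks: int = 8,
    sentences_per_doc: int = 6,
    words_per_sentence: int = 12,
    soa_ms: float = 700.0,
    seed: int = 0,
) -> SessionPlan:
    """Plan a reading session: pair documents into blocks and lay out the
    word-by-word presentations.

    Within a block the two documents' sentences alternate, the leading
    document swapping every trial; words appear at ``soa_ms`` spacing with
    onsets restarting at 0 within each block.  "Sentences" are consecutive
    ``words_per_sentence``-token chunks of the document.
    """
    needed = 2 * n_blocks
    if corpus.n_documents < needed:
        raise ValueError(
            f"corpus has {corpus.n_documents} documents; {needed} needed for "
            f"{n_blocks} blocks"
        )
    span = sentences_per_doc * words_per_sentence
    for doc_id in corpus.doc_ids:
        if len(corpus.documents[doc_id]) < span:
            raise ValueError(
                f"document {doc_id!r} has fewer than {span} tokens for "
                f"{sentences_per_doc} sentences of {words_per_sentence} words"
            )
    rng = np.random.default_rng(seed)
    chosen = list(rng.permutation(corpus.doc_ids)[:needed])
    blocks, rows = [], []
    for b in range(n_blocks):
        pair = chosen[2 * b : 2 * b + 2]
        preferred = pair[int(rng.integers(2))]
        blocks.append({"block": b, "doc_ids": list(pair), "preferred": preferred})
        sentences = {
            doc_id: [
                corpus.documents[doc_id][s * words_per_sentence : (s + 1) * words_per_sentence]
                for s in range(sentences_per_doc)
            ]
            for doc_id in pair
        }
        onset = 0.0
        for trial in range(sentences_per_doc):
            order = pair if trial % 2 == 0 else pair[::-1]
            for doc_id in order:
                for word in sentences[doc_id][trial]:
                    rows.append(
                        {
                            "word": word,
                            "doc_id": doc_id,
                            "block": b,
                            "onset_ms": onset,
                            "preference": int(doc_id == preferred),
                        }
                    )
                    onset += soa_ms
    return SessionPlan(subject_id, blocks, pd.DataFrame(rows))


def _raised_cosine_template(
    times: np.ndarray, window: tuple[float, float], ramp_ms: float = 50.0
) -> np.ndarray:
    """Unit-mean plateau over *window* with raised-cosine onset/offset.

    Normalised so its mean over the (closed) window samples is exactly 1,
    making injected slopes read directly in window-mean microvolts.
    """
    lo, hi = window
    g = np.zeros_like(times, dtype=float)
    inside = (times >= lo) & (times <= hi)
    t = times[inside]
    shape = np.ones_like(t)
    rise = t < lo + ramp_ms
    fall = t > hi - ramp_ms
    shape[rise] = 0.5 * (1 - np.cos(np.pi * (t[rise] - lo) / ramp_ms))
    shape[fall] = 0.5 * (1 - np.cos(np.pi * (hi - t[fall]) / ramp_ms))
    g[inside] = shape
    mean_in_window = g[inside].mean()
    if mean_in_window <= 0:
        raise ValueError("component window too narrow for the template ramps")
    return g / mean_in_window


def _profile_vector(channel_names: Sequence[str], profile: dict[str, float]) -> np.ndarray:
    return np.array([profile.get(ch, 0.0) for ch in channel_names])


def _coloured_noise(rng: np.random.Generator, shape: tuple, effect: EffectConfig) -> np.ndarray:
    white = rng.standard_normal(shape)
    if effect.noise_model == "white":
        return effect.noise_scale * white
    if effect.noise_model == "ar1":
        phi = effect.ar1_phi
        ar = lfilter([1.0], [1.0, -phi], white, axis=-1)
        return effect.noise_scale * np.sqrt(1.0 - phi**2) * ar
    # one_over_f: shape the amplitude spectrum as f^-1/2, keep unit variance
    n = shape[-1]
    freqs = np.fft.rfftfreq(n, d=1.0)
    scale = np.ones_like(freqs)
    scale[1:] = freqs[1:] ** -0.5
    spec = np.fft.rfft(white, axis=-1) * scale
    pink = np.fft.irfft(spec, n=n, axis=-1)
    pink /= pink.std(axis=-1, keepdims=True)
    return effect.noise_scale * pink


def generate_epochs(
    plan: SessionPlan,
    stats: pd.DataFrame,
    effect: EffectConfig | None = None,
    channel_names: Sequence[str] | None = None,
    sfreq: float = 250.0,
    word_effects: dict[str, float] | None = None,
    subject_intercept: float | None = None,
) -> tuple[EpochArray, dict]:
    """Render one epoch per planned presentation, plus its ground truth.

    Per-epoch signal = coloured noise + (eps_slope·z(IG) + subject intercept
    + word intercept) × parietal template + p200_slope·z(IG) × frontal
    template; a random ``artifact_fraction`` of epochs receives a ±500 µV
    excursion on a central channel inside −100..600 ms.  ``word_effects``
    and ``subject_intercept`` may be supplied to share random effects across
    subjects; otherwise they are drawn here.
    """
    effect = effect or EffectConfig()
    channel_names = list(channel_names or mont.CHANNELS_32)
    for required in ("Fz", "Pz"):
        if required not in channel_names:
            raise ValueError(f"montage lacks required channel {required!r}")
    rng = np.random.default_rng(effect.seed)
    pres = plan.presentations
    missing = set(pres["word"]) - set(stats["word"])
    if missing:
        raise ValueError(f"presented words missing from stats: {sorted(missing)[:5]} …")

    lookup = stats.set_index("word")
    ig = lookup.loc[pres["word"], "information_gain"].to_numpy(float)
    sd = ig.std()
    z = (ig - ig.mean()) / sd if sd > 0 else np.zeros_like(ig)

    words = pres["word"].to_numpy()
    if word_effects is None:
        uniq = sorted(set(words))
        draws = rng.normal(0.0, effect.word_intercept_sd, len(uniq))
        word_effects = dict(zip(uniq, draws))
    if subject_intercept is None:
        subject_intercept = float(rng.normal(0.0, effect.subject_intercept_sd))
    b_word = np.array([word_effects[w] for w in words])

    times = default_times(sfreq)
    n_epochs, n_ch, n_samp = len(pres), len(channel_names), len(times)
    data = _coloured_noise(rng, (n_epochs, n_ch, n_samp), effect)

    eps_t = _raised_cosine_template(times, effect.eps_window)
    p200_t = _raised_cosine_template(times, effect.p200_window, ramp_ms=30.0)
    eps_sp = _profile_vector(channel_names, mont.EPS_PROFILE)
    p200_sp = _profile_vector(channel_names, mont.P200_PROFILE)

    a_eps = effect.eps_slope * z + subject_intercept + b_word
    a_p200 = effect.p200_slope * z
    data += a_eps[:, None, None] * eps_sp[None, :, None] * eps_t[None, None, :]
    data += a_p200[:, None, None] * p200_sp[None, :, None] * p200_t[None, None, :]

    n_artifacts = int(round(effect.artifact_fraction * n_epochs))
    artifact_idx = np.sort(rng.choice(n_epochs, size=n_artifacts, replace=False))
    central_present = [c for c in mont.CENTRAL_CHANNELS if c in channel_names]
    for i in artifact_idx:
        ch = channel_names.index(central_present[int(rng.integers(len(central_present)))])
        t0 = float(rng.uniform(-100.0, 600.0))
        sign = 1.0 if rng.integers(2) else -1.0
        window = (times >= t0) & (times < t0 + 50.0)
        data[i, ch, window] += sign * effect.artifact_amplitude

    metadata = pres.copy().reset_index(drop=True)
    metadata.insert(0, "subject", plan.subject_id)
    metadata["information_gain"] = ig
    if "ig_label" in lookup.columns:
        metadata["ig_label"] = lookup.loc[pres["word"], "ig_label"].to_numpy()

    truth = {
        "artifact_indices": artifact_idx.tolist(),
        "eps_amplitude": a_eps.tolist(),
        "p200_amplitude": a_p200.tolist(),
        "subject_intercept": subject_intercept,
        "word_effects": dict(word_effects),
    }
    return EpochArray(data, times, sfreq, channel_names, metadata), truth


def generate_study(
    corpus: Corpus,
    stats: pd.DataFrame,
    n_subjects: int = 15,
    effect: EffectConfig | None = None,
    seed: int = 0,
    channel_names: Sequence[str] | None = None,
    sfreq: float = 250.0,
    **session_kwargs,
) -> list[tuple[SessionPlan, EpochArray, dict]]:
    """Simulate a multi-subject study sharing one set of word intercepts.

    Word random effects are drawn once for the whole vocabulary so they are
    crossed with subjects (the structure the mixed models assume); each
    subject gets an independent session plan, intercept and noise stream,
    all derived deterministically from *seed*.
    """
    effect = effect or EffectConfig()
    rng = np.random.default_rng(seed)
    word_effects = dict(
        zip(stats["word"], rng.normal(0.0, effect.word_intercept_sd, len(stats)))
    )
    out = []
    for s in range(n_subjects):
        plan = generate_session(
            corpus, f"sub{s:02d}", seed=int(rng.integers(2**31 - 1)), **session_kwargs
        )
        sub_effect = replace(effect, seed=int(rng.integers(2**31 - 1)))
        intercept = float(rng.normal(0.0, effect.subject_intercept_sd))
        ep, truth = generate_epochs(
            plan, stats, sub_effect, channel_names, sfreq,
            word_effects=word_effects, subject_intercept=intercept,
        )
        out.append((plan, ep, truth))
    return out
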