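# Methods

## The word score

For a document collection *D* of *N* documents and a word *w*, the
information gain is the entropy reduction

    IG(D|w) = H(D) − H(D|w),

where the prior over documents is uniform, so `H(D) = log₂ N` bits, and the
posterior is obtained by Bayes' rule from smoothed unigram document language
models (the query-likelihood model):

    P(d|w) ∝ P(w|d) · P(d),     P(w|d) = (c(w,d) + μ·P(w|C)) / (|d| + μ).

`c(w,d)` is the count of *w* in *d*, `|d|` the document length in tokens,
`P(w|C)` the corpus-wide unigram probability, and μ the Dirichlet
pseudo-count mass. A word concentrated in few documents collapses the
posterior (`IG → log₂ N`); a word spread proportionally across all documents
leaves it uniform (`IG = 0`). IG is always in `[0, log₂ N]`.

Choices and their rationale:

* **Dirichlet smoothing, μ = 100 by default.** The standard query-likelihood
  instantiation. μ is in pseudo-token units and should be scaled with
  document length; 100 against the default 400-token synthetic documents
  gives moderate smoothing. Jelinek–Mercer interpolation and the raw
  maximum-likelihood model are selectable through `LanguageModelConfig`.
* **Log base 2** (bits) everywhere; configurable.
* **Uniform document prior.** The only prior implemented; the posterior
  normalisation then cancels it.
* **Scoring per word type.** Every occurrence of a word string carries the
  same score.
* **Tokenization**: lowercase, alphanumeric runs, intra-word hyphens kept.
* **Word class** (functional vs content) is membership in a shipped
  closed-class list (determiners, prepositions, conjunctions, pronouns,
  auxiliaries).
* **High/low split**: median over presented word *tokens* (a token-weighted
  median over types), ties at the median labelled *low*. Because frequent
  words have low gain, the token-weighted median sits far down the type
  distribution: roughly half of presented *epochs* are high-gain while most
  *types* are. Both the criterion and the tie rule are deterministic.

One property worth knowing: under Dirichlet smoothing, IG is **not**
monotone in the count of *w* in a single document — adding occurrences also
raises the corpus-wide background `P(w|C)`, which lifts every other
document's smoothed likelihood and can lower the gain. Under the
maximum-likelihood model monotonicity holds, and the test suite asserts it
there.

## The synthetic study

No real reading EEG or reference corpus ships with the package; the
`simulate` module generates the full study so that every downstream stage
is testable.

**Corpus.** 20 documents of 400 tokens (defaults). Each document mixes
~90 tokens of 30 document-unique topic words with shared words drawn from a
Zipfian rank-frequency law (exponent 1.2) over 150 types whose most
frequent ranks are real English function words. This reproduces the two
regularities the analysis depends on: a strong inverse correlation between
information gain and log-frequency (r ≈ −0.8 on the default corpus), and a
functional/content covariate that varies. Topic-word strings have uniform
length, so the length–gain correlation is stronger in the synthetic corpus
than in natural text; treat length effects on synthetic data accordingly.

**Session.** 8 blocks per subject, each pairing two unseen documents with a
random binary preference. Within a block the documents' "sentences"
(consecutive 12-token chunks; 6 per document by default) are presented in
alternating order, the leading document swapping every trial, one word per
700 ms.

**Epochs.** −200..1000 ms around each word at 250 Hz (a sampling rate chosen
as typical for this class of recordings), 32 channels named after a
standard 10–20-style equidistant cap. Per epoch the signal is

    coloured noise
    + (eps_slope·z(IG) + b_subject + b_word) × parietal template
    + p200_slope·z(IG) × frontal template
    (+ a rectangular ±500 µV excursion on a central channel
       for a random 5% of epochs)

with `z(IG)` the gain standardized over the subject's presentations,
`b_subject ~ N(0, 2²)` µV and `b_word ~ N(0, 1²)` µV random intercepts
(word effects drawn once per study so they are crossed with subjects). The
parietal template is a raised-cosine-edged plateau over 250–700 ms whose
window mean is normalised to exactly 1 at Pz, so `eps_slope` reads directly
in µV per SD of gain; its spatial profile is Pz-centred (with a small
frontal tail so that frontal component means inherit the random-intercept
structure). The frontal template covers 100–250 ms, Fz-centred. Defaults:
`eps_slope = +1.5` µV (higher gain → larger parietal positivity, the sign
configurable), `p200_slope = −0.5` µV (low-gain words drive the early
frontal positivity), AR(1) noise with φ = 0.7 scaled to 8 µV marginal SD —
single-trial amplitudes typical of scalp EEG, and an SNR at which one
subject's session decodes at AUC ≈ 0.65–0.8, bracketing what single-trial
ERP classifiers achieve in practice.

What the generator does **not** emulate: volume-conducted spatial noise
correlations, ocular/muscle artifact morphology, autocorrelation between
consecutive epochs (the 700-ms SOA means real epochs overlap), drifting
electrode impedances, and any semantics — the "effect" is injected directly
as a linear function of the score. Passing tests therefore demonstrate that
the pipeline recovers what was planted under realistic noise, not that real
brains behave this way.

## Preprocessing

* **Band-pass 0.25–35 Hz**: Hamming-window linear-phase FIR, order from the
  3.3/transition-width heuristic (0.5 Hz transition ⇒ 1651 taps at 250 Hz),
  applied in a single pass with group-delay compensation. Passband 1–30 Hz
  within ±0.5%, DC gain < 0.01, ≥40 dB above 40 Hz.
* **Epoching/baseline**: −200..1000 ms windows; the mean over [−200, 0) ms
  subtracted per epoch and channel (idempotent). Onsets too close to a
  recording edge are dropped and counted.
* **Artifact threshold**: per epoch, the absolute-maximum voltage over the
  13 central channels (F3, Fz, F4, FC1, FC2, C3, Cz, C4, CP1, CP2, P3, Pz,
  P4) within −200..700 ms; the participant's threshold is the 80th
  percentile of these maxima under the **nearest-rank** convention
  (recorded in the QC block). Epochs strictly above threshold are rejected.
* **Bad channels**: a channel is invalid in an epoch if its own absolute
  maximum exceeds the threshold; channels invalid in strictly more than 20%
  of epochs are rebuilt as the unweighted mean of their good neighbours
  (shipped adjacency map). Spline interpolation is deliberately out of
  scope for an equidistant 32-channel cap.
* **Order**: threshold → bad-channel flagging → interpolation → rejection
  computed on the interpolated data. Rationale: a globally bad channel
  should not cost every epoch it corrupts when its neighbours can rebuild
  it; only then is the per-epoch rejection meaningful.

## Component statistics

Components are window means at fixed channels: parietal shift (EPS)
250–700 ms and P300 250–350, N400 350–500, P600 500–800 ms at Pz; P200
100–250 ms at Fz. Windows are closed intervals on the sample grid (at
250 Hz the 250–700 ms window holds samples 252..700 ms, so a ramp's window
mean sits 0.01 µV off the idealized midpoint — the tests account for the
grid).

Per retained epoch the component means are joined with the word covariates
(gain, length, log-frequency, class) and the preference flag, continuous
variables are z-scored, and each component is modelled as

    component ~ information_gain + length + log_frequency
                + word_class + preference
                + (1 | subject) + (1 | word)

fit by **maximum likelihood** (not REML — the model pairs compared by the
likelihood-ratio test differ in fixed effects, for which REML likelihoods
are not comparable). Crossed random intercepts are expressed as variance
components over a single grouping level. The maximal structure attempted
also includes a by-subject gain slope; non-converging fits drop the
smallest-variance term until convergence, and the removal trail is kept.
The gain effect is tested by `χ² = 2·Δloglik` against `χ²₁`; the four
component models are Bonferroni-corrected with m = 4, the EPS model is
reported uncorrected. R² follows the fixed/random variance decomposition:
marginal = var(Xβ̂)/(var(Xβ̂)+Σσ̂²_random+σ̂²), conditional adds the random
variances to the numerator.

Numerical care: profiled-likelihood surfaces for small variance components
are nearly flat, and a single quasi-Newton run can stall short of the
optimum or report convergence at a suboptimal point — which corrupts
likelihood-ratio statistics (we observed null χ² values inflated several-
fold this way). Fits therefore accept a cleanly converged BFGS run and
otherwise fall back to derivative-free optimizers (Powell, then CG),
keeping the best likelihood; agreement of two optimizers within 10⁻²
log-likelihood units also counts as convergence. A constant gain column
(zero variance) short-circuits to χ² = 0, p = 1 rather than fitting a
singular design.

## Decoding

Features: mean voltage per channel in 50-ms windows tiling [0, 1000) ms
(32 × 20 = 640 features; the pipeline default uses 100-ms windows for
speed). Classifier: linear discriminant with the pooled within-class
covariance shrunk toward a scaled identity, `Σ̃ = (1−γ)S + γ(tr S/p)I`,
γ from the Ledoit–Wolf analytic estimator on class-centred data (fixed γ
selectable). Evaluation: leave-one-block-out over the 8 reading blocks,
features z-scored with training-fold statistics only; blocks missing a
class are excluded and counted. Performance is the rank-statistic AUC
(ties ½). Significance: the whole cross-validation is re-run on labels
permuted across the subject's epochs, `p = (b+1)/(k+1)` with *b* the count
of permutation mean-AUCs at or above the observed one — never zero, floor
1/(k+1), i.e. 0.001 at the k = 1000 default. The confidence report pools
out-of-fold decision scores per (document, word) and lists the top-5 words
per predicted class next to the ground-truth extremes by actual gain.

## Operating characteristics (simulation studies)

The `validation` module measures, at reduced problem sizes chosen so the
studies run in minutes on one CPU:

* **Decoder chance level**: 8 blocks × 100 signal-free epochs, labels
  permuted, full leave-one-block-out evaluation; the mean AUC over 20
  seeds sits within ±0.03 of 0.5.
* **Type-I error of the gain LRT**: 4 subjects × 96 epochs (2 blocks,
  3 sentences × 8 words), a 4-channel montage, effect off. This size was
  chosen as the smallest at which the asymptotic χ²₁ reference is
  trustworthy: with materially fewer observations per word the word
  variance component frequently hits the zero boundary and the test runs
  visibly anticonservative.
* **Power**: 15 subjects at the default +1.5 µV effect with a longer
  session (3 blocks, 3 sentences × 10 words, 180 epochs/subject). Power
  for the *partial* gain effect is governed by the ~30% of gain variance
  that its collinear covariates (log-frequency, class, length) leave
  unexplained — a deliberately conservative design mirrored from the
  analysis model, which is why the session must be this long to reach
  high power.

## Known limitations

* The mixed models ship a single family of random structures (intercepts
  plus an optional by-subject gain slope); arbitrary lme4-style formulas
  are out of scope.
* Neighbour-mean interpolation is crude compared to spherical splines and
  is only defensible for small equidistant caps.
* The permutation test permutes labels across all of a subject's epochs;
  block-stratified permutation is a config away but not the default.
* Synthetic topic words share a fixed string length, inflating the
  length–gain correlation relative to natural text.
* The generator's epochs are mutually independent; consecutive real RSVP
  epochs at a 700-ms SOA are not.
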