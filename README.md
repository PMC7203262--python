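# igreader

Corpus-level word informativeness meets word-synchronised EEG. `igreader`
implements, as a tested analysis pipeline, the chain from an
information-theoretic word score to event-related potential (ERP)
statistics and single-trial decoding:

1. **Score** every word of a document collection by its *information gain*
   — the entropy drop over documents after observing the word,
   `IG(D|w) = H(D) − H(D|w)`, with the posterior `P(d|w) ∝ P(w|d)·P(d)`
   from Dirichlet-smoothed unigram language models (the query-likelihood
   model). Frequent, everywhere-usable words gain almost nothing; words
   tied to one topic gain up to `log₂ N` bits.
2. **Simulate** the study the analysis expects: a Zipfian topical corpus,
   rapid serial visual presentation sessions (8 blocks of document pairs,
   one word per 700 ms), and 32-channel epochs (−200..1000 ms) carrying a
   parietal positive shift whose amplitude is linear in standardized gain,
   subject/word random intercepts, coloured noise and planted artifacts —
   with full ground truth.
3. **Preprocess**: FIR band-pass 0.25–35 Hz, baseline correction, a
   per-participant artifact threshold (80th percentile, nearest rank, of
   central-channel absolute maxima in −200..700 ms), strict-over-20%
   bad-channel flagging with neighbour-mean interpolation.
4. **Test** the gain effect on ERP components (parietal shift 250–700 ms at
   Pz; P200, P300, N400, P600) with linear mixed models — crossed random
   intercepts for subjects and word types, maximum-likelihood fits — via
   likelihood-ratio tests, Bonferroni m = 4 across the four component
   models, plus marginal/conditional R².
5. **Decode** high vs low gain from single epochs with a shrinkage-
   regularized linear discriminant, leave-one-block-out AUC, and a
   label-permutation test (`p = (b+1)/(k+1)`, floor 0.001 at k = 1000).

Intended users: cognitive-neuroscience and neurolinguistics researchers who
want a reproducible reference implementation of this analysis chain, and
methodologists who want its operating characteristics on data with known
ground truth.

## Worked example

Run the numbered drivers in order (or `igreader run --out results/run`):

```bash
cd analysis
python 01_simulate.py      # corpus + 4 subjects of epochs + ground truth
python 02_score_corpus.py  # per-word gain, covariates, high/low split
python 03_preprocess.py    # thresholds, rejection, interpolation
python 04_component_stats.py
python 05_decode.py
python 06_report.py
```

`02_score_corpus.py` prints the measure-comparison matrix; on the default
corpus (seed 7):

```
                  length  log_frequency  information_gain
length             1.000         -0.713             0.949
log_frequency     -0.713          1.000            -0.778
information_gain   0.949         -0.778             1.000
```

— information gain and corpus log-frequency are strongly inversely
related, which is exactly why the mixed models control for frequency when
testing the gain effect. `03_preprocess.py` reports per-subject thresholds
of ~33 µV with 100% recall of the planted 500 µV artifacts.
`04_component_stats.py` prints the component table:

```
component   slope    chi2        p   p_bonf    R2m    R2c
EPS         0.470    6.89   0.0086   0.0086  0.156  0.370
P200        0.086    0.27   0.6003   1.0000  0.005  0.006
P300        0.349    3.83   0.0503   0.2010  0.072  0.170
N400        0.431    6.19   0.0128   0.0513  0.149  0.329
P600        0.252    1.91   0.1665   0.6660  0.075  0.189
```

The injected +1.5 µV/SD parietal effect is detected on the parietal shift
(χ² = 6.89, p = 0.009, standardized slope 0.47) and echoes through the
overlapping windows (N400 strongest of the four), while the frontal P200 —
whose injected slope is small and negative — stays flat. `05_decode.py`
reaches per-subject AUCs of 0.71–0.80 (mean 0.75), every permutation p at
the k = 200 floor of 0.005. `07_operating_characteristics.py` measures
chance level, type-I error and power of the whole machinery by simulation.

## Layout

```
src/igreader/     infogain, simulate, preprocess, erpstats, decode,
                  epochs (array + disk format), montage, validation,
                  pipeline, cli
analysis/         numbered drivers over the library
scripts/          acceptance.py
docs/methods.md   models, defaults, numerical choices, limitations
tests/            pytest suite
```
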