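"""Staged, reproducible pipeline: simulate → score → prep → analyze → classify → report.

A single config (YAML-serialisable nested dict) drives every stage.  Each
stage derives its own seed deterministically from the master seed and the
stage name, writes its outputs under the run directory, and appends to a
JSON-lines log; a manifest records the config hash, stage seeds and output
hashes.  Re-running with the same config and master seed reproduces the
result files byte for byte.
"""

from __future__ import annotations

import copy
import hashlib
import json
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import decode, erpstats, preprocess, simulate
from .epochs import EpochArray
from .infogain import (
    LanguageModelConfig, load_corpus_jsonl, measure_report, save_corpus_jsonl,
    split_high_low, word_statistics,
)

STAGES = ["simulate", "score", "prep", "analyze", "classify", "report"]


def default_config(master_seed: int = 0) -> dict:
    """The pipeline's default study conditions (desk scale, one CPU)."""
    return {
        "master_seed": master_seed,
        "corpus": {
            "n_documents": 20,
            "n_topic_words_per_doc": 30,
            "n_shared_words": 150,
            "zipf_exponent": 1.2,
            "doc_length": 400,
        },
        "language_model": {"smoothing": "dirichlet", "mu": 100.0, "log_base": 2.0},
        "session": {"n_blocks": 8, "sentences_per_doc": 3, "words_per_sentence": 10},
        "effect": {},  # overrides of simulate.EffectConfig fields
        "n_subjects": 4,
        "sfreq": 250.0,
        "prep": {"percentile": 80.0, "max_bad_rate": 0.20},
        "decoder": {"window_ms": 100.0, "k": 200, "shrinkage": "auto"},
    }


def load_config(path: str | Path) -> dict:
    cfg = default_config()
    with open(path) as fh:
        user = yaml.safe_load(fh) or {}
    for key, value in user.items():
        if isinstance(value, dict) and isinstance(cfg.get(key), dict):
            cfg[key].update(value)
        else:
            cfg[key] = value
    return cfg


def derive_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage seed (below 2^31) from the master seed."""
    digest = hashlib.sha256(f"{master_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "little") % (2**31 - 1)


def _versions() -> dict:
    import sklearn
    import statsmodels

    from . import __version__

    return {
        "igreader": __version__,
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "scikit-learn": sklearn.__version__,
        "statsmodels": statsmodels.__version__,
    }


def _config_hash(config: dict) -> str:
    return hashlib.sha256(json.dumps(config, sort_keys=True).encode()).hexdigest()[:16]


def _write_json(path: Path, obj) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(obj, sort_keys=True, indent=1))


class _Run:
    def __init__(self, config: dict, out_dir: Path):
        self.config = config
        self.out = out_dir
        self.out.mkdir(parents=True, exist_ok=True)
        self.log_path = self.out / "log.jsonl"
        self.manifest = {
            "config": copy.deepcopy(config),
            "config_hash": _config_hash(config),
            "stage_seeds": {s: derive_seed(config["master_seed"], s) for s in STAGES},
            "versions": _versions(),
            "stages": {},
        }

    def log(self, stage: str, message: str, **extra) -> None:
        entry = {"stage": stage, "level": "info", "message": message,
                 "elapsed_s": round(time.time() - self._t0, 3), **extra}
        with open(self.log_path, "a") as fh:
            fh.write(json.dumps(entry) + "\n")

    def record(self, stage: str, outputs: list[Path]) -> None:
        hashes = {}
        for p in outputs:
            hashes[str(p.relative_to(self.out))] = hashlib.sha256(p.read_bytes()).hexdigest()[:16]
        self.manifest["stages"][stage] = {"outputs": hashes}

    def subjects(self):
        return [f"sub{s:02d}" for s in range(self.config["n_subjects"])]

    def lm_config(self) -> LanguageModelConfig:
        return LanguageModelConfig(**self.config["language_model"])


def _scored_stats(run: _Run, corpus) -> pd.DataFrame:
    """Word statistics with the token-weighted high/low median split."""
    stats = word_statistics(corpus, run.lm_config())
    weights = {w: corpus.corpus_count(w) for w in stats["word"]}
    return split_high_low(stats, weights=weights)


def _stage_simulate(run: _Run) -> None:
    cfg = run.config
    seed = derive_seed(cfg["master_seed"], "simulate")
    corpus = simulate.generate_corpus(**cfg["corpus"], seed=derive_seed(cfg["master_seed"], "corpus"))
    save_corpus_jsonl(corpus, run.out / "corpus.jsonl")
    stats = _scored_stats(run, corpus)
    effect = simulate.EffectConfig(**cfg["effect"])
    study = simulate.generate_study(
        corpus, stats, n_subjects=cfg["n_subjects"], effect=effect, seed=seed,
        sfreq=cfg["sfreq"], **cfg["session"],
    )
    outputs = [run.out / "corpus.jsonl"]
    truths = {}
    for (plan, epochs, truth), subject in zip(study, run.subjects()):
        prefix = run.out / "epochs" / subject
        epochs.save(prefix)
        outputs += [prefix.with_suffix(".f32"), prefix.with_suffix(".json")]
        truths[subject] = truth
    _write_json(run.out / "ground_truth.json", truths)
    outputs.append(run.out / "ground_truth.json")
    run.record("simulate", outputs)
    run.log("simulate", f"wrote corpus ({corpus.n_documents} docs) and "
            f"{len(study)} subjects of epochs")


def _stage_score(run: _Run) -> None:
    corpus = load_corpus_jsonl(run.out / "corpus.jsonl")
    stats = _scored_stats(run, corpus)
    stats_path = run.out / "word_stats.csv"
    stats.to_csv(stats_path, index=False,
                 columns=["word", "information_gain", "log_frequency", "length",
                          "word_class", "ig_label"])
    corr, ranks = measure_report(stats)
    corr.to_csv(run.out / "measure_correlations.csv")
    ranks.head(20).to_csv(run.out / "measure_ranks.csv")
    run.record("score", [stats_path, run.out / "measure_correlations.csv",
                         run.out / "measure_ranks.csv"])
    run.log("score", f"scored {len(stats)} words; "
            f"r(IG, log-frequency) = {corr.loc['information_gain', 'log_frequency']:.3f}")


def _stage_prep(run: _Run) -> None:
    outputs = []
    qc_all = {}
    for subject in run.subjects():
        epochs = EpochArray.load(run.out / "epochs" / subject)
        clean = preprocess.run_preprocessing(epochs, **run.config["prep"])
        prefix = run.out / "clean" / subject
        clean.save(prefix)
        outputs += [prefix.with_suffix(".f32"), prefix.with_suffix(".json")]
        qc_all[subject] = {k: clean.qc[k] for k in
                           ("threshold_uv", "n_rejected", "bad_channels", "invalid_rates")}
    _write_json(run.out / "qc.json", qc_all)
    outputs.append(run.out / "qc.json")
    run.record("prep", outputs)
    run.log("prep", f"preprocessed {len(qc_all)} subjects; "
            f"thresholds {[round(v['threshold_uv'], 1) for v in qc_all.values()]}")


def _stage_analyze(run: _Run) -> None:
    stats = pd.read_csv(run.out / "word_stats.csv")
    tables = []
    for subject in run.subjects():
        clean = EpochArray.load(run.out / "clean" / subject)
        tables.append(erpstats.component_means(clean, stats=stats))
    table = pd.concat(tables, ignore_index=True)
    table.to_csv(run.out / "component_table.csv", index=False)
    z = erpstats.standardize(table)
    results = [erpstats.lrt_information_gain(z, "EPS", m_correction=1).to_dict()]
    for comp in ("P200", "P300", "N400", "P600"):
        results.append(erpstats.lrt_information_gain(z, comp, m_correction=4).to_dict())
    _write_json(run.out / "erp_stats.json", results)
    run.record("analyze", [run.out / "component_table.csv", run.out / "erp_stats.json"])
    eps = results[0]
    run.log("analyze", f"EPS: chi2={eps['chi2']:.2f}, p={eps['p']:.4f}, "
            f"slope={eps['slope']:.3f}")


def _stage_classify(run: _Run) -> None:
    stats = pd.read_csv(run.out / "word_stats.csv")
    dec = run.config["decoder"]
    seed = derive_seed(run.config["master_seed"], "classify")
    results, features = {}, {}
    for i, subject in enumerate(run.subjects()):
        clean = EpochArray.load(run.out / "clean" / subject)
        feat = decode.featurize(clean, window_ms=dec["window_ms"])
        res = decode.permutation_test(feat, k=dec["k"], seed=seed + i,
                                      shrinkage=dec["shrinkage"])
        results[subject], features[subject] = res, feat
    _write_json(run.out / "decoding.json", {s: r.to_dict() for s, r in results.items()})
    report = decode.confidence_report(results, features, stats)
    report.to_csv(run.out / "confidence_report.csv", index=False)
    run.record("classify", [run.out / "decoding.json", run.out / "confidence_report.csv"])
    mean_auc = float(np.mean([r.auc_mean for r in results.values()]))
    run.log("classify", f"mean AUC over subjects: {mean_auc:.3f}")


def _stage_report(run: _Run) -> None:
    corr = pd.read_csv(run.out / "measure_correlations.csv", index_col=0)
    erp = json.loads((run.out / "erp_stats.json").read_text())
    dec = json.loads((run.out / "decoding.json").read_text())
    qc = json.loads((run.out / "qc.json").read_text())
    summary = {
        "ig_logfreq_correlation": float(corr.loc["information_gain", "log_frequency"]),
        "erp_tests": {r["component"]: {"chi2": r["chi2"], "p": r["p"],
                                       "p_bonferroni": r["p_bonferroni"],
                                       "slope": r["slope"]} for r in erp},
        "decoding": {
            "mean_auc": float(np.mean([d["auc_mean"] for d in dec.values()])),
            "per_subject": {s: {"auc_mean": d["auc_mean"], "p_value": d["p_value"]}
                            for s, d in dec.items()},
        },
        "preprocessing": {s: {"threshold_uv": q["threshold_uv"],
                              "n_rejected": q["n_rejected"],
                              "bad_channels": q["bad_channels"]}
                          for s, q in qc.items()},
    }
    _write_json(run.out / "summary.json", summary)
    run.record("report", [run.out / "summary.json"])
    run.log("report", "wrote summary.json")


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "score": _stage_score,
    "prep": _stage_prep,
    "analyze": _stage_analyze,
    "classify": _stage_classify,
    "report": _stage_report,
}

_STAGE_INPUTS = {
    "simulate": [],
    "score": ["corpus.jsonl"],
    "prep": ["epochs"],
    "analyze": ["clean", "word_stats.csv"],
    "classify": ["clean", "word_stats.csv"],
    "report": ["erp_stats.json", "decoding.json", "qc.json", "measure_correlations.csv"],
}

_STAGE_PRODUCES = {
    "simulate": ["corpus.jsonl", "epochs", "ground_truth.json"],
    "score": ["word_stats.csv", "measure_correlations.csv", "measure_ranks.csv"],
    "prep": ["clean", "qc.json"],
    "analyze": ["erp_stats.json", "component_table.csv"],
    "classify": ["decoding.json", "confidence_report.csv"],
    "report": ["summary.json"],
}


def run_pipeline(config: dict, out_dir: str | Path, stages: list[str] | None = None) -> Path:
    """Execute the requested *stages* (default: all, in order) into *out_dir*.

    Raises if a stage's inputs are neither on disk nor produced by an
    earlier requested stage.  Returns the run directory.
    """
    unknown = set(stages or []) - set(STAGES)
    if unknown:
        raise ValueError(f"unknown stage(s): {sorted(unknown)}")
    stages = [s for s in STAGES if s in (stages or STAGES)]
    out_dir = Path(out_dir)
    run = _Run(config, out_dir)
    run._t0 = time.time()
    produced = set()
    for stage in stages:
        for needed in _STAGE_INPUTS[stage]:
            if needed not in produced and not (out_dir / needed).exists():
                raise FileNotFoundError(
                    f"stage {stage!r} requires {needed!r}; run its producer first"
                )
        _STAGE_FUNCS[stage](run)
        produced.update(_STAGE_PRODUCES[stage])
    _write_json(out_dir / "manifest.json", run.manifest)
    return out_dir
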