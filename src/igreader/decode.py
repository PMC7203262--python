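"""Single-trial decoding of high/low information gain from epochs.

Features are channel × time-window mean voltages over 0–1000 ms.  A
shrinkage-regularized linear discriminant (pooled covariance shrunk toward
a scaled identity, intensity from an analytic Ledoit–Wolf estimator) is
trained per subject and evaluated with leave-one-block-out cross-validation
scored by AUC; significance comes from re-running the whole procedure on
permuted labels, with p = (b + 1)/(k + 1).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.covariance import ledoit_wolf_shrinkage

from .epochs import EpochArray

__all__ = [
    "FeatureMatrix",
    "LDAModel",
    "ClassifierResult",
    "featurize",
    "train_rlda",
    "auc",
    "leave_one_block_out",
    "permutation_p_value",
    "permutation_test",
    "confidence_report",
]


@dataclass
class FeatureMatrix:
    X: np.ndarray  # (n_epochs, n_channels * n_windows), microvolts
    y: np.ndarray  # 0 = low, 1 = high information gain
    blocks: np.ndarray
    columns: list[tuple[str, float]]  # (channel, window start ms)
    words: np.ndarray | None = None
    doc_ids: np.ndarray | None = None


def featurize(epochs: EpochArray, window_ms: float = 50.0) -> FeatureMatrix:
    """Mean voltage per channel in consecutive windows tiling [0, 1000) ms.

    Windows are half-open ``[w, w + window_ms)``; only retained epochs
    enter; labels come from the ``ig_label`` metadata column.
    """
    if 1000 % int(window_ms) != 0:
        raise ValueError(f"window_ms={window_ms} does not divide 1000 ms evenly")
    epochs = epochs.retained()
    starts = np.arange(0.0, 1000.0, window_ms)
    feats, columns = [], []
    for w in starts:
        tmask = (epochs.times >= w) & (epochs.times < w + window_ms)
        feats.append(epochs.data[:, :, tmask].mean(axis=2))  # (epochs, channels)
        columns.extend((ch, float(w)) for ch in epochs.channel_names)
    X = np.concatenate(feats, axis=1)
    meta = epochs.metadata
    y = (meta["ig_label"].to_numpy() == "high").astype(int)
    return FeatureMatrix(
        X, y, meta["block"].to_numpy(), columns,
        words=meta["word"].to_numpy(),
        doc_ids=meta["doc_id"].to_numpy() if "doc_id" in meta else None,
    )


@dataclass
class LDAModel:
    weights: np.ndarray
    bias: float
    shrinkage: float

    def decision(self, X: np.ndarray) -> np.ndarray:
        return X @ self.weights + self.bias


def train_rlda(X: np.ndarray, y: np.ndarray, shrinkage: str | float = "auto") -> LDAModel:
    """Fit a regularized linear discriminant.

    Direction ``w = Σ̃⁻¹(μ₁ − μ₀)`` with shrinkage covariance
    ``Σ̃ = (1 − γ)S + γ·(tr S / p)·I`` where ``S`` is the pooled
    within-class covariance; ``γ`` comes from the Ledoit–Wolf analytic
    estimator on the class-centred data when ``shrinkage="auto"``.
    """
    classes = np.unique(y)
    if len(classes) != 2:
        raise ValueError("rLDA needs exactly two classes in the training data")
    X0, X1 = X[y == classes[0]], X[y == classes[1]]
    if len(X0) < 2 or len(X1) < 2:
        raise ValueError("each class needs at least 2 training rows")
    mu0, mu1 = X0.mean(axis=0), X1.mean(axis=0)
    centred = np.concatenate([X0 - mu0, X1 - mu1])
    n, p = centred.shape
    S = centred.T @ centred / (n - 2)
    if shrinkage == "auto":
        gamma = float(ledoit_wolf_shrinkage(centred, assume_centered=True))
    else:
        gamma = float(shrinkage)
        if not 0 <= gamma <= 1:
            raise ValueError("fixed shrinkage must lie in [0, 1]")
    target = np.trace(S) / p
    sigma = (1.0 - gamma) * S + gamma * target * np.eye(p)
    w = np.linalg.solve(sigma, mu1 - mu0)
    b = -float(w @ (mu0 + mu1) / 2.0)
    return LDAModel(w, b, gamma)


def auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Rank-statistic AUC: P(random positive outscores random negative),
    ties counted one half."""
    labels = np.asarray(labels).astype(bool)
    n_pos, n_neg = labels.sum(), (~labels).sum()
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC undefined: one class is absent")
    ranks = rankdata(scores)
    return float((ranks[labels].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


@dataclass
class ClassifierResult:
    auc_blocks: dict
    auc_mean: float
    oof_scores: np.ndarray = field(repr=False)
    excluded_blocks: list = field(default_factory=list)
    permutation_aucs: list[float] = field(default_factory=list)
    p_value: float | None = None

    def to_dict(self) -> dict:
        out = {
            "auc_blocks": {str(k): v for k, v in self.auc_blocks.items()},
            "auc_mean": self.auc_mean,
            "excluded_blocks": [str(b) for b in self.excluded_blocks],
        }
        if self.p_value is not None:
            out["k"] = len(self.permutation_aucs)
            out["p_value"] = self.p_value
        return out


def leave_one_block_out(features: FeatureMatrix, shrinkage: str | float = "auto") -> ClassifierResult:
    """Train on all blocks but one, score the held-out block, repeat.

    Features are z-scored with training-fold statistics only.  Blocks
    missing a class are excluded from the average (and listed).
    """
    blocks = np.unique(features.blocks)
    if len(blocks) < 2:
        raise ValueError("leave-one-block-out needs at least 2 blocks")
    aucs, excluded = {}, []
    oof = np.full(len(features.y), np.nan)
    for b in blocks:
        test = features.blocks == b
        y_test = features.y[test]
        if len(np.unique(y_test)) < 2:
            excluded.append(b)
            continue
        X_train, y_train = features.X[~test], features.y[~test]
        mean, sd = X_train.mean(axis=0), X_train.std(axis=0)
        sd[sd == 0] = 1.0
        model = train_rlda((X_train - mean) / sd, y_train, shrinkage)
        scores = model.decision((features.X[test] - mean) / sd)
        oof[test] = scores
        aucs[b] = auc(scores, y_test)
    if not aucs:
        raise ValueError("every block lacked one of the classes")
    return ClassifierResult(aucs, float(np.mean(list(aucs.values()))), oof, excluded)


def permutation_p_value(b: int, k: int) -> float:
    """p = (b + 1)/(k + 1): never zero, floor 1/(k + 1)."""
    if k < 1:
        raise ValueError("need at least one permutation")
    return (b + 1) / (k + 1)


def permutation_test(
    features: FeatureMatrix,
    k: int = 1000,
    seed: int = 0,
    shrinkage: str | float = "auto",
) -> ClassifierResult:
    """Observed leave-one-block-out AUC against k label permutations.

    Labels are shuffled across all of the subject's epochs (block structure
    kept); the full cross-validation is re-run per permutation and
    ``p = (b + 1)/(k + 1)`` counts permutation means at or above the
    observed mean.
    """
    observed = leave_one_block_out(features, shrinkage)
    rng = np.random.default_rng(seed)
    perm_aucs = []
    for _ in range(k):
        perm = FeatureMatrix(features.X, rng.permutation(features.y),
                             features.blocks, features.columns)
        try:
            perm_aucs.append(leave_one_block_out(perm, shrinkage).auc_mean)
        except ValueError:  # a degenerate permutation left a fold single-class
            perm_aucs.append(0.5)
    b = int(np.sum(np.asarray(perm_aucs) >= observed.auc_mean))
    observed.permutation_aucs = perm_aucs
    observed.p_value = permutation_p_value(b, k)
    return observed


def confidence_report(
    results: dict[str, ClassifierResult],
    features: dict[str, FeatureMatrix],
    stats: pd.DataFrame,
    top_n: int = 5,
) -> pd.DataFrame:
    """Rank words by pooled out-of-fold classifier confidence per document.

    For each document, the ``top_n`` words with the highest mean decision
    score form the predicted high-gain list and the lowest form the
    predicted low-gain list, shown beside the ground-truth extremes by
    actual information gain.
    """
    rows = []
    for subject, feat in features.items():
        oof = results[subject].oof_scores
        ok = ~np.isnan(oof)
        rows.append(pd.DataFrame({
            "word": feat.words[ok],
            "doc_id": feat.doc_ids[ok] if feat.doc_ids is not None else "all",
            "score": oof[ok],
        }))
    pooled = pd.concat(rows).groupby(["doc_id", "word"], as_index=False)["score"].mean()
    ig = stats.set_index("word")["information_gain"]
    pooled["information_gain"] = pooled["word"].map(ig)
    report = []
    for doc_id, grp in pooled.groupby("doc_id"):
        by_score = grp.sort_values("score", ascending=False, kind="stable")
        by_ig = grp.sort_values("information_gain", ascending=False, kind="stable")
        n = min(top_n, len(grp))
        for cls, pred, true in (
            ("high", by_score.head(n), by_ig.head(n)),
            ("low", by_score.tail(n).iloc[::-1], by_ig.tail(n).iloc[::-1]),
        ):
            for rank in range(n):
                report.append({
                    "document": doc_id,
                    "class": cls,
                    "rank": rank + 1,
                    "word_predicted": pred["word"].iloc[rank],
                    "word_true": true["word"].iloc[rank],
                })
    return pd.DataFrame(report)
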