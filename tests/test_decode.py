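"""Featurization, regularized LDA, AUC and the block-wise permutation test."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

from igreader.epochs import EpochArray, default_times
from igreader.montage import CHANNELS_32
from igreader import decode as dc


def _labelled_epochs(n=40, n_blocks=4, seed=0, value=None) -> EpochArray:
    rng = np.random.default_rng(seed)
    times = default_times()
    data = rng.normal(size=(n, 32, len(times))) if value is None else np.full(
        (n, 32, len(times)), float(value))
    meta = pd.DataFrame({
        "subject": ["s0"] * n,
        "word": [f"w{i % 10}" for i in range(n)],
        "doc_id": [f"d{i % 4}" for i in range(n)],
        "block": np.arange(n) % n_blocks,
        "ig_label": np.where(rng.integers(2, size=n) == 1, "high", "low"),
    })
    return EpochArray(data, times, 250.0, CHANNELS_32, meta)


class TestFeaturize:
    def test_shape_is_channels_times_windows(self):
        feat = dc.featurize(_labelled_epochs(), window_ms=50.0)
        assert feat.X.shape == (40, 32 * 20)
        assert len(feat.columns) == 640

    def test_constant_epoch_gives_constant_features(self):
        feat = dc.featurize(_labelled_epochs(value=3.0), window_ms=50.0)
        assert np.allclose(feat.X, 3.0)

    def test_ramp_window_means_match_sampled_oracle(self):
        ep = _labelled_epochs(value=0.0)
        ramp = np.clip(ep.times, 0, None)  # µV = ms past onset
        ep.data[:] = ramp[None, None, :]
        feat = dc.featurize(ep, window_ms=100.0)
        for j, (ch, start) in enumerate(feat.columns):
            in_window = (ep.times >= start) & (ep.times < start + 100.0)
            assert feat.X[0, j] == pytest.approx(ramp[in_window].mean())

    def test_indivisible_window_rejected(self):
        with pytest.raises(ValueError):
            dc.featurize(_labelled_epochs(), window_ms=70.0)

    def test_rejected_epochs_excluded(self):
        ep = _labelled_epochs()
        ep.qc["rejected"] = [True] * 10 + [False] * 30
        assert dc.featurize(ep).X.shape[0] == 30


class TestTrainRLDA:
    def test_separable_classes_fit_perfectly(self):
        rng = np.random.default_rng(1)
        X = np.vstack([rng.normal(0, 1, (50, 5)), rng.normal(8, 1, (50, 5))])
        y = np.repeat([0, 1], 50)
        model = dc.train_rlda(X, y)
        assert dc.auc(model.decision(X), y) > 0.99

    def test_full_shrinkage_reduces_to_mean_difference(self):
        rng = np.random.default_rng(2)
        X, y = rng.normal(size=(60, 4)), np.repeat([0, 1], 30)
        model = dc.train_rlda(X, y, shrinkage=1.0)
        delta = X[y == 1].mean(0) - X[y == 0].mean(0)
        cosine = model.weights @ delta / np.linalg.norm(model.weights) / np.linalg.norm(delta)
        assert cosine == pytest.approx(1.0, abs=1e-10)

    def test_unregularized_weights_match_hand_inverse(self):
        # p=2 toy small enough to invert the pooled covariance by hand
        X0 = np.array([[0.0, 0.0], [2.0, 0.0], [0.0, 2.0], [2.0, 2.0]])
        X1 = X0 + np.array([3.0, 1.0])
        X, y = np.vstack([X0, X1]), np.repeat([0, 1], 4)
        model = dc.train_rlda(X, y, shrinkage=0.0)
        centred = np.vstack([X0 - X0.mean(0), X1 - X1.mean(0)])
        S = centred.T @ centred / (len(X) - 2)
        expected = np.linalg.inv(S) @ np.array([3.0, 1.0])
        assert np.allclose(model.weights, expected)

    def test_auto_shrinkage_matches_sklearn_direction(self):
        rng = np.random.default_rng(3)
        X = np.vstack([rng.normal(0, 1, (40, 12)), rng.normal(0.5, 1, (40, 12))])
        y = np.repeat([0, 1], 40)
        mine = dc.train_rlda(X, y, shrinkage="auto")
        sk = LinearDiscriminantAnalysis(solver="lsqr", shrinkage="auto").fit(X, y)
        cosine = mine.weights @ sk.coef_[0] / (
            np.linalg.norm(mine.weights) * np.linalg.norm(sk.coef_[0]))
        # sklearn shrinks per-class scatter with class-size weights, the
        # pooled formulation here shrinks the pooled scatter: directions
        # agree closely but not identically
        assert cosine > 0.95
        assert dc.auc(mine.decision(X), y) == pytest.approx(
            dc.auc(sk.decision_function(X), y), abs=0.05)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            dc.train_rlda(np.zeros((4, 2)), np.zeros(4))


class TestAUC:
    def test_perfect_ordering(self):
        assert dc.auc(np.array([1, 2, 3, 4.0]), np.array([0, 0, 1, 1])) == 1.0

    def test_all_ties_give_half(self):
        assert dc.auc(np.ones(6), np.array([0, 1] * 3)) == 0.5

    def test_hand_counted_pairs(self):
        scores = np.array([0.1, 0.4, 0.35, 0.8])
        labels = np.array([0, 0, 1, 1])
        assert dc.auc(scores, labels) == 0.75

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            dc.auc(np.arange(3.0), np.ones(3))

    @given(st.integers(0, 10_000))
    @settings(deadline=None, max_examples=100, derandomize=True)
    def test_matches_allpairs_bruteforce(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 31))
        scores = np.round(rng.normal(size=n), 1)  # rounding forces ties
        labels = np.zeros(n, int)
        labels[rng.choice(n, size=int(rng.integers(1, n)), replace=False)] = 1
        if labels.sum() in (0, n):
            return
        pos, neg = scores[labels == 1], scores[labels == 0]
        wins = sum((p > q) + 0.5 * (p == q) for p in pos for q in neg)
        assert dc.auc(scores, labels) == pytest.approx(wins / (len(pos) * len(neg)))

    @given(st.integers(0, 10_000))
    @settings(deadline=None, max_examples=25, derandomize=True)
    def test_label_flip_antisymmetry(self, seed):
        rng = np.random.default_rng(seed)
        scores = rng.normal(size=20)
        labels = rng.integers(2, size=20)
        if labels.sum() in (0, 20):
            return
        assert dc.auc(scores, labels) == pytest.approx(1.0 - dc.auc(scores, 1 - labels))


def _block_features(n_blocks=4, per_block=30, signal=0.0, seed=0) -> dc.FeatureMatrix:
    rng = np.random.default_rng(seed)
    n = n_blocks * per_block
    y = np.tile(np.repeat([0, 1], per_block // 2), n_blocks)
    X = rng.normal(size=(n, 8))
    X[:, 0] += signal * y
    return dc.FeatureMatrix(X, y, np.repeat(np.arange(n_blocks), per_block),
                            [("ch", float(i)) for i in range(8)])


class TestLeaveOneBlockOut:
    def test_chance_level_without_signal(self):
        aucs = [dc.leave_one_block_out(_block_features(seed=s)).auc_mean
                for s in range(20)]
        assert abs(np.mean(aucs) - 0.5) < 0.05

    def test_signal_recovered(self):
        res = dc.leave_one_block_out(_block_features(signal=2.0, seed=1))
        assert res.auc_mean > 0.9

    def test_epoch_order_within_blocks_irrelevant(self):
        feat = _block_features(signal=1.0, seed=2)
        res_a = dc.leave_one_block_out(feat)
        rng = np.random.default_rng(3)
        perm = np.concatenate([rng.permutation(np.nonzero(feat.blocks == b)[0])
                               for b in np.unique(feat.blocks)])
        shuffled = dc.FeatureMatrix(feat.X[perm], feat.y[perm], feat.blocks[perm],
                                    feat.columns)
        res_b = dc.leave_one_block_out(shuffled)
        assert res_a.auc_blocks == pytest.approx(res_b.auc_blocks)

    def test_single_class_blocks_excluded_not_fatal(self):
        feat = _block_features(seed=4)
        feat.y[feat.blocks == 0] = 1
        res = dc.leave_one_block_out(feat)
        assert res.excluded_blocks == [0]
        assert set(res.auc_blocks) == {1, 2, 3}

    def test_held_out_block_cannot_leak_into_training(self):
        # plant a feature that separates classes perfectly inside one block
        # only; without leakage the classifier cannot exploit it there
        feat = _block_features(seed=5)
        target = feat.blocks == 0
        feat.X[target, 1] = feat.y[target] * 100.0 - 50.0
        res = dc.leave_one_block_out(feat)
        assert res.auc_blocks[0] < 0.7  # would be ~1.0 with leakage


class TestPermutationTest:
    @pytest.mark.parametrize("b,k,expected", [(0, 1000, 1 / 1001), (2, 9, 0.3), (9, 9, 1.0)])
    def test_p_value_formula(self, b, k, expected):
        assert dc.permutation_p_value(b, k) == pytest.approx(expected)

    def test_floor_never_zero(self):
        assert dc.permutation_p_value(0, 1000) > 0
        assert round(dc.permutation_p_value(0, 1000), 3) == 0.001

    def test_strong_signal_yields_floor_p(self):
        feat = _block_features(signal=2.5, seed=6)
        res = dc.permutation_test(feat, k=19, seed=0)
        assert res.p_value == pytest.approx(1 / 20)
        assert len(res.permutation_aucs) == 19

    def test_null_p_values_calibrated(self):
        # under no signal the permutation p-value must be super-uniform-ish:
        # rejection at alpha stays near alpha
        ps = []
        for s in range(40):
            feat = _block_features(n_blocks=4, per_block=16, seed=100 + s)
            ps.append(dc.permutation_test(feat, k=39, seed=s).p_value)
        rate = np.mean(np.asarray(ps) <= 0.1)
        assert rate <= 0.2
        assert min(ps) >= 1 / 40


class TestConfidenceReport:
    def test_shape_and_columns(self, clean_epochs, zipf_stats):
        feat = dc.featurize(clean_epochs, window_ms=100.0)
        res = dc.leave_one_block_out(feat)
        report = dc.confidence_report({"sub00": res}, {"sub00": feat}, zipf_stats)
        assert list(report.columns) == ["document", "class", "rank",
                                        "word_predicted", "word_true"]
        assert set(report["class"]) == {"high", "low"}
        per_doc = report.groupby(["document", "class"]).size()
        assert (per_doc == 5).all()

    def test_noise_free_strong_signal_recovers_truth(self, default_session, zipf_stats):
        from igreader.simulate import EffectConfig, generate_epochs

        # near-perfect signal: a huge injected slope against unit noise (a
        # literally zero noise floor would degenerate the per-fold feature
        # standardization, which divides by training-fold SDs)
        effect = EffectConfig(eps_slope=50.0, p200_slope=0.0, noise_scale=1.0,
                              subject_intercept_sd=0.0, word_intercept_sd=0.0,
                              artifact_fraction=0.0, seed=0)
        epochs, _ = generate_epochs(default_session, zipf_stats, effect)
        feat = dc.featurize(epochs)
        res = dc.leave_one_block_out(feat)
        report = dc.confidence_report({"s": res}, {"s": feat}, zipf_stats)
        # scores track gain closely, so per document the predicted top-5
        # carries (almost) the same multiset of gains as the true top-5;
        # word identity and order can differ among gain ties, and single
        # stray flips remain possible because many words contribute only
        # one epoch
        ig = zipf_stats.set_index("word")["information_gain"]
        mismatches = 0
        total = 0
        for _, grp in report[report["class"] == "high"].groupby("document"):
            got = np.sort(ig[grp["word_predicted"]].to_numpy())
            want = np.sort(ig[grp["word_true"]].to_numpy())
            mismatches += int((~np.isclose(got, want, atol=1e-9)).sum())
            total += len(grp)
        assert mismatches / total <= 0.2
        # and the predicted-high lists must carry far more gain than the
        # predicted-low lists
        gain_high = ig[report.loc[report["class"] == "high", "word_predicted"]].mean()
        gain_low = ig[report.loc[report["class"] == "low", "word_predicted"]].mean()
        assert gain_high > gain_low + 1.0

    def test_score_tracks_gain_on_default_fixture(self, clean_epochs, zipf_stats):
        feat = dc.featurize(clean_epochs, window_ms=100.0)
        res = dc.leave_one_block_out(feat)
        ok = ~np.isnan(res.oof_scores)
        ig = clean_epochs.retained().metadata["information_gain"].to_numpy()[ok]
        from scipy.stats import spearmanr

        rho = spearmanr(res.oof_scores[ok], ig).statistic
        assert rho > 0.2
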