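"""SVM-RFE with correlation-bias reduction, leave-one-subject-out folds,
and decoding metrics."""

import itertools

import numpy as np
import pytest
from scipy import stats
from sklearn.metrics import cohen_kappa_score

from fractalconn.selection import (
    FeatureDataset,
    RFEConfig,
    chance_level,
    cohens_kappa,
    eloo_folds,
    rfe_cbr,
    run_selection,
    sample_accuracy,
    subject_vote,
    train_linear_svm,
)


class TestElooFolds:
    def test_study_fold_count(self):
        y = [f"y{i}" for i in range(24)]
        e = [f"e{i}" for i in range(19)]
        assert len(eloo_folds(y, e)) == 456

    def test_counting_and_membership(self):
        folds = eloo_folds(["a", "b", "c"], ["d", "e"])
        assert len(folds) == 6
        # every subject appears in exactly (other-group size) test sets
        test_counts = {}
        for train, (ty, te) in folds:
            assert set(train) | {ty, te} == {"a", "b", "c", "d", "e"}
            assert ty not in train and te not in train
            test_counts[ty] = test_counts.get(ty, 0) + 1
            test_counts[te] = test_counts.get(te, 0) + 1
        assert test_counts == {"a": 2, "b": 2, "c": 2, "d": 3, "e": 3}

    def test_degenerate_and_overlap(self):
        with pytest.raises(ValueError):
            eloo_folds(["a"], ["b"])
        with pytest.raises(ValueError):
            eloo_folds(["a", "b"], ["b", "c"])


class TestLinearSvm:
    def test_separable_1d(self):
        X = np.array([[-2.0], [-1.0], [1.0], [2.0]])
        y = np.array([0, 0, 1, 1])
        w, b, imp = train_linear_svm(X, y, C=100.0)
        pred = (X @ w + b > 0).astype(int)
        assert np.array_equal(pred, y)
        assert np.all(imp >= 0) and imp.sum() > 0

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            train_linear_svm(np.zeros((4, 2)), np.zeros(4), 1.0)


class TestRfeCbr:
    def make_planted(self, rng, n=200, n_noise=9, dup=False):
        sep = np.concatenate([rng.normal(-2, 0.5, n // 2), rng.normal(2, 0.5, n // 2)])
        y = np.repeat([0, 1], n // 2)
        cols = [sep] + [rng.standard_normal(n) for _ in range(n_noise)]
        if dup:
            cols.insert(1, sep.copy())
        return np.column_stack(cols), y

    def test_ranking_is_permutation(self, rng):
        X, y = self.make_planted(rng)
        rank = rfe_cbr(X, y, RFEConfig())
        assert sorted(rank.astype(int)) == list(range(1, X.shape[1] + 1))

    def test_separating_feature_ranked_first(self):
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            X, y = self.make_planted(rng)
            rank = rfe_cbr(X, y, RFEConfig())
            hits += rank[0] == 1
        assert hits >= 9

    def test_cbr_restores_duplicated_feature(self):
        # two identical perfectly separating columns: correlation 1 > 0.9,
        # so whenever both fall in an eliminated batch one is restored and
        # must outrank every noise feature
        for seed in range(5):
            rng = np.random.default_rng(seed)
            X, y = self.make_planted(rng, n_noise=30, dup=True)
            cfg = RFEConfig(one_by_one_below=4)
            rank = rfe_cbr(X, y, cfg)
            assert min(rank[0], rank[1]) <= 4

    def test_nonfinite_rejected(self, rng):
        X, y = self.make_planted(rng)
        X[0, 0] = np.inf
        with pytest.raises(ValueError):
            rfe_cbr(X, y, RFEConfig())


class TestMetrics:
    def test_perfect_predictions(self):
        pred = np.array([0, 1, 0, 1])
        assert sample_accuracy(pred, pred) == 100.0
        cm = np.array([[2, 0], [0, 2]])
        assert cohens_kappa(cm) == 1.0

    def test_one_class_on_balanced_set_is_chance(self):
        cm = np.array([[5, 0], [5, 0]])
        assert cohens_kappa(cm) == 0.0

    def test_kappa_equals_2acc_minus_1_on_balanced_confusions(self, rng):
        # algebraic identity when both marginals are exactly balanced
        for _ in range(50):
            a = int(rng.integers(0, 50))
            b = int(rng.integers(0, 50))
            cm = np.array([[a, b], [b, a]], dtype=float)
            if cm.sum() == 0:
                continue
            acc = np.trace(cm) / cm.sum()
            assert cohens_kappa(cm) == pytest.approx(2 * acc - 1, abs=1e-12)

    def test_kappa_matches_sklearn(self, rng):
        truth = rng.integers(0, 2, 60)
        pred = rng.integers(0, 2, 60)
        cm = np.zeros((2, 2))
        for t, p in zip(truth, pred):
            cm[t, p] += 1
        assert cohens_kappa(cm) == pytest.approx(cohen_kappa_score(truth, pred))

    def test_subject_vote_majority_and_tie(self):
        assert subject_vote(np.array([1, 1, 0])) == 1
        assert subject_vote(np.array([0, 0, 1])) == 0
        assert subject_vote(np.array([0, 1]), decision=np.array([-2.0, 1.0])) == 0
        with pytest.raises(ValueError):
            subject_vote(np.array([0, 1]))


class TestChanceLevel:
    def test_study_value(self):
        # 2 test subjects x 137 windows at alpha = 1e-4
        assert chance_level(274, alpha=1e-4) == pytest.approx(61.31, abs=0.005)

    def test_small_case_exact(self):
        # n=10, alpha=0.05: F(7)=0.9453 < 0.95 <= F(8)=0.9893 -> k=8 -> 80%
        assert chance_level(10, alpha=0.05) == 80.0

    def test_monotone_in_alpha(self):
        levels = [chance_level(274, alpha=a) for a in (1e-4, 1e-3, 0.05, 0.5)]
        assert levels == sorted(levels, reverse=True)
        assert levels[-1] >= 50.0

    @pytest.mark.parametrize("alpha", [0.05, 1e-3, 1e-4])
    def test_matches_brute_force_binomial_tail(self, alpha):
        from math import comb

        for n in (5, 37, 150, 274, 300):
            cdf = np.cumsum([comb(n, k) * 0.5**n for k in range(n + 1)])
            k_star = int(np.searchsorted(cdf, 1 - alpha))
            assert chance_level(n, alpha=alpha) == pytest.approx(100 * k_star / n)


class TestRunSelection:
    def make_dataset(self, rng, n_subj=4, windows=12, n_feat=6):
        """Tiny planted dataset: feature 0 separates the groups."""
        rows, ys, subs = [], [], []
        for s in range(2 * n_subj):
            g = int(s >= n_subj)
            mu = np.zeros(n_feat)
            mu[0] = -1.5 + 3.0 * g
            rows.append(mu + rng.standard_normal((windows, n_feat)))
            ys.extend([g] * windows)
            subs.extend([f"s{s}"] * windows)
        names = [("a", "b", 2**i) for i in range(n_feat)]
        return FeatureDataset(np.vstack(rows), np.array(ys), np.array(subs), names)

    def test_fold_hygiene_and_chosen_contains_planted(self, rng):
        ds = self.make_dataset(rng)
        sel = run_selection(ds, RFEConfig(C=1.0))
        assert 0 in sel.chosen_set
        assert sel.acc_sw > 80.0
        assert -1 <= sel.kappa_sw <= 1
        assert len(sel.per_fold) == 16

    def test_accuracy_of_chosen_not_below_full_set(self, rng):
        ds = self.make_dataset(rng)
        sel = run_selection(ds, RFEConfig(C=1.0))
        assert max(sel.accuracy_curve) == sel.acc_sw
        assert sel.acc_sw >= sel.accuracy_curve[-1]

    def test_k_max_one_selects_top_ranked(self, rng):
        ds = self.make_dataset(rng)
        sel = run_selection(ds, RFEConfig(C=1.0), k_max=1)
        assert sel.chosen_set == [0]

    def test_deterministic(self, rng):
        ds = self.make_dataset(rng)
        a = run_selection(ds, RFEConfig(C=1.0))
        b = run_selection(ds, RFEConfig(C=1.0))
        assert a.chosen_set == b.chosen_set
        assert a.acc_sw == b.acc_sw
        assert np.array_equal(a.avg_rank, b.avg_rank)

    def test_nan_features_rejected(self, rng):
        ds = self.make_dataset(rng)
        with pytest.raises(ValueError):
            FeatureDataset(np.full_like(ds.X, np.nan), ds.y, ds.subject_of, ds.feature_names)
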