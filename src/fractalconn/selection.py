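"""Discriminative-feature selection: linear SVM-RFE with correlation-bias
reduction inside extensive leave-one-subject-out cross-validation.

The feature matrix has one row per (subject, analysis window) and one
column per (channel pair, scale) DCCC value. Selection proceeds in three
stages:

1. **ELOO-CV folds** — every possible pairing of one held-out subject per
   group defines a fold; all windows of a subject stay on one side, so
   decoding reflects group membership rather than subject identity.
2. **SVM-RFE with CBR** — per fold, a linear SVM is trained repeatedly;
   feature importance is the squared primal weight, the least important
   half of the active set is eliminated each round, and correlation-bias
   reduction restores the most important member of any highly
   inter-correlated cluster (|Pearson r| above threshold) found inside the
   eliminated batch. Once at most ``one_by_one_below`` features remain they
   are removed one at a time, producing a strict elimination order. Fold
   rankings are averaged into a single ranking.
3. **Subset selection** — features are added back in average-rank order;
   the prefix maximising mean ELOO-CV sample-wise accuracy (smallest size
   on ties) is the chosen set.

Decoding performance is reported as sample-wise and majority-vote
subject-wise accuracy with Cohen's kappa, against an exact binomial
chance-level threshold.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.svm import SVC

__all__ = [
    "FeatureDataset",
    "RFEConfig",
    "SelectionResult",
    "build_feature_dataset",
    "eloo_folds",
    "train_linear_svm",
    "rfe_cbr",
    "average_ranking",
    "select_subset",
    "sample_accuracy",
    "subject_vote",
    "cohens_kappa",
    "chance_level",
    "run_selection",
]

logger = logging.getLogger(__name__)

C_GRID = (1e-2, 1e-1, 1.0, 10.0, 100.0)


@dataclass
class FeatureDataset:
    """Window-level connectivity features with subject bookkeeping.

    ``X``: (n_samples, n_features); one sample per (subject, window), one
    feature per (channel pair, scale). ``y``: 0 = young, 1 = elderly.
    ``subject_of``: subject ID per row. ``feature_names``: per-column
    (ch1, ch2, scale) tuples.
    """

    X: np.ndarray
    y: np.ndarray
    subject_of: np.ndarray
    feature_names: list[tuple[str, str, int]]

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=int)
        self.subject_of = np.asarray(self.subject_of)
        if self.X.ndim != 2 or not (len(self.X) == len(self.y) == len(self.subject_of)):
            raise ValueError("inconsistent dataset shapes")
        if np.isnan(self.X).any():
            raise ValueError("feature matrix contains NaN; apply a missing-value policy first")

    @property
    def n_features(self) -> int:
        return self.X.shape[1]

    def subjects(self, label: int) -> list:
        mask = self.y == label
        return list(pd.unique(self.subject_of[mask]))


def build_feature_dataset(tensors: dict, groups: dict[str, str]) -> FeatureDataset:
    """Stack per-subject connectivity tensors into a window-level dataset.

    Parameters
    ----------
    tensors : dict subject_id -> ConnectivityTensor
    groups : dict subject_id -> {"young", "elderly"}

    Windows containing any NaN coefficient are dropped (flagged-missing
    policy); the drop count is logged.
    """
    rows, ys, subs = [], [], []
    names: list[tuple[str, str, int]] | None = None
    dropped = 0
    for sid, tensor in tensors.items():
        if names is None:
            names = [
                (a, b, s)
                for (a, b) in tensor.pair_labels()
                for s in tensor.scales.scales
            ]
        flat = tensor.dccc.reshape(tensor.n_windows, -1)  # (pair, scale) row-major
        ok = ~np.isnan(flat).any(axis=1)
        dropped += int((~ok).sum())
        rows.append(flat[ok])
        label = 0 if groups[sid] == "young" else 1
        ys.extend([label] * int(ok.sum()))
        subs.extend([sid] * int(ok.sum()))
    if dropped:
        logger.warning("dropped %d windows containing missing coefficients", dropped)
    assert names is not None
    return FeatureDataset(np.vstack(rows), np.array(ys), np.array(subs), names)


@dataclass(frozen=True)
class RFEConfig:
    """Tunables of the elimination procedure (defaults follow common
    SVM-RFE practice for connectivity features)."""

    C: float = 1.0
    elim_frac: float = 0.5
    corr_threshold: float = 0.9
    one_by_one_below: int = 20
    standardize: bool = True

    def __post_init__(self) -> None:
        if not (0 < self.elim_frac < 1):
            raise ValueError("elim_frac must lie in (0, 1)")
        if not (0 < self.corr_threshold <= 1):
            raise ValueError("corr_threshold must lie in (0, 1]")


@dataclass
class SelectionResult:
    """Averaged ranking, chosen subset and decoding metrics."""

    avg_rank: np.ndarray
    chosen_set: list[int]
    per_fold: pd.DataFrame
    acc_sw: float
    acc_subj: float
    kappa_sw: float
    kappa_subj: float
    chance_level_pct: float
    accuracy_curve: np.ndarray = field(default_factory=lambda: np.array([]))


def eloo_folds(young: list, elderly: list) -> list[tuple[list, tuple]]:
    """All (train subjects, test pair) divisions with one held-out subject
    per group — the extensive leave-one-subject-out scheme."""
    young, elderly = list(young), list(elderly)
    if not young or not elderly:
        raise ValueError("both groups must be non-empty")
    if set(young) & set(elderly):
        raise ValueError(f"subjects in both groups: {set(young) & set(elderly)}")
    if len(young) < 2 and len(elderly) < 2:
        raise ValueError("at least one group needs >= 2 subjects for a non-empty training set")
    folds = []
    for ty, te in itertools.product(young, elderly):
        train = [s for s in young if s != ty] + [s for s in elderly if s != te]
        folds.append((train, (ty, te)))
    return folds


def _standardize(X_train: np.ndarray, X_test: np.ndarray | None = None):
    mu = X_train.mean(axis=0)
    sd = X_train.std(axis=0, ddof=0)
    sd = np.where(sd > 0, sd, 1.0)
    if X_test is None:
        return (X_train - mu) / sd
    return (X_train - mu) / sd, (X_test - mu) / sd


def train_linear_svm(X: np.ndarray, y: np.ndarray, C: float = 1.0):
    """Fit a linear-kernel SVM; returns (weights, bias, importances) with
    importance = squared primal weight."""
    if len(np.unique(y)) < 2:
        raise ValueError("training data must contain both classes")
    clf = SVC(kernel="linear", C=C)
    clf.fit(X, y)
    w = clf.coef_.ravel()
    return w, float(clf.intercept_[0]), w * w


def _cbr_restore(
    X_active: np.ndarray,
    eliminated: np.ndarray,
    importances: np.ndarray,
    threshold: float,
) -> list[int]:
    """Indices (into ``eliminated``) to restore: the top-importance member
    of each connected component (size >= 2) of the |Pearson r| > threshold
    graph over the eliminated batch."""
    m = len(eliminated)
    if m < 2:
        return []
    sub = X_active[:, eliminated]
    sd = sub.std(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(sub, rowvar=False)
    corr = np.nan_to_num(corr, nan=0.0)
    adj = np.abs(corr) > threshold
    np.fill_diagonal(adj, False)
    # connected components by union-find over the small eliminated batch
    parent = list(range(m))

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    for i in range(m):
        for j in range(i + 1, m):
            if adj[i, j]:
                ri, rj = find(i), find(j)
                if ri != rj:
                    parent[ri] = rj
    comps: dict[int, list[int]] = {}
    for i in range(m):
        comps.setdefault(find(i), []).append(i)
    restore = []
    for members in comps.values():
        if len(members) >= 2:
            best = max(members, key=lambda i: (importances[i], -i))
            restore.append(best)
    return restore


def rfe_cbr(X: np.ndarray, y: np.ndarray, cfg: RFEConfig) -> np.ndarray:
    """Recursive feature elimination with correlation-bias reduction.

    Returns a strict elimination-order ranking (a permutation; rank 1 = the
    last surviving feature). Features are standardised with the training
    statistics before every SVM fit so that weight magnitudes are
    comparable across columns.
    """
    X = np.asarray(X, dtype=float)
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite feature values")
    n_features = X.shape[1]
    if n_features < 2:
        raise ValueError("need at least 2 features")
    if min(np.bincount(np.asarray(y, dtype=int))) < 2:
        raise ValueError("need at least 2 samples per class")
    Xs = _standardize(X) if cfg.standardize else X
    active = list(range(n_features))
    rank = np.zeros(n_features, dtype=float)
    next_rank = n_features  # worst rank assigned first
    while len(active) > 1:
        _, _, imp = train_linear_svm(Xs[:, active], y, cfg.C)
        order = np.argsort(imp, kind="stable")  # ascending importance
        if len(active) > cfg.one_by_one_below:
            n_drop = max(1, int(np.floor(len(active) * cfg.elim_frac)))
        else:
            n_drop = 1
        drop_local = order[:n_drop]
        if n_drop > 1:
            keep_back = _cbr_restore(
                Xs, np.array([active[i] for i in drop_local]), imp[drop_local],
                cfg.corr_threshold,
            )
            if keep_back:
                drop_local = np.array(
                    [i for k, i in enumerate(drop_local) if k not in set(keep_back)]
                )
        # eliminate in ascending importance: least important gets worst rank
        for i in drop_local:
            rank[active[i]] = next_rank
            next_rank -= 1
        active = [a for k, a in enumerate(active) if k not in set(drop_local.tolist())]
    rank[active[0]] = 1
    assert sorted(rank.astype(int)) == list(range(1, n_features + 1))
    return rank


def average_ranking(
    rankings: np.ndarray, importances: np.ndarray | None = None
) -> np.ndarray:
    """Mean elimination rank over folds; feature order by ascending mean
    rank, ties broken by mean importance (descending) then feature index."""
    mean_rank = np.asarray(rankings, dtype=float).mean(axis=0)
    if importances is None:
        importances = np.zeros_like(mean_rank)
    order = sorted(
        range(len(mean_rank)), key=lambda i: (mean_rank[i], -importances[i], i)
    )
    return np.array(order, dtype=int)


def sample_accuracy(pred: np.ndarray, truth: np.ndarray) -> float:
    """Percentage of correctly classified samples."""
    pred, truth = np.asarray(pred), np.asarray(truth)
    if pred.size == 0 or pred.shape != truth.shape:
        raise ValueError("predictions and truth must be non-empty and equal length")
    return 100.0 * float(np.mean(pred == truth))


def subject_vote(pred: np.ndarray, decision: np.ndarray | None = None) -> int:
    """Majority vote over one subject's window predictions; ties broken by
    the sign of the summed SVM decision values."""
    pred = np.asarray(pred, dtype=int)
    if pred.size == 0:
        raise ValueError("empty prediction vector")
    ones = int(pred.sum())
    zeros = pred.size - ones
    if ones != zeros:
        return int(ones > zeros)
    if decision is None:
        raise ValueError("tied vote with no decision values to break it")
    return int(np.sum(decision) > 0)


def cohens_kappa(confusion: np.ndarray) -> float:
    """Chance-corrected agreement from a 2x2 confusion matrix:
    kappa = (p_o - p_e) / (1 - p_e) with p_e from marginal products."""
    cm = np.asarray(confusion, dtype=float)
    if cm.shape != (2, 2) or (cm < 0).any():
        raise ValueError("confusion must be 2x2 with non-negative entries")
    n = cm.sum()
    if n == 0:
        raise ValueError("empty confusion matrix")
    p_o = np.trace(cm) / n
    p_e = float(cm.sum(axis=0) @ cm.sum(axis=1)) / (n * n)
    if p_e == 1.0:
        return 0.0
    return float((p_o - p_e) / (1 - p_e))


def chance_level(n: int, alpha: float = 1e-4, p: float = 0.5) -> float:
    """Exact binomial inverse-CDF chance threshold, in percent.

    The smallest correct-count ``k`` whose binomial CDF reaches
    ``1 - alpha`` defines the accuracy that a chance-level classifier
    exceeds with probability at most ``alpha``.
    """
    if n < 1 or not (0 < alpha < 1):
        raise ValueError("need n >= 1 and 0 < alpha < 1")
    k = int(stats.binom.ppf(1 - alpha, n, p))
    return 100.0 * k / n


def _fold_arrays(ds: FeatureDataset, train_subjects, test_pair):
    train_mask = np.isin(ds.subject_of, train_subjects)
    test_mask = np.isin(ds.subject_of, list(test_pair))
    return train_mask, test_mask


def run_selection(
    ds: FeatureDataset,
    cfg: RFEConfig = RFEConfig(),
    k_max: int | None = None,
) -> SelectionResult:
    """Full pipeline: per-fold SVM-RFE ranking, rank averaging, add-back
    subset search, and decoding metrics on the chosen set.

    ``k_max`` caps the add-back search (default: all features). All steps
    are deterministic given the dataset.
    """
    young = ds.subjects(0)
    elderly = ds.subjects(1)
    folds = eloo_folds(young, elderly)
    n_feat = ds.n_features
    rankings = np.empty((len(folds), n_feat))
    mean_imps = np.zeros(n_feat)
    for f, (train, test) in enumerate(folds):
        tr, _ = _fold_arrays(ds, train, test)
        rankings[f] = rfe_cbr(ds.X[tr], ds.y[tr], cfg)
        Xs = _standardize(ds.X[tr]) if cfg.standardize else ds.X[tr]
        _, _, imp = train_linear_svm(Xs, ds.y[tr], cfg.C)
        mean_imps += imp / len(folds)
    feature_order = average_ranking(rankings, mean_imps)
    avg_rank = rankings.mean(axis=0)

    k_max = n_feat if k_max is None else min(k_max, n_feat)
    # add-back search: mean sample-wise ELOO accuracy for each prefix size
    fold_cache = [(_fold_arrays(ds, train, test), test) for train, test in folds]
    curve = np.empty(k_max)
    for k in range(1, k_max + 1):
        cols = feature_order[:k]
        accs = []
        for (tr, te), _ in fold_cache:
            Xtr, Xte = (
                _standardize(ds.X[tr][:, cols], ds.X[te][:, cols])
                if cfg.standardize
                else (ds.X[tr][:, cols], ds.X[te][:, cols])
            )
            clf = SVC(kernel="linear", C=cfg.C)
            clf.fit(Xtr, ds.y[tr])
            accs.append(sample_accuracy(clf.predict(Xte), ds.y[te]))
        curve[k - 1] = np.mean(accs)
    best_k = int(np.argmax(curve)) + 1  # argmax takes smallest index on ties
    chosen = feature_order[:best_k].tolist()

    # decoding metrics on the chosen set
    rows = []
    cm_sw = np.zeros((2, 2))
    cm_subj = np.zeros((2, 2))
    n_test = None
    for (tr, te), test_pair in fold_cache:
        Xtr, Xte = (
            _standardize(ds.X[tr][:, chosen], ds.X[te][:, chosen])
            if cfg.standardize
            else (ds.X[tr][:, chosen], ds.X[te][:, chosen])
        )
        clf = SVC(kernel="linear", C=cfg.C)
        clf.fit(Xtr, ds.y[tr])
        pred = clf.predict(Xte)
        dec = clf.decision_function(Xte)
        ytest = ds.y[te]
        subs = ds.subject_of[te]
        n_test = len(ytest)
        for t, p in zip(ytest, pred):
            cm_sw[t, p] += 1
        acc = sample_accuracy(pred, ytest)
        subj_correct = 0
        for sid in test_pair:
            m = subs == sid
            vote = subject_vote(pred[m], dec[m])
            truth = int(ytest[m][0])
            cm_subj[truth, vote] += 1
            subj_correct += int(vote == truth)
        rows.append(
            {
                "test_young": test_pair[0],
                "test_elderly": test_pair[1],
                "acc_sw": acc,
                "acc_subj": 100.0 * subj_correct / 2.0,
            }
        )
    per_fold = pd.DataFrame(rows)
    return SelectionResult(
        avg_rank=avg_rank,
        chosen_set=chosen,
        per_fold=per_fold,
        acc_sw=float(per_fold["acc_sw"].mean()),
        acc_subj=float(per_fold["acc_subj"].mean()),
        kappa_sw=cohens_kappa(cm_sw),
        kappa_subj=cohens_kappa(cm_subj),
        chance_level_pct=chance_level(n_test if n_test else 1),
        accuracy_curve=curve,
    )
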