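"""Group-level and brain-behavior statistics for connectivity summaries.

Covers: per-subject time-mean and time-variance summaries of the DCCC
tensor and windowed DFA exponents; normality-gated two-group comparisons
(Lilliefors gate routing to Welch t or Mann-Whitney U); Benjamini-Hochberg
FDR adjustment; Spearman correlation tables between chosen connectivity
features and cognitive scores (reported unadjusted, as appropriate for a
pre-curated feature set); and the Pearson relation between coupling
strength <|DCCC|> and its temporal variance across connections.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.diagnostic import lilliefors
from statsmodels.stats.multitest import multipletests

from .fractal import ConnectivityTensor, DFAExponentSeries

__all__ = [
    "subject_summaries",
    "summary_table",
    "group_compare",
    "fdr_bh",
    "spearman_with_p",
    "spearman_table",
    "abs_mean_variance_corr",
]


def subject_summaries(
    tensor: ConnectivityTensor, dfa: DFAExponentSeries
) -> pd.DataFrame:
    """One-row summary of a subject: time-mean and time-variance per
    (pair, scale) DCCC and per-channel DFA exponent.

    Missing (NaN) windows are excluded pairwise; variances use the n-1
    divisor. Column names: ``mu_dccc_<ch1>_<ch2>_s<scale>``,
    ``var_dccc_...``, ``mu_dfa_<ch>``, ``var_dfa_<ch>``.
    """
    if tensor.n_windows < 2:
        raise ValueError("need at least 2 windows for a variance")
    cols = {}
    for p, (a, b) in enumerate(tensor.pair_labels()):
        for k, s in enumerate(tensor.scales.scales):
            series = tensor.dccc[:, p, k]
            cols[f"mu_dccc_{a}_{b}_s{s}"] = np.nanmean(series)
            cols[f"var_dccc_{a}_{b}_s{s}"] = np.nanvar(series, ddof=1)
    for c, ch in enumerate(dfa.labels):
        series = dfa.exponents[:, c]
        cols[f"mu_dfa_{ch}"] = np.nanmean(series)
        cols[f"var_dfa_{ch}"] = np.nanvar(series, ddof=1)
    return pd.DataFrame([cols])


def summary_table(
    tensors: dict, dfas: dict, groups: dict[str, str]
) -> pd.DataFrame:
    """Stack per-subject summaries into one table indexed by subject, with a
    ``group`` column."""
    frames = []
    for sid in tensors:
        row = subject_summaries(tensors[sid], dfas[sid])
        row.index = [sid]
        row.insert(0, "group", groups[sid])
        frames.append(row)
    return pd.concat(frames)


def group_compare(a: np.ndarray, b: np.ndarray, alpha_normality: float = 0.05):
    """Two-group comparison with a Lilliefors normality gate.

    Both samples are tested for normality (Lilliefors, i.e.
    Kolmogorov-Smirnov with estimated mean and sd); if both pass at
    ``alpha_normality`` a two-sided Welch t-test runs, otherwise a
    two-sided Mann-Whitney U. Returns ``(p, test_used)`` with ``test_used``
    in {"t", "mannwhitney"}.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if min(a.size, b.size) < 4:
        raise ValueError("each group needs at least 4 values")
    if np.ptp(a) == 0 and np.ptp(b) == 0 and a[0] == b[0]:
        import warnings

        warnings.warn("all values identical in both groups; p set to 1")
        return 1.0, "degenerate"
    normal = True
    for sample in (a, b):
        if np.ptp(sample) == 0:
            normal = False
            break
        _, p_lf = lilliefors(sample, dist="norm")
        if p_lf < alpha_normality:
            normal = False
            break
    if normal:
        _, p = stats.ttest_ind(a, b, equal_var=False)
        return float(p), "t"
    _, p = stats.mannwhitneyu(a, b, alternative="two-sided")
    return float(p), "mannwhitney"


def fdr_bh(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def spearman_with_p(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Spearman rho with average-rank ties and a two-sided p-value.

    For n >= 10 the p-value uses the t approximation; for n < 10 an exact
    permutation distribution of rho is enumerated, which is feasible at
    these sample sizes and avoids the approximation breaking down.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if n != y.size or n < 3:
        raise ValueError("need two equal-length samples of size >= 3")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    if np.ptp(rx) == 0 or np.ptp(ry) == 0:
        return float("nan"), float("nan")
    rho = float(np.corrcoef(rx, ry)[0, 1])
    if n >= 10:
        return stats.spearmanr(x, y)  # t-approximation p
    # exact permutation null of |rho|
    rxc = rx - rx.mean()
    denom = math.sqrt(float(rxc @ rxc) * float((ry - ry.mean()) @ (ry - ry.mean())))
    count = 0
    total = 0
    target = abs(float(rxc @ (ry - ry.mean())) / denom)
    for perm in itertools.permutations(range(n)):
        r = abs(float(rxc @ (ry[list(perm)] - ry.mean())) / denom)
        count += r >= target - 1e-12
        total += 1
    return rho, count / total


@dataclass(frozen=True)
class CorrelationRecord:
    feature: str
    score: str
    group: str
    rho: float
    p: float


def spearman_table(
    summaries: pd.DataFrame,
    scores: pd.DataFrame,
    feature_cols: list[str],
    group_col: str = "group",
) -> pd.DataFrame:
    """Per-group Spearman correlations between chosen connectivity summaries
    and cognitive scores.

    No multiple-testing adjustment is applied — the table is meant for a
    pre-curated feature set where comparisons serve description, not
    discovery. Constant columns are flagged with NaN rho.
    """
    if group_col not in summaries.columns:
        raise ValueError(f"summaries must carry a '{group_col}' column")
    records = []
    for group, sub in summaries.groupby(group_col, sort=True):
        if len(sub) < 5:
            raise ValueError(f"group '{group}' has fewer than 5 subjects")
        sc = scores.loc[sub.index]
        for feat in feature_cols:
            for score_name in scores.columns:
                rho, p = spearman_with_p(
                    sub[feat].to_numpy(), sc[score_name].to_numpy()
                )
                records.append(
                    {
                        "group": group,
                        "feature": feat,
                        "score": score_name,
                        "rho": rho,
                        "p": p,
                    }
                )
    return pd.DataFrame(records)


def abs_mean_variance_corr(
    summaries: pd.DataFrame,
    feature_pairs: list[tuple[str, str]],
    group_col: str = "group",
) -> pd.DataFrame:
    """Pearson relation between coupling strength and temporal variability.

    For each group (and pooled), correlates the absolute group-mean DCCC
    <|mu|> with the group-mean temporal variance across the given
    (mu column, var column) connection pairs, returning r and the OLS
    regression line (slope, intercept).
    """
    if len(feature_pairs) < 3:
        raise ValueError("need at least 3 connections")
    rows = []
    groups = list(summaries[group_col].unique()) + ["combined"]
    for group in groups:
        sub = summaries if group == "combined" else summaries[summaries[group_col] == group]
        xs = np.array([abs(sub[mu].mean()) for mu, _ in feature_pairs])
        ys = np.array([sub[var].mean() for _, var in feature_pairs])
        r = float(np.corrcoef(xs, ys)[0, 1])
        slope, intercept = np.polyfit(xs, ys, 1)
        rows.append(
            {"group": group, "r": r, "slope": float(slope), "intercept": float(intercept),
             "n_connections": len(feature_pairs)}
        )
    return pd.DataFrame(rows)
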