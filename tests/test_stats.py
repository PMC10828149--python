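"""Group comparison gate, FDR adjustment, summaries and correlation
reports."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from fractalconn.fractal import ConnectivityTensor, DFAExponentSeries, ScaleSet
from fractalconn.stats_tools import (
    abs_mean_variance_corr,
    fdr_bh,
    group_compare,
    spearman_table,
    spearman_with_p,
    subject_summaries,
)


def make_tensor(dccc, labels=("a", "b"), scales=(8, 16, 32)):
    dccc = np.asarray(dccc, dtype=float)
    pairs = [(i, j) for i in range(len(labels)) for j in range(i + 1, len(labels))]
    return ConnectivityTensor(dccc, pairs, ScaleSet(scales), list(labels))


class TestSummaries:
    def test_constant_series(self):
        dccc = np.full((5, 1, 3), 0.4)
        dfa = DFAExponentSeries(np.full((5, 2), 0.7), ["a", "b"])
        row = subject_summaries(make_tensor(dccc), dfa)
        assert row["mu_dccc_a_b_s8"].iloc[0] == pytest.approx(0.4)
        assert row["var_dccc_a_b_s8"].iloc[0] == 0.0
        assert row["mu_dfa_a"].iloc[0] == pytest.approx(0.7)

    def test_sample_variance_divisor(self):
        dccc = np.zeros((2, 1, 3))
        dccc[0, 0, :] = -1.0
        dccc[1, 0, :] = 1.0
        dfa = DFAExponentSeries(np.zeros((2, 2)), ["a", "b"])
        row = subject_summaries(make_tensor(dccc), dfa)
        assert row["mu_dccc_a_b_s16"].iloc[0] == 0.0
        assert row["var_dccc_a_b_s16"].iloc[0] == pytest.approx(2.0)

    def test_nan_windows_excluded(self):
        dccc = np.full((4, 1, 3), 0.5)
        dccc[2] = np.nan
        dfa = DFAExponentSeries(np.zeros((4, 2)), ["a", "b"])
        row = subject_summaries(make_tensor(dccc), dfa)
        assert row["mu_dccc_a_b_s8"].iloc[0] == pytest.approx(0.5)


class TestGroupCompare:
    def test_identical_samples_large_p(self, rng):
        a = rng.standard_normal(30)
        p, _ = group_compare(a, a.copy())
        assert p > 0.9

    def test_power_on_shifted_normals(self):
        hits = 0
        for seed in range(50):
            r = np.random.default_rng(seed)
            p, test = group_compare(r.normal(0, 1, 50), r.normal(2, 1, 50))
            hits += p < 1e-3
        assert hits >= 48

    def test_heavy_tails_route_to_mannwhitney(self):
        routed = 0
        for seed in range(50):
            r = np.random.default_rng(seed)
            a = r.standard_cauchy(50)
            b = r.standard_cauchy(50)
            _, test = group_compare(a, b)
            routed += test == "mannwhitney"
        assert routed >= 45

    def test_normal_samples_route_to_t(self):
        routed = 0
        for seed in range(50):
            r = np.random.default_rng(seed)
            _, test = group_compare(r.normal(0, 1, 40), r.normal(0, 1, 40))
            routed += test == "t"
        # Lilliefors at alpha=0.05 falsely rejects ~5% per sample
        assert routed >= 40

    def test_null_pvalues_roughly_uniform(self):
        # Kolmogorov distance of null p-values from U(0,1)
        ps = []
        for seed in range(300):
            r = np.random.default_rng(seed)
            p, _ = group_compare(r.normal(0, 1, 30), r.normal(0, 1, 30))
            ps.append(p)
        d = stats.kstest(ps, "uniform").statistic
        assert d < 0.07

    def test_degenerate_identical_constants(self):
        with pytest.warns(UserWarning):
            p, test = group_compare(np.ones(5), np.ones(5))
        assert p == 1.0


class TestFdrBh:
    def test_single_p_unchanged(self):
        assert fdr_bh([0.03])[0] == pytest.approx(0.03)

    def test_worked_example(self):
        # step-up: p(i)*m/i = [.04, .04, .04, .04] after running minimum
        adj = fdr_bh([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(adj, 0.04)

    def test_adjusted_at_least_raw_and_order_invariant(self, rng):
        p = rng.uniform(size=25)
        adj = fdr_bh(p)
        assert np.all(adj >= p - 1e-15)
        perm = rng.permutation(25)
        assert np.allclose(fdr_bh(p[perm]), adj[perm])

    def test_invalid_rejected(self):
        with pytest.raises(ValueError):
            fdr_bh([0.5, 1.2])


class TestSpearman:
    def test_monotone_gives_unity(self):
        x = np.array([1.0, 2.0, 5.0, 9.0, 11.0, 20.0, 21.0, 30.0, 31.0, 40.0])
        rho, p = spearman_with_p(x, np.exp(x / 10))
        assert rho == pytest.approx(1.0)
        assert p < 1e-6

    def test_ties_match_rank_then_pearson_oracle(self, rng):
        for _ in range(20):
            x = rng.integers(0, 4, 12).astype(float)
            y = rng.standard_normal(12)
            if np.ptp(x) == 0:
                continue
            rho, _ = spearman_with_p(x, y)
            oracle = np.corrcoef(stats.rankdata(x), stats.rankdata(y))[0, 1]
            assert rho == pytest.approx(oracle, abs=1e-12)

    def test_small_n_exact_permutation_p(self):
        # n=5 monotone: exact two-sided p = 2/5! for the extreme ranking
        rho, p = spearman_with_p(np.arange(5.0), np.arange(5.0) ** 2)
        assert rho == pytest.approx(1.0)
        assert p == pytest.approx(2 / 120)

    def test_null_false_positive_rate(self):
        hits = 0
        reps = 100
        for seed in range(reps):
            r = np.random.default_rng(seed)
            _, p = spearman_with_p(r.standard_normal(20), r.standard_normal(20))
            hits += p < 0.05
        assert 0.05 - 0.03 <= hits / reps <= 0.05 + 0.03


class TestSpearmanTable:
    def make_inputs(self, rng, n=6):
        idx = [f"s{i}" for i in range(2 * n)]
        summaries = pd.DataFrame(
            {
                "group": ["young"] * n + ["elderly"] * n,
                "mu_dccc_a_b_s8": rng.standard_normal(2 * n),
                "var_dccc_a_b_s8": rng.uniform(0.01, 0.1, 2 * n),
            },
            index=idx,
        )
        scores = pd.DataFrame(
            {"latency": summaries["mu_dccc_a_b_s8"] * 2.0}, index=idx
        )
        return summaries, scores

    def test_perfect_monotone_score(self, rng):
        summaries, scores = self.make_inputs(rng)
        table = spearman_table(summaries, scores, ["mu_dccc_a_b_s8"])
        assert set(table["group"]) == {"young", "elderly"}
        assert np.allclose(table["rho"], 1.0)

    def test_requires_five_per_group(self, rng):
        summaries, scores = self.make_inputs(rng, n=4)
        with pytest.raises(ValueError):
            spearman_table(summaries, scores, ["mu_dccc_a_b_s8"])


class TestAbsMeanVarianceCorr:
    def test_exact_negative_relation(self):
        mus = [0.1, 0.4, 0.8]
        summaries = pd.DataFrame(
            {
                "group": ["young", "elderly"] * 3,
                **{f"mu_dccc_p{i}": m for i, m in enumerate(mus)},
                **{f"var_dccc_p{i}": 1.0 - m for i, m in enumerate(mus)},
            }
        )
        pairs = [(f"mu_dccc_p{i}", f"var_dccc_p{i}") for i in range(3)]
        out = abs_mean_variance_corr(summaries, pairs)
        assert np.allclose(out["r"], -1.0)
        combined = out[out["group"] == "combined"].iloc[0]
        assert combined["slope"] == pytest.approx(-1.0)

    def test_too_few_connections(self):
        with pytest.raises(ValueError):
            abs_mean_variance_corr(pd.DataFrame({"group": []}), [("a", "b")])

    def test_stronger_couplings_fluctuate_less(self):
        """Across connections spanning weak to strong static couplings, the
        bounded coefficient's temporal variance shrinks as |mean| grows, so
        the strength-variability Pearson r is negative."""
        from fractalconn.fractal import ScaleSet, WindowPlan, sliding_connectivity
        from fractalconn.preprocess import EEGRecording
        from fractalconn.synthetic import gen_coupled_pair

        rhos = np.linspace(0.2, 0.9, 8)
        neg = 0
        for seed in range(10):
            rows = {"group": ["x"]}
            for i, rho in enumerate(rhos):
                x, y = gen_coupled_pair(0.7, rho, 4736, 1000 * seed + i)
                rec = EEGRecording(np.vstack([x, y]), 256.0)
                tensor, _ = sliding_connectivity(
                    rec, ScaleSet((8, 32, 128)), WindowPlan(1024, 128)
                )
                v = tensor.dccc[:, 0, 0]
                rows[f"mu_dccc_p{i}"] = [v.mean()]
                rows[f"var_dccc_p{i}"] = [v.var(ddof=1)]
            frame = pd.DataFrame(rows)
            pairs = [(f"mu_dccc_p{i}", f"var_dccc_p{i}") for i in range(len(rhos))]
            out = abs_mean_variance_corr(frame, pairs)
            neg += out.query("group == 'combined'")["r"].iloc[0] < 0
        assert neg >= 8
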