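"""Differential methylation: normalization, stratification, NB Wald test."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from m6akit.diffmeth import (
    BinwiseDiffMeth,
    benjamini_hochberg,
    compile_label_sets,
    estimate_size_factors,
    gene_log2fc,
    stratify_genes,
)
from m6akit.io import GenomicSite
from m6akit.peaks import Peak


class TestSizeFactors:
    def test_identical_columns_give_unit_factors(self):
        counts = pd.DataFrame(np.tile([[10], [20], [30]], (1, 4)))
        assert np.allclose(estimate_size_factors(counts), 1.0)

    def test_doubled_column(self):
        rng = np.random.default_rng(0)
        base = rng.integers(10, 100, size=(50, 1))
        counts = pd.DataFrame(np.hstack([base, base, 2 * base]))
        f = estimate_size_factors(counts).to_numpy()
        # before rescaling the doubled column is 2x the others
        assert np.isclose(f[2] / f[0], 2.0)
        assert np.isclose(np.exp(np.mean(np.log(f))), 1.0)

    def test_matches_naive_median_of_ratios(self):
        rng = np.random.default_rng(1)
        counts = pd.DataFrame(rng.integers(0, 200, size=(200, 6)))
        got = estimate_size_factors(counts).to_numpy()
        # independent brute-force oracle
        mat = counts.to_numpy(dtype=float)
        rows = mat[(mat > 0).all(axis=1)]
        geo = np.prod(rows, axis=1) ** (1 / rows.shape[1])
        naive = np.array([np.median(rows[:, j] / geo) for j in range(6)])
        naive = naive / np.prod(naive) ** (1 / 6)
        assert np.allclose(got, naive)

    def test_fallback_when_no_common_gene(self):
        counts = pd.DataFrame([[5, 0], [0, 5]])
        with pytest.warns(UserWarning, match="total-count"):
            f = estimate_size_factors(counts)
        assert np.allclose(f, 1.0)


class TestGeneLog2fc:
    def _expr(self, wt, ko):
        data = {f"WT_{i}": [v] for i, v in enumerate(wt)}
        data.update({f"KO_{i}": [v] for i, v in enumerate(ko)})
        return pd.DataFrame(data, index=["g"])

    def test_hand_arithmetic(self):
        expr = self._expr([100, 100], [25, 25])
        lfc = gene_log2fc(expr, ["WT_0", "WT_1"], ["KO_0", "KO_1"],
                          size_factors=pd.Series(1.0, index=expr.columns))
        assert np.isclose(lfc["g"], np.log2(26 / 101), atol=1e-9)

    def test_equal_means_zero(self):
        expr = self._expr([50, 50], [50, 50])
        lfc = gene_log2fc(expr, ["WT_0", "WT_1"], ["KO_0", "KO_1"],
                          size_factors=pd.Series(1.0, index=expr.columns))
        assert lfc["g"] == 0.0

    def test_ko_all_zero(self):
        expr = self._expr([100, 100], [0, 0])
        lfc = gene_log2fc(expr, ["WT_0", "WT_1"], ["KO_0", "KO_1"],
                          size_factors=pd.Series(1.0, index=expr.columns))
        assert np.isclose(lfc["g"], np.log2(1 / 101), atol=1e-9)

    def test_all_zero_gene_excluded(self):
        expr = pd.DataFrame({"WT_0": [0, 5], "WT_1": [0, 5], "KO_0": [0, 5], "KO_1": [0, 5]},
                            index=["dead", "alive"])
        lfc = gene_log2fc(expr, ["WT_0", "WT_1"], ["KO_0", "KO_1"],
                          size_factors=pd.Series(1.0, index=expr.columns))
        assert list(lfc.index) == ["alive"]


class TestStratifyGenes:
    def test_quantile_bins(self):
        lfc = pd.Series(np.arange(100, dtype=float), index=[f"g{i}" for i in range(100)])
        bins = stratify_genes(lfc, n_bins=4, min_genes=10)
        sizes = bins.gene_bin.value_counts().sort_index()
        assert list(sizes) == [25, 25, 25, 25]

    def test_degenerate_identical_values_single_bin(self):
        lfc = pd.Series(0.0, index=[f"g{i}" for i in range(50)])
        bins = stratify_genes(lfc, n_bins=10)
        assert bins.n_bins == 1

    def test_bin_means_non_decreasing(self):
        rng = np.random.default_rng(2)
        lfc = pd.Series(rng.normal(size=300), index=[f"g{i}" for i in range(300)])
        bins = stratify_genes(lfc, n_bins=20)
        means = lfc.groupby(bins.gene_bin).mean()
        assert (means.sort_index().diff().dropna() >= 0).all()

    def test_fewer_genes_than_bins_warns(self):
        lfc = pd.Series(np.arange(5, dtype=float), index=list("abcde"))
        with pytest.warns(UserWarning, match="reducing"):
            stratify_genes(lfc, n_bins=10, min_genes=1)


class TestBenjaminiHochberg:
    def test_hand_computation(self):
        # p (0.01,0.02,0.03,0.04), m=4: q_i = p_i * 4/i then monotone -> all 0.04
        q = benjamini_hochberg(np.array([0.01, 0.02, 0.03, 0.04]))
        assert np.allclose(q, 0.04)

    def test_matches_textbook_formula(self):
        rng = np.random.default_rng(3)
        p = rng.uniform(size=100)
        q = benjamini_hochberg(p)
        # brute-force oracle
        m = len(p)
        order = np.argsort(p)
        expected = np.empty(m)
        prev = 1.0
        for rank in range(m, 0, -1):
            i = order[rank - 1]
            prev = min(prev, p[i] * m / rank)
            expected[i] = prev
        assert np.allclose(q, expected)

    def test_nan_propagates_and_is_excluded(self):
        q = benjamini_hochberg(np.array([0.01, np.nan, 0.04]))
        assert np.isnan(q[1])
        assert np.allclose(q[[0, 2]], [0.02, 0.04])


def _fit(wt, ko, bins=None, genes=None):
    counts = pd.DataFrame(
        [list(wt) + list(ko)],
        index=["p1"],
        columns=[f"WT_{i}" for i in range(len(wt))] + [f"KO_{i}" for i in range(len(ko))],
    )
    model = BinwiseDiffMeth(counts, ["WT"] * len(wt) + ["KO"] * len(ko),
                            peak_genes=genes, bins=bins)
    return model.fit().table.iloc[0]


class TestWaldTest:
    def test_symmetric_null(self):
        rec = _fit([20, 22, 18], [20, 19, 21])
        assert abs(rec["log2fc"]) < 0.1
        assert rec["pvalue"] > 0.5

    def test_strong_depletion(self):
        rec = _fit([100, 90, 110], [5, 4, 6])
        assert rec["log2fc"] < -3.5
        assert rec["pvalue"] < 1e-6

    def test_zero_count_peak_untested(self):
        counts = pd.DataFrame(
            {"WT_1": [0, 10], "WT_2": [0, 12], "KO_1": [0, 11], "KO_2": [0, 9]},
            index=["dead", "alive"],
        )
        res = BinwiseDiffMeth(counts, ["WT", "WT", "KO", "KO"]).fit()
        assert np.isnan(res.table.loc["dead", "pvalue"])
        assert not np.isnan(res.table.loc["alive", "pvalue"])

    def test_requires_two_replicates_per_condition(self):
        counts = pd.DataFrame({"WT_1": [5], "KO_1": [5], "KO_2": [5]})
        with pytest.raises(ValueError, match="replicates"):
            BinwiseDiffMeth(counts, ["WT", "KO", "KO"])

    def test_rank_concordant_with_nb_likelihood_ratio(self):
        """Wald p-values agree in rank with an NB likelihood-ratio oracle
        (fixed dispersion, closed-form mean MLEs) over random counts."""
        rng = np.random.default_rng(4)
        n_cases = 200
        rows = []
        for _ in range(n_cases):
            mu_wt = rng.uniform(5, 200)
            mu_ko = mu_wt * 2.0 ** rng.normal(0, 1.5)
            phi = rng.uniform(0.01, 0.3)
            r = 1 / phi
            wt = rng.negative_binomial(r, r / (r + mu_wt), size=3)
            ko = rng.negative_binomial(r, r / (r + max(mu_ko, 0.5)), size=3)
            rows.append(list(wt) + list(ko))
        counts = pd.DataFrame(
            rows, columns=["WT_1", "WT_2", "WT_3", "KO_1", "KO_2", "KO_3"],
            index=[f"p{i}" for i in range(n_cases)],
        )
        counts = counts[counts.sum(axis=1) > 0]
        model = BinwiseDiffMeth(counts, ["WT"] * 3 + ["KO"] * 3)
        table = model.fit().table

        def nb_loglik(x, mu, phi):
            r = 1 / phi
            return stats.nbinom.logpmf(x, r, r / (r + mu)).sum()

        lr_p = []
        for pid, row in counts.iterrows():
            x_wt, x_ko = row.to_numpy()[:3], row.to_numpy()[3:]
            phi = table.loc[pid, "dispersion"]
            mu_w, mu_k = max(x_wt.mean(), 1e-6), max(x_ko.mean(), 1e-6)
            mu_0 = row.mean()
            ll_alt = nb_loglik(x_wt, mu_w, phi) + nb_loglik(x_ko, mu_k, phi)
            ll_null = nb_loglik(x_wt, mu_0, phi) + nb_loglik(x_ko, mu_0, phi)
            lr = max(2 * (ll_alt - ll_null), 0.0)
            lr_p.append(stats.chi2.sf(lr, df=1))
        rho = stats.spearmanr(table["pvalue"], lr_p).statistic
        assert rho >= 0.95

    def test_null_calibration(self):
        """Under a global NB null the fraction of FDR<=0.05 calls stays
        near zero."""
        rates = []
        for seed in range(20):
            rng = np.random.default_rng(100 + seed)
            r = 1 / 0.1
            mu = rng.uniform(10, 100, size=2000)
            counts = pd.DataFrame(
                rng.negative_binomial(r, r / (r + mu[:, None]), size=(2000, 6)),
                columns=["WT_1", "WT_2", "WT_3", "KO_1", "KO_2", "KO_3"],
            )
            res = BinwiseDiffMeth(counts, ["WT"] * 3 + ["KO"] * 3).fit()
            rates.append((res.table["fdr"] <= 0.05).mean())
        assert np.mean(rates) <= 0.07


class TestOneRunVsBinBased:
    def test_agreement_without_confounding(self):
        """With no expression shifts the two strategies call nearly the
        same site set (Jaccard >= 0.9)."""
        from m6akit.synthetic import SimConfig, simulate_dataset
        from m6akit.diffmeth import gene_log2fc as glfc, stratify_genes as strat

        ds = simulate_dataset(SimConfig(seed=15, n_genes=150, n_true_sites=300,
                                        n_background_peaks=1200, frac_genes_shifted=0.0))
        cols = ds.counts.expression.columns
        lfc = glfc(ds.counts.expression, cols[:3], cols[3:])
        bins = strat(lfc)
        binbased = BinwiseDiffMeth(ds.counts.peak_counts, ds.counts.sample_conditions,
                                   peak_genes=ds.counts.peak_genes, bins=bins).fit()
        onerun = BinwiseDiffMeth(ds.counts.peak_counts, ds.counts.sample_conditions).fit()
        a = set(binbased.significant(0.01).index)
        b = set(onerun.significant(0.01).index)
        assert len(a & b) / len(a | b) >= 0.9

    def test_empty_input(self):
        counts = pd.DataFrame(columns=["WT_1", "WT_2", "KO_1", "KO_2"])
        res = BinwiseDiffMeth(counts, ["WT", "WT", "KO", "KO"]).fit()
        assert len(res.table) == 0


class TestCompileLabelSets:
    def _peak(self, pid, base):
        return Peak(site=GenomicSite("chr1", 10, "+"), peak_id=pid, base=base)

    def _results(self, rows):
        import m6akit.diffmeth as dm

        table = pd.DataFrame(rows).set_index("peak_id")
        return dm.DiffMethResults(table=table, mode="bin-based")

    def test_threshold_semantics(self):
        res = self._results([
            {"peak_id": "a", "log2fc": -1.2, "fdr": 0.005},
            {"peak_id": "b", "log2fc": -1.0, "fdr": 0.2},
            {"peak_id": "c", "log2fc": 0.3, "fdr": 0.8},
            {"peak_id": "d", "log2fc": -0.5, "fdr": np.nan},
        ])
        peaks = [self._peak(p, "A") for p in "abcd"] + [self._peak("u", "T")]
        pos, neg = compile_label_sets(res, peaks)
        assert [p.peak_id for p in pos] == ["a"]
        assert [p.peak_id for p in neg] == ["c"]

    def test_non_adenosine_excluded(self):
        res = self._results([{"peak_id": "x", "log2fc": -2.0, "fdr": 1e-4}])
        pos, neg = compile_label_sets(res, [self._peak("x", "T")])
        assert pos == [] and neg == []
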