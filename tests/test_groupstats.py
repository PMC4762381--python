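import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats
from scipy.cluster.hierarchy import cophenet, linkage
from scipy.spatial.distance import squareform

import nonzein as nz

from conftest import make_counts


class TestEnrichmentScore:
    def test_single_p_of_005_gives_1_30(self):
        assert nz.enrichment_score([0.05]) == pytest.approx(1.30, abs=0.005)

    def test_all_ones_give_zero(self):
        assert nz.enrichment_score([1, 1, 1]) == 0.0

    def test_geometric_mean_by_hand(self):
        # geometric mean of 0.01 and 0.0001 is 1e-3
        assert nz.enrichment_score([0.01, 0.0001]) == pytest.approx(3.0)

    def test_out_of_range_rejected(self):
        with pytest.raises(nz.ValidationError):
            nz.enrichment_score([0.0, 0.5])
        with pytest.raises(nz.ValidationError):
            nz.enrichment_score([1.5])

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.lists(st.floats(1e-12, 1.0), min_size=1, max_size=12))
    def test_equals_mean_neg_log10(self, ps):
        expected = np.mean([-np.log10(p) for p in ps])
        assert nz.enrichment_score(ps) == pytest.approx(expected, rel=1e-9)

    def test_monotone_decreasing_in_each_member(self):
        base = [0.1, 0.2, 0.3]
        lowered = [0.05, 0.2, 0.3]
        assert nz.enrichment_score(lowered) > nz.enrichment_score(base)


def exhaustive_ranksum_p(values, bin_idx):
    """Two-sided rank-sum p by full enumeration of bin assignments."""
    ranks = stats.rankdata(values)
    n, k = len(values), len(bin_idx)
    obs = ranks[list(bin_idx)].sum()
    sums = np.array(
        [ranks[list(c)].sum() for c in itertools.combinations(range(n), k)]
    )
    center = sums.mean()
    return np.mean(np.abs(sums - center) >= abs(obs - center) - 1e-12)


class TestBinwiseWilcoxon:
    @pytest.mark.parametrize("n_bin,n_rest", [(3, 5), (4, 7), (6, 10), (2, 9)])
    def test_matches_exhaustive_enumeration(self, n_bin, n_rest):
        rng = np.random.default_rng(n_bin * 100 + n_rest)
        values = rng.normal(size=n_bin + n_rest)
        ids = [f"P{i}" for i in range(n_bin + n_rest)]
        fc = pd.Series(values, index=ids)
        bins = nz.BinMap(
            {"test": set(ids[:n_bin]), "other": set(ids[n_bin:])}, min_bin_size=2
        )
        out = nz.binwise_wilcoxon(fc, bins)
        expected = exhaustive_ranksum_p(values, range(n_bin))
        assert out.loc["test", "p_value"] == pytest.approx(expected, rel=1e-9)

    def test_separated_bin_from_worked_example(self):
        fc = pd.Series(
            [10.0, 11, 12, 1, 2, 3, 4, 5],
            index=["a", "b", "c", "d", "e", "f", "g", "h"],
        )
        bins = nz.BinMap({"bin": {"a", "b", "c"}, "bg": set("defgh")})
        out = nz.binwise_wilcoxon(fc, bins)
        assert out.loc["bin", "p_value"] == pytest.approx(
            exhaustive_ranksum_p(fc.to_numpy(), range(3))
        )
        assert out.loc["bin", "direction"] == "up"

    def test_shift_invariance(self):
        rng = np.random.default_rng(8)
        ids = [f"P{i}" for i in range(30)]
        fc = pd.Series(rng.normal(size=30), index=ids)
        bins = nz.BinMap({"a": set(ids[:6]), "b": set(ids[6:])})
        p1 = nz.binwise_wilcoxon(fc, bins)["p_value"]
        p2 = nz.binwise_wilcoxon(fc + 42.0, bins)["p_value"]
        np.testing.assert_allclose(p1, p2, rtol=1e-12)

    def test_null_bins_rarely_significant(self):
        rng = np.random.default_rng(12)
        hits, trials = 0, 200
        for _ in range(trials):
            ids = [f"P{i}" for i in range(40)]
            fc = pd.Series(rng.normal(size=40), index=ids)
            bins = nz.BinMap({"a": set(ids[:8]), "rest": set(ids[8:])})
            hits += int(nz.binwise_wilcoxon(fc, bins).loc["a", "significant"])
        # 99% binomial envelope around 0.05 for 200 trials
        assert hits / trials < 0.05 + 2.5758 * np.sqrt(0.05 * 0.95 / trials)

    def test_small_bins_skipped(self):
        fc = pd.Series([1.0, 2, 3, 4, 5], index=list("abcde"))
        bins = nz.BinMap({"tiny": {"a", "b"}, "rest": {"c", "d", "e"}}, min_bin_size=3)
        out = nz.binwise_wilcoxon(fc, bins)
        assert "tiny" not in out.index


def _isa_table(values, genotypes):
    m = make_counts(values, genotypes, zero_corrected=True)
    return nz.AbundanceTable(m.counts, 1.0, "genotype_mean", m.sample_meta), m.sample_meta


def manual_balanced_pointbiserial(a, labels, combo):
    member = np.isin(labels, combo)
    w = np.where(member, 0.5 / member.sum(), 0.5 / (~member).sum())
    ma = (a * w).sum()
    cov = (a * w * member).sum() - 0.5 * ma
    va = (a * a * w).sum() - ma**2
    return 2 * cov / np.sqrt(va)


class TestIndicatorAnalysis:
    def test_perfect_indicator_has_statistic_one(self):
        tab, meta = _isa_table(
            [[1.0, 1.0, 0.0, 0.0, 0.0, 0.0]], ["A", "A", "B", "B", "C", "C"]
        )
        res = nz.indicator_analysis(tab, meta, max_combo_size=2, exhaustive=True)
        assert res.table.loc["P0", "combination"] == "A"
        assert res.table.loc["P0", "statistic"] == pytest.approx(1.0)

    def test_exhaustive_matches_hand_enumeration(self):
        labels = ["A", "A", "B", "B"]
        tab, meta = _isa_table([[1.0, 0.9, 0.1, 0.0], [0.2, 0.8, 0.3, 0.7]], labels)
        res = nz.indicator_analysis(tab, meta, max_combo_size=1, exhaustive=True)
        arrangements = sorted(set(itertools.permutations(labels)))
        for pid in ["P0", "P1"]:
            a = tab.values.loc[pid].to_numpy()
            obs = max(
                manual_balanced_pointbiserial(a, np.array(labels), c)
                for c in (("A",), ("B",))
            )
            ge = sum(
                max(
                    manual_balanced_pointbiserial(a, np.array(arr), c)
                    for c in (("A",), ("B",))
                )
                >= obs - 1e-12
                for arr in arrangements
            )
            assert res.table.loc[pid, "p_value"] == pytest.approx(ge / len(arrangements))

    def test_constant_protein_missing_statistic_p_one(self):
        tab, meta = _isa_table([[3.0, 3.0, 3.0, 3.0]], ["A", "A", "B", "B"])
        res = nz.indicator_analysis(tab, meta, exhaustive=True)
        assert np.isnan(res.table.loc["P0", "statistic"])
        assert res.table.loc["P0", "p_value"] == 1.0

    def test_null_super_uniform(self):
        rng = np.random.default_rng(21)
        vals = rng.lognormal(0, 0.5, size=(150, 12))
        tab, meta = _isa_table(vals, ["A"] * 4 + ["B"] * 4 + ["C"] * 4)
        res = nz.indicator_analysis(tab, meta, n_perm=199, seed=5)
        frac = (res.table["p_value"] < 0.05).mean()
        # valid permutation p-values: rejection rate at most ~alpha
        assert frac <= 0.05 + 2.5758 * np.sqrt(0.05 * 0.95 / len(vals))


class TestPCA:
    def test_variance_fractions_sum_to_one(self, small_nsaf):
        _, ratios = nz.pca(small_nsaf)
        assert ratios.sum() == pytest.approx(1.0)

    def test_collinear_data_single_component(self):
        t = np.linspace(0, 1, 5)
        vals = np.vstack([2 * t + 1, -3 * t + 4])  # proteins x samples, on a line
        df = pd.DataFrame(vals, index=["P0", "P1"], columns=[f"s{i}" for i in range(5)])
        tab = nz.AbundanceTable(df, 1.0, "genotype_mean")
        _, ratios = nz.pca(tab)
        assert ratios[0] == pytest.approx(1.0)

    def test_scores_match_eigendecomposition(self):
        rng = np.random.default_rng(4)
        df = pd.DataFrame(
            rng.normal(size=(6, 3)), index=[f"P{i}" for i in range(6)], columns=list("abc")
        )
        tab = nz.AbundanceTable(df, 1.0, "log")
        scores, ratios = nz.pca(tab)
        X = df.to_numpy().T
        Xc = X - X.mean(axis=0)
        cov = Xc.T @ Xc / (X.shape[0] - 1)
        w, v = np.linalg.eigh(cov)
        order = np.argsort(w)[::-1]
        w, v = w[order], v[:, order]
        expected = Xc @ v[:, : scores.shape[1]]
        for j in range(scores.shape[1]):
            got = scores.iloc[:, j].to_numpy()
            assert np.allclose(got, expected[:, j], atol=1e-9) or np.allclose(
                got, -expected[:, j], atol=1e-9
            )
        np.testing.assert_allclose(ratios, (w / w.sum())[: len(ratios)], atol=1e-9)

    def test_reconstruction_from_all_components(self, small_nsaf):
        X = small_nsaf.values.to_numpy().T
        scores, _ = nz.pca(small_nsaf)
        from sklearn.decomposition import PCA

        model = PCA(n_components=scores.shape[1], svd_solver="full").fit(X)
        back = model.inverse_transform(model.transform(X))
        np.testing.assert_allclose(back, X, atol=1e-6 * np.abs(X).max())


class TestHcluster:
    def test_identical_columns_merge_at_zero(self):
        rng = np.random.default_rng(9)
        x = rng.normal(size=20)
        df = pd.DataFrame({"a": x, "b": x, "c": rng.normal(size=20)})
        tree = nz.hcluster(df)
        first = tree.merges[0]
        assert {first[0], first[1]} == {"a", "b"}
        assert first[2] == pytest.approx(0.0, abs=1e-12)

    def test_anticorrelated_columns_maximal_distance(self):
        x = np.array([1.0, 2, 3, 4])
        df = pd.DataFrame({"a": x, "b": -x})
        assert nz.pearson_distance(df).loc["a", "b"] == pytest.approx(2.0)

    def test_constant_column_rejected_by_name(self):
        df = pd.DataFrame({"a": [1.0, 2, 3], "b": [5.0, 5, 5]})
        with pytest.raises(nz.ValidationError, match="b"):
            nz.hcluster(df)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_matches_scipy_average_linkage(self, seed):
        rng = np.random.default_rng(seed)
        df = pd.DataFrame(
            rng.normal(size=(40, 4)), columns=["w", "x", "y", "z"]
        )
        tree = nz.hcluster(df)
        D = nz.pearson_distance(df)
        Z = linkage(squareform(D.to_numpy(), checks=False), method="average")
        expected = squareform(cophenet(Z))
        got = tree.cophenetic().loc[df.columns, df.columns].to_numpy()
        np.testing.assert_allclose(got, expected, atol=1e-10)

    def test_newick_is_parseable_and_complete(self, small_nsaf):
        from io import StringIO

        from Bio import Phylo

        means = nz.genotype_means(small_nsaf)
        tree = nz.hcluster(means.values)
        parsed = Phylo.read(StringIO(tree.to_newick()), "newick")
        assert sorted(t.name for t in parsed.get_terminals()) == sorted(
            means.values.columns
        )
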