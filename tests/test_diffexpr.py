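"""NB differential expression, BH correction, overlap tests, sex-bias
classification, and PPI filtering against independent oracles."""

import itertools
import math

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import dosagefx as d
from dosagefx.preprocess import prefilter_low_counts


def brute_force_bh(p):
    """Step-up BH by direct definition: padj_i = min over j with
    p_j >= p_i of p_j * n / rank_j, capped at 1."""
    n = len(p)
    order = np.argsort(p, kind="mergesort")
    out = np.empty(n)
    running = np.inf
    for rank in range(n, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * n / rank)
        out[i] = min(running, 1.0)
    return out


def hypergeom_tail(k, M, n, N):
    """P(X >= k) by exhaustive summation of hypergeometric pmf terms."""
    total = 0.0
    for x in range(k, min(n, N) + 1):
        total += (
            math.comb(n, x) * math.comb(M - n, N - x) / math.comb(M, N)
        )
    return total


def frame(arr, prefix="s"):
    return pd.DataFrame(
        np.asarray(arr),
        index=[f"g{i}" for i in range(len(arr))],
        columns=[f"{prefix}{j}" for j in range(np.asarray(arr).shape[1])],
    )


class TestSizeFactors:
    def test_identical_columns_give_unit_factors(self):
        K = frame([[10, 10], [100, 100]])
        assert np.allclose(d.size_factors(K), 1.0)

    def test_doubled_column(self):
        K = frame([[10, 20], [100, 200], [7, 14]])
        sf = d.size_factors(K)
        assert sf.iloc[1] / sf.iloc[0] == pytest.approx(2.0)

    def test_manual_median_of_ratios(self):
        """3x2 toy verified by hand: geometric means (sqrt(200), sqrt(20000),
        sqrt(2)); every ratio column is (1/sqrt 2, sqrt 2) times a constant,
        so factors are (1/sqrt2, sqrt2) after median."""
        K = frame([[10, 20], [100, 200], [1, 2]])
        gm = np.sqrt(np.array([10 * 20, 100 * 200, 1 * 2]))
        expected = [np.median(K.to_numpy()[:, j] / gm) for j in range(2)]
        assert np.allclose(d.size_factors(K), expected)
        assert d.size_factors(K).iloc[0] == pytest.approx(1 / np.sqrt(2))

    def test_no_all_positive_gene_rejected(self):
        K = frame([[0, 5], [5, 0]])
        with pytest.raises(ValueError, match="prefilter"):
            d.size_factors(K)


class TestBH:
    def test_hand_computed_stepup(self):
        out = d.bh_adjust([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(out, [0.04, 0.04, 0.04, 0.04])

    def test_single_and_saturated(self):
        assert d.bh_adjust([0.42]) == pytest.approx([0.42])
        assert np.allclose(d.bh_adjust([1.0, 1.0, 1.0]), 1.0)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            d.bh_adjust([0.5, 1.5])

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=20))
    @settings(max_examples=300, deadline=None)
    def test_matches_brute_force_oracle(self, p):
        assert np.allclose(d.bh_adjust(p), brute_force_bh(np.array(p)))

    @given(st.lists(st.floats(0, 1), min_size=2, max_size=15))
    @settings(max_examples=100, deadline=None)
    def test_monotone_in_p(self, p):
        p = np.array(p)
        adj = d.bh_adjust(p)
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-15).all()


class TestOverlap:
    def test_enumerated_example(self):
        """Universe 10, |a|=4, |b|=5, overlap 4: verified against the
        exhaustive hypergeometric tail summation."""
        u = [f"g{i}" for i in range(10)]
        a, b = set(u[:4]), set(u[:5])
        res = d.overlap_test(a, b, u)
        assert res["intersection"] == 4
        assert res["p_value"] == pytest.approx(hypergeom_tail(4, 10, 4, 5))

    def test_disjoint_sets_not_enriched(self):
        u = [f"g{i}" for i in range(10)]
        res = d.overlap_test(set(u[:3]), set(u[5:8]), u)
        assert res["p_value"] == pytest.approx(1.0)

    def test_forced_overlap(self):
        u = [f"g{i}" for i in range(6)]
        res = d.overlap_test(set(u), set(u[:2]), u)
        assert res["intersection"] == 2
        assert res["p_value"] == pytest.approx(1.0)

    def test_set_outside_universe_rejected(self):
        with pytest.raises(ValueError):
            d.overlap_test({"x"}, {"y"}, {"y"})

    def test_exhaustive_oracle_small_universes(self):
        """All (universe, set sizes, overlap) configurations up to a
        universe of 30 on a deterministic subsample."""
        rng = np.random.default_rng(0)
        for M in range(2, 31, 4):
            u = [f"g{i}" for i in range(M)]
            for na, nb in itertools.product(range(1, M + 1, 5), repeat=2):
                a = set(rng.choice(u, na, replace=False))
                b = set(rng.choice(u, nb, replace=False))
                k = len(a & b)
                assert d.overlap_test(a, b, u)["p_value"] == pytest.approx(
                    hypergeom_tail(k, M, na, nb), abs=1e-12
                )


class TestNBWald:
    def test_null_calibration_small(self, nb_matrix):
        """Quick null check (500 genes); the full-size calibration lives in
        the acceptance suite."""
        rng = np.random.default_rng(21)
        mu = rng.lognormal(5, 1.2, 500)
        K = frame(nb_matrix(rng, mu, 0.1, 6))
        res = d.nb_wald_test(K, pd.Series(["a"] * 3 + ["b"] * 3, index=K.columns))
        assert 0.02 <= (res["pvalue"] < 0.05).mean() <= 0.09

    def test_contrast_reversal_negates_exactly(self, nb_matrix):
        rng = np.random.default_rng(22)
        K = frame(nb_matrix(rng, rng.lognormal(4, 1, 300), 0.1, 6))
        grp = pd.Series(["a"] * 3 + ["b"] * 3, index=K.columns)
        r1 = d.nb_wald_test(K, grp)
        r2 = d.nb_wald_test(K, grp, levels=("b", "a"))
        assert np.array_equal(r1["log2fc"].to_numpy(), -r2["log2fc"].to_numpy())
        assert np.array_equal(r1["pvalue"].to_numpy(), r2["pvalue"].to_numpy())

    def test_identical_groups_zero_log2fc(self, nb_matrix):
        rng = np.random.default_rng(23)
        half = nb_matrix(rng, rng.lognormal(4, 1, 200), 0.1, 3)
        K = frame(np.hstack([half, half]))
        res = d.nb_wald_test(K, pd.Series(["a"] * 3 + ["b"] * 3, index=K.columns))
        assert (res["log2fc"] == 0).all()

    def test_de_counts_monotone_in_alpha(self, nb_matrix):
        rng = np.random.default_rng(24)
        mu = rng.lognormal(5, 1, 400)
        lfc = np.where(np.arange(400) < 60, 1.2, 0.0)
        K = frame(
            np.hstack([nb_matrix(rng, mu, 0.05, 3),
                       nb_matrix(rng, mu * 2**lfc, 0.05, 3)])
        )
        res = d.nb_wald_test(K, pd.Series(["a"] * 3 + ["b"] * 3, index=K.columns))
        counts = [int((res["padj"] < a).sum()) for a in (0.01, 0.05, 0.1, 0.2)]
        assert counts == sorted(counts)

    def test_padj_at_least_pvalue(self, nb_matrix):
        rng = np.random.default_rng(25)
        K = frame(nb_matrix(rng, rng.lognormal(4, 1, 300), 0.1, 6))
        res = d.nb_wald_test(K, pd.Series(["a"] * 3 + ["b"] * 3, index=K.columns))
        assert (res["padj"] >= res["pvalue"] - 1e-15).all()
        assert (res["padj"] <= 1.0).all()

    def test_fewer_than_two_per_group_rejected(self, nb_matrix):
        rng = np.random.default_rng(26)
        K = frame(nb_matrix(rng, np.full(10, 50.0), 0.1, 3))
        with pytest.raises(ValueError, match="fewer than 2"):
            d.nb_wald_test(K, pd.Series(["a", "a", "b"], index=K.columns))

    def test_agrees_with_pydeseq2_reference(self, nb_matrix):
        """Independent cross-check of fold changes against the DESeq2
        reference implementation on a small fixture."""
        from pydeseq2.dds import DeseqDataSet
        from pydeseq2.ds import DeseqStats

        rng = np.random.default_rng(7)
        G = 300
        mu = rng.lognormal(4, 1, G)
        lfc = np.where(np.arange(G) < 30, 1.5, 0.0)
        K = np.hstack(
            [nb_matrix(rng, mu, 0.05, 3), nb_matrix(rng, mu * 2**lfc, 0.05, 3)]
        )
        counts = frame(K)
        meta = pd.DataFrame({"condition": ["A"] * 3 + ["B"] * 3}, index=counts.columns)
        dds = DeseqDataSet(counts=counts.T, metadata=meta, design="~condition", quiet=True)
        dds.deseq2()
        stat = DeseqStats(dds, contrast=["condition", "B", "A"], quiet=True)
        stat.summary()
        ref = stat.results_df
        mine = d.nb_wald_test(counts, pd.Series(["A"] * 3 + ["B"] * 3, index=counts.columns))
        corr = np.corrcoef(ref["log2FoldChange"], mine["log2fc"])[0, 1]
        assert corr > 0.99
        assert (ref["log2FoldChange"] - mine["log2fc"]).abs().mean() < 0.05


@pytest.fixture(scope="module")
def classified(genome, model):
    cm = d.simulate_counts(
        genome, model, [("diploid_female", 4, 1), ("diploid_male", 4, 1)], seed=33
    )
    cm = prefilter_low_counts(cm)
    res = d.nb_wald_test(
        cm, cm.samples["genotype"], levels=("diploid_male", "diploid_female")
    )
    truth = genome.set_index("gene_id")["sex_bias_truth"]
    return d.classify_sex_bias(res), truth.reindex(res.index)


class TestSexBias:
    def test_biased_genes_recovered(self, classified):
        cls, truth = classified
        assert (cls[truth == "female"] == "female_biased").mean() >= 0.9
        assert (cls[truth == "male"] == "male_biased").mean() >= 0.9

    def test_unbiased_genes_specific(self, classified):
        cls, truth = classified
        assert (cls[truth == "none"] == "non_biased").mean() >= 0.9

    def test_rule_application(self):
        de = pd.DataFrame(
            {"log2fc": [-2.0, 1.0, 0.5], "padj": [0.049, 0.2, np.nan]},
            index=["g0", "g1", "g2"],
        )
        with pytest.warns(UserWarning, match="without padj"):
            cls = d.classify_sex_bias(de)
        assert list(cls) == ["male_biased", "non_biased", "non_biased"]

    def test_partition_exhaustive_exclusive(self, classified):
        cls, _ = classified
        assert set(cls.unique()) <= {"female_biased", "male_biased", "non_biased"}
        assert cls.notna().all()


class TestPPIFilter:
    def test_chain_within_two_edges(self):
        g = nx.Graph([("a", "b"), ("b", "c")])
        sub = d.shortest_path_filter(g, "a", 2)
        assert set(sub) == {"a", "b", "c"}

    def test_disconnected_node_excluded(self):
        g = nx.Graph([("a", "b")])
        g.add_node("island")
        assert "island" not in d.shortest_path_filter(g, "a", 3)

    def test_zero_edges_keeps_seed_alone(self):
        g = nx.Graph([("a", "b")])
        assert set(d.shortest_path_filter(g, "a", 0)) == {"a"}

    def test_missing_seed_rejected(self):
        with pytest.raises(ValueError, match="seed node"):
            d.shortest_path_filter(nx.Graph([("a", "b")]), "z", 2)

    def test_string_dialect_scores_normalized(self, tmp_path):
        path = tmp_path / "edges.tsv"
        path.write_text("msl-2\tmof\t950\nmof\tmsl-1\t400\nmsl-2\tmsl-2\t999\n")
        g = d.read_ppi_tsv(path)
        assert g["msl-2"]["mof"]["combined_score"] == pytest.approx(0.95)
        assert not any(u == v for u, v in g.edges)

    def test_female_vs_male_cutoffs_nest(self):
        """The 2-edge (female) neighborhood is contained in the 3-edge
        (male) neighborhood around the same seed."""
        rng = np.random.default_rng(4)
        g = nx.gnp_random_graph(40, 0.08, seed=2)
        g.add_node(0)
        two = set(d.shortest_path_filter(g, 0, 2))
        three = set(d.shortest_path_filter(g, 0, 3))
        assert two <= three
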