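import itertools

import numpy as np
import pandas as pd
import pytest

from scgenolink.errors import ParameterError
from scgenolink.markers import (
    NormalizationParams,
    combined_top_markers,
    correlate_with_bulk,
    marker_sharing,
    normalize_cells,
    pseudo_bulk,
    rank_correlation,
    rank_score,
    size_factors_median_of_ratios,
    top_markers,
    wilcoxon_markers,
)

from conftest import make_matrix


def exact_ranksum_p(x, y):
    """Enumerate every assignment of the pooled values into two groups of
    the observed sizes; two-sided p is twice the smaller tail (capped at 1)."""
    pooled = np.concatenate([x, y])
    ranks = pd.Series(pooled).rank().to_numpy()
    n1 = len(x)
    obs = ranks[:n1].sum()
    sums = [sum(ranks[list(c)]) for c in itertools.combinations(range(len(pooled)), n1)]
    sums = np.array(sums)
    p_low = np.mean(sums <= obs)
    p_high = np.mean(sums >= obs)
    return min(1.0, 2 * min(p_low, p_high))


def bh_by_hand(pvals):
    """Textbook step-up BH: p_(i) * n / i with cumulative minimum."""
    n = len(pvals)
    order = np.argsort(pvals)
    adj = np.empty(n)
    running = 1.0
    for rank_idx in range(n, 0, -1):
        i = order[rank_idx - 1]
        running = min(running, pvals[i] * n / rank_idx)
        adj[i] = running
    return adj


# ----------------------------------------------------------------------
# normalization


def test_normalize_identity_when_already_at_target():
    m = make_matrix([[2, 2]])
    out = normalize_cells(m, NormalizationParams(4, log_transform=False))
    assert out.tolist() == [[2.0, 2.0]]


def test_normalize_scale_invariance():
    m = make_matrix([[3, 5, 2], [6, 10, 4]])
    out = normalize_cells(m, NormalizationParams(1e6, log_transform=False))
    np.testing.assert_allclose(out[0], out[1])


def test_normalize_matches_per_cell_division():
    rng = np.random.default_rng(0)
    counts = rng.poisson(5, size=(10, 8)) + 1
    m = make_matrix(counts)
    out = normalize_cells(m, NormalizationParams(1e4, log_transform=True, pseudocount=1))
    for i in range(10):
        expected = np.log2(counts[i] / counts[i].sum() * 1e4 + 1)
        np.testing.assert_allclose(out[i], expected)


def test_normalize_rejects_zero_total_cell():
    with pytest.raises(ParameterError):
        normalize_cells(make_matrix([[0, 0], [1, 2]]))


# ----------------------------------------------------------------------
# rank-sum testing


def test_exact_p_for_separated_triplets():
    # group {1,2,3} vs {4,5,6}: 20 assignments, two-sided p = 0.1
    vals = np.array([1, 2, 3, 4, 5, 6])
    counts = np.column_stack([vals, 10 - vals])  # constant totals: CPM keeps order
    m = make_matrix(counts, samples=["a"] * 3 + ["b"] * 3)
    tab = wilcoxon_markers(m, "a")
    assert tab["pval"].iloc[0] == pytest.approx(0.1, abs=1e-12)
    assert exact_ranksum_p([1, 2, 3], [4, 5, 6]) == pytest.approx(0.1)


@pytest.mark.parametrize("seed", range(4))
def test_exact_path_matches_enumeration_with_ties(seed):
    rng = np.random.default_rng(seed)
    n1, n2 = rng.integers(3, 9), rng.integers(3, 9)
    # small integer support forces ties
    counts = rng.integers(0, 4, size=(n1 + n2, 3))
    counts[:, 0] += 1  # avoid zero-total cells
    m = make_matrix(counts, samples=["a"] * n1 + ["b"] * n2)
    params = NormalizationParams(1, log_transform=False)
    tab = wilcoxon_markers(m, "a", params=params)
    cpm = normalize_cells(m, NormalizationParams(1, log_transform=False))
    for j, gene in enumerate(m.gene_ids):
        expected = exact_ranksum_p(cpm[:n1, j], cpm[n1:, j])
        got = tab.set_index("gene").loc[gene, "pval"]
        assert got == pytest.approx(expected, abs=1e-9), gene


def test_identical_groups_give_zero_effect():
    counts = np.tile([[5, 10]], (6, 1))
    m = make_matrix(counts, samples=["a", "b"] * 3)
    tab = wilcoxon_markers(m, "a")
    assert (tab["log2FC"] == 0).all()
    assert (tab["rank_score"] == 0).all()


def test_group_swap_symmetry():
    rng = np.random.default_rng(2)
    counts = rng.poisson(20, size=(30, 5)) + 1
    m = make_matrix(counts, samples=["a"] * 12 + ["b"] * 18)
    ta = wilcoxon_markers(m, "a").set_index("gene")
    tb = wilcoxon_markers(m, "b").set_index("gene")
    np.testing.assert_allclose(ta["pval"], tb["pval"], rtol=1e-12)
    np.testing.assert_allclose(ta["log2FC"], -tb["log2FC"], rtol=1e-9)
    np.testing.assert_allclose(ta["rank_score"], -tb["rank_score"], rtol=1e-9)


def test_missing_group_is_an_error():
    m = make_matrix([[1], [2], [3], [4]], samples=["a", "a", "b", "b"])
    with pytest.raises(ParameterError, match="nope"):
        wilcoxon_markers(m, "nope")


def test_asymptotic_pvalues_match_scanpy():
    import scanpy as sc
    from anndata import AnnData

    rng = np.random.default_rng(4)
    counts = rng.poisson(8, size=(60, 20)) + 1
    m = make_matrix(counts, samples=["a"] * 25 + ["b"] * 35)
    cpm = normalize_cells(m, NormalizationParams(1e6, log_transform=False))
    adata = AnnData(cpm)
    adata.var_names = list(m.gene_ids)
    adata.obs["grp"] = pd.Categorical(m.sample_of.to_numpy())
    sc.tl.rank_genes_groups(
        adata, "grp", groups=["a"], reference="rest", method="wilcoxon", tie_correct=True
    )
    res = adata.uns["rank_genes_groups"]
    sp = pd.Series(np.asarray(res["pvals"]["a"]), index=np.asarray(res["names"]["a"]))
    ours = wilcoxon_markers(m, "a").set_index("gene")["pval"]
    np.testing.assert_allclose(ours.loc[sp.index], sp.to_numpy(), rtol=1e-6)


# ----------------------------------------------------------------------
# BH and rank score


def test_bh_matches_hand_computation():
    rng = np.random.default_rng(6)
    counts = rng.poisson([10, 2, 30], size=(8, 3)) + 1
    m = make_matrix(counts, samples=["a"] * 4 + ["b"] * 4)
    tab = wilcoxon_markers(m, "a")
    np.testing.assert_allclose(tab["padj"], bh_by_hand(tab["pval"].to_numpy()), rtol=1e-12)
    # the printed triple
    np.testing.assert_allclose(
        bh_by_hand(np.array([0.01, 0.02, 0.03])), [0.03, 0.03, 0.03]
    )
    from statsmodels.stats.multitest import multipletests

    np.testing.assert_allclose(
        multipletests([0.01, 0.02, 0.03], method="fdr_bh")[1], [0.03, 0.03, 0.03]
    )


def test_rank_score_values_and_floor():
    assert rank_score(1.0, 3.7) == 0.0
    assert rank_score(0.01, 2.0) == pytest.approx(4.0)
    assert rank_score(0.01, -2.0) == pytest.approx(-4.0)
    assert rank_score(0.0, 1.0) == pytest.approx(300.0)  # floored at 1e-300


# ----------------------------------------------------------------------
# top lists and correlations


def _records(genes, scores, padj=None):
    return pd.DataFrame(
        {
            "gene": genes,
            "rank_score": scores,
            "padj": padj if padj is not None else np.linspace(0.01, 0.5, len(genes)),
        }
    )


def test_top_markers_orders_by_absolute_score():
    rec = _records(["a", "b", "c"], [1.0, -5.0, 3.0])
    assert top_markers(rec, 2) == ["b", "c"]


def test_top_markers_tie_break_lexicographic():
    rec = _records(["z", "a", "m"], [2.0, -2.0, 2.0], padj=[0.5, 0.5, 0.5])
    assert top_markers(rec, 3) == ["a", "m", "z"]


def test_top_markers_matches_full_sort():
    rng = np.random.default_rng(9)
    genes = [f"g{i}" for i in range(500)]
    rec = _records(genes, rng.normal(size=500), padj=rng.uniform(size=500))
    expected = sorted(
        rec.itertuples(), key=lambda r: (-abs(r.rank_score), r.padj, r.gene)
    )
    assert top_markers(rec, 100) == [r.gene for r in expected[:100]]


def test_combined_top_markers_sums_absolute_scores():
    a = _records(["x", "y"], [5.0, 3.0])
    b = _records(["y"], [-3.0])
    assert combined_top_markers(a, b, 1) == ["y"]  # 3+3 beats 5
    same = combined_top_markers(a, a, 2)
    assert same == top_markers(a, 2)


def test_rank_correlation_identity_reversal_and_formula():
    genes = [f"g{i}" for i in range(20)]
    assert rank_correlation(genes, genes) == pytest.approx(1.0)
    assert rank_correlation(genes, genes[::-1]) < 0
    # permuted lists match the closed-form Pearson on ln ranks
    rng = np.random.default_rng(1)
    other = list(rng.permutation(genes))
    r = rank_correlation(genes, other)
    ra = np.log(np.arange(1, 21))
    rb = np.log([other.index(g) + 1 for g in genes])
    expected = np.corrcoef(ra, rb)[0, 1]
    assert r == pytest.approx(expected, abs=1e-12)
    with pytest.raises(ParameterError):
        rank_correlation(["a"], ["a"])


def test_pseudo_bulk_conservation_and_oracle():
    rng = np.random.default_rng(3)
    counts = rng.poisson(4, size=(50, 20))
    m = make_matrix(counts, samples=["a"] * 20 + ["b"] * 30)
    pb = pseudo_bulk(m)
    assert pb.to_numpy().sum() == counts.sum()
    for j, g in enumerate(m.gene_ids):
        assert pb.loc[g, "a"] == counts[:20, j].sum()
        assert pb.loc[g, "b"] == counts[20:, j].sum()


def test_size_factors_hand_example_and_scaling():
    table = pd.DataFrame([[2, 4], [4, 8]], columns=["s1", "s2"])
    f = size_factors_median_of_ratios(table)
    np.testing.assert_allclose(f, [0.70710678, 1.41421356], atol=1e-6)
    # doubling a column doubles its factor relative to the other
    rng = np.random.default_rng(2)
    base = rng.poisson(50, size=100) + 1
    t2 = pd.DataFrame({"a": base, "b": 2 * base})
    f2 = size_factors_median_of_ratios(t2)
    assert f2["b"] / f2["a"] == pytest.approx(2.0)
    single = size_factors_median_of_ratios(pd.DataFrame({"a": base}))
    assert single["a"] == pytest.approx(1.0)


def test_size_factors_require_an_all_nonzero_gene():
    table = pd.DataFrame([[0, 4], [4, 0]], columns=["s1", "s2"])
    with pytest.raises(ParameterError, match="pseudocount"):
        size_factors_median_of_ratios(table)


def test_correlate_with_bulk_perfect_when_bulk_is_pseudobulk():
    rng = np.random.default_rng(8)
    counts = rng.poisson(10, size=(40, 30)) + 1
    m = make_matrix(counts, samples=["a"] * 20 + ["b"] * 20)
    pb = pseudo_bulk(m)
    corr = correlate_with_bulk(pb, pb.copy(), list(m.gene_ids[:20]))
    assert corr.loc["a", "bulk:a"] == pytest.approx(1.0)
    assert corr.loc["b", "bulk:b"] == pytest.approx(1.0)


def test_marker_sharing_matrix():
    lists = {"a": ["g1", "g2", "g3"], "b": ["g2", "g3", "g4"], "c": ["g9"]}
    shared = marker_sharing(lists)
    assert shared.loc["a", "a"] == 3
    assert shared.loc["a", "b"] == shared.loc["b", "a"] == 2
    assert shared.loc["a", "c"] == 0
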