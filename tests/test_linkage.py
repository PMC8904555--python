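import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy import stats

from scgenolink.errors import ConsistencyError, ParameterError
from scgenolink.linkage import (
    assign_mutant_cells,
    average_expression_by_sample,
    de_mutant_vs_nonmutant,
    export_gene_lists,
    mutant_fraction_per_cluster,
    mutation_percentage,
    regulon_regression,
    top_regulon_genes,
)
from scgenolink.markers import NormalizationParams

from conftest import make_matrix


def evidence_frame(rows):
    return pd.DataFrame(rows, columns=["cell_id", "variant_id", "alt_read_count",
                                       "total_read_count"])


# ----------------------------------------------------------------------
# mutant assignment


def test_single_alt_read_makes_a_cell_mutant():
    ev = evidence_frame([("c0", "v", 1, 10), ("c1", "v", 0, 10)])
    status = assign_mutant_cells(ev, "v", pd.Index(["c0", "c1", "c2"]))
    assert status.tolist() == [True, False, False]  # c2 has no evidence row


def test_min_alt_reads_is_configurable():
    ev = evidence_frame([("c0", "v", 2, 10), ("c1", "v", 3, 10)])
    status = assign_mutant_cells(ev, "v", pd.Index(["c0", "c1"]), min_alt_reads=3)
    assert status.tolist() == [False, True]


def test_unknown_evidence_cell_is_inconsistent():
    ev = evidence_frame([("ghost", "v", 1, 5)])
    with pytest.raises(ConsistencyError, match="ghost"):
        assign_mutant_cells(ev, "v", pd.Index(["c0"]))


def test_status_matches_planted_truth(default_dataset):
    ds = default_dataset
    for s, vid in ds.truth.target_variant.items():
        cells = ds.matrix.cells_of(s)
        ev = ds.evidence[ds.evidence["cell_id"].isin(cells)]
        status = assign_mutant_cells(ev, vid, cells)
        pd.testing.assert_series_equal(
            status, ds.truth.mutant_status[s], check_names=False
        )
        # conservation: mutant + non-mutant = all sample cells
        assert status.sum() + (~status).sum() == len(cells)


# ----------------------------------------------------------------------
# mutation percentages and cluster fractions


def test_mutation_percentage_arithmetic():
    cells = [f"c{i}" for i in range(40)]
    sample_of = pd.Series(["s1"] * 40, index=cells)
    status = pd.Series([True] * 10 + [False] * 30, index=cells)
    m = mutation_percentage(status, sample_of)
    assert m["s1"] == pytest.approx(25.0)
    none = mutation_percentage(pd.Series(False, index=cells), sample_of)
    assert none["s1"] == 0.0
    full = mutation_percentage(pd.Series(True, index=cells), sample_of)
    assert full["s1"] == 100.0


def test_mutation_percentage_other_samples_zero():
    cells = ["a0", "a1", "b0", "b1"]
    sample_of = pd.Series(["A", "A", "B", "B"], index=cells)
    status = pd.Series([True, False], index=["a0", "a1"])
    m = mutation_percentage(status, sample_of)
    assert m["A"] == 50.0 and m["B"] == 0.0


def test_mutant_fraction_per_cluster():
    status = pd.Series([True, True, False, False], index=["c0", "c1", "c2", "c3"])
    clusters = pd.Series([1, 1, 1, 2, 2], index=["c0", "c1", "c2", "c3", "other"])
    f = mutant_fraction_per_cluster(status, clusters)
    assert f[1] == pytest.approx(2 / 3)
    assert f[2] == pytest.approx(0.0)
    empty = mutant_fraction_per_cluster(status, pd.Series([3], index=["stranger"]))
    assert np.isnan(empty[3])
    all_mut = mutant_fraction_per_cluster(
        pd.Series(True, index=["c0", "c1"]), pd.Series([1, 1], index=["c0", "c1"])
    )
    assert all_mut[1] == 1.0


# ----------------------------------------------------------------------
# regulon regression


def _samples(n=8):
    return [f"S{i}" for i in range(n)]


def test_noise_free_regression_is_exact():
    s = _samples()
    m = pd.Series([0, 10, 20, 30, 40, 50, 0, 5], index=s, dtype=float)
    g = pd.Series([1, 4, 2, 8, 5, 7, 3, 6], index=s, dtype=float)
    E = pd.DataFrame({"gene_a": 2 + 0.5 * m + 0 * g}).T
    E.columns = s
    fit = regulon_regression(E, m, g).iloc[0]
    assert fit["x"] == pytest.approx(2.0, abs=1e-10)
    assert fit["y"] == pytest.approx(0.5, abs=1e-10)
    assert fit["z"] == pytest.approx(0.0, abs=1e-10)


def test_regression_matches_statsmodels_oracle():
    rng = np.random.default_rng(12)
    s = _samples()
    m = pd.Series(rng.uniform(0, 80, 8), index=s)
    g = pd.Series(rng.uniform(1, 9, 8), index=s)
    E = pd.DataFrame(
        rng.normal(size=(40, 8)) + np.outer(rng.normal(0.8, 0.3, 40), m.to_numpy() / 10),
        columns=s,
        index=[f"g{i}" for i in range(40)],
    )
    fits = regulon_regression(E, m, g).set_index("gene")
    X = sm.add_constant(np.column_stack([m.to_numpy(), g.to_numpy()]))
    for gene in ["g0", "g17", "g39"]:
        res = sm.OLS(E.loc[gene].to_numpy(), X).fit()
        assert fits.loc[gene, "x"] == pytest.approx(res.params[0], rel=1e-8)
        assert fits.loc[gene, "y"] == pytest.approx(res.params[1], rel=1e-8)
        assert fits.loc[gene, "z"] == pytest.approx(res.params[2], rel=1e-8)
        assert fits.loc[gene, "p_y"] == pytest.approx(res.pvalues[1], rel=1e-8)


def test_constant_m_is_unidentifiable():
    s = _samples()
    m = pd.Series(5.0, index=s)
    g = pd.Series(np.arange(8.0), index=s)
    E = pd.DataFrame(np.random.default_rng(0).normal(size=(3, 8)), columns=s,
                     index=list("abc"))
    fits = regulon_regression(E, m, g)
    assert fits["unidentifiable"].all()
    assert fits["y"].isna().all()


def test_too_few_samples_rejected():
    s = _samples(3)
    E = pd.DataFrame(np.ones((2, 3)), columns=s, index=["a", "b"])
    with pytest.raises(ParameterError, match="4 samples"):
        regulon_regression(E, pd.Series(1.0, index=s), pd.Series(1.0, index=s))


def test_null_p_values_are_uniform():
    rng = np.random.default_rng(42)
    s = _samples()
    m = pd.Series([0, 13, 27, 40, 53, 67, 0, 80], index=s, dtype=float)
    g = pd.Series(rng.uniform(2, 6, 8), index=s)
    pvals = []
    for _ in range(20):
        E = pd.DataFrame(rng.normal(size=(60, 8)), columns=s,
                         index=[f"g{i}" for i in range(60)])
        pvals.extend(regulon_regression(E, m, g)["p_y"])
    assert stats.kstest(pvals, "uniform").pvalue > 0.01


def test_planted_regulon_genes_rank_first(default_dataset):
    ds = default_dataset
    E = average_expression_by_sample(ds.matrix)
    m = ds.truth.mutation_pct
    some_patient = [s for s in ds.truth.sample_names if s.startswith("P")][0]
    g = E.loc[ds.truth.target_gene[some_patient]]
    fits = regulon_regression(E, m, g)
    planted = set(ds.truth.regulon_genes["gene"])
    top = top_regulon_genes(fits, len(planted))
    assert set(top) == planted


# ----------------------------------------------------------------------
# mutant-vs-non-mutant DE


def _de_matrix(seed=0, n_per_group=60, fold=4.0, n_genes=30, n_affected=5):
    rng = np.random.default_rng(seed)
    mean = np.full(n_genes, 20.0)
    mut = rng.poisson(np.where(np.arange(n_genes) < n_affected, mean * fold, mean),
                      size=(n_per_group, n_genes))
    non = rng.poisson(mean, size=(n_per_group, n_genes))
    counts = np.vstack([mut, non])
    m = make_matrix(counts)
    status = pd.Series([True] * n_per_group + [False] * n_per_group, index=m.cell_ids)
    return m, status


def test_de_prefilter_boundary_is_inclusive():
    m, status = _de_matrix()
    free = de_mutant_vs_nonmutant(m, status, prefilter=0.0)
    gene = free.loc[free["log2FC"].abs().between(0.05, 1.0).idxmax(), "gene"]
    L = float(free.set_index("gene").loc[gene, "log2FC"])
    at = de_mutant_vs_nonmutant(m, status, prefilter=abs(L)).set_index("gene")
    assert bool(at.loc[gene, "tested"])  # |log2FC| == prefilter -> included
    above = de_mutant_vs_nonmutant(
        m, status, prefilter=np.nextafter(abs(L), np.inf)
    ).set_index("gene")
    assert not bool(above.loc[gene, "tested"])


def test_de_small_fold_changes_excluded_before_testing():
    m, status = _de_matrix()
    de = de_mutant_vs_nonmutant(m, status, prefilter=0.25).set_index("gene")
    small = de[de["log2FC"].abs() < 0.25]
    assert (~small["tested"]).all()
    assert small["pval"].isna().all()
    # BH runs over tested genes only
    tested = de[de["tested"]]
    from statsmodels.stats.multitest import multipletests

    np.testing.assert_allclose(
        tested["padj"], multipletests(tested["pval"], method="fdr_bh")[1]
    )


def test_de_recovers_planted_effects():
    m, status = _de_matrix(n_per_group=100, fold=4.0)
    de = de_mutant_vs_nonmutant(m, status).set_index("gene")
    hits = de[(de["padj"] < 0.05) & (de["log2FC"].abs() >= 1)]
    planted = {f"g{i}" for i in range(5)}
    assert planted <= set(hits.index)
    assert (de.loc[sorted(planted), "direction"] == "up").all()


def test_de_always_include_bypasses_prefilter():
    m, status = _de_matrix()
    de = de_mutant_vs_nonmutant(m, status, prefilter=50.0, always_include=["g20"])
    de = de.set_index("gene")
    assert bool(de.loc["g20", "tested"])
    assert de["tested"].sum() == 1


def test_de_requires_both_groups():
    m, status = _de_matrix()
    with pytest.raises(ParameterError):
        de_mutant_vs_nonmutant(m, pd.Series(True, index=m.cell_ids))


def test_export_gene_lists(tmp_path):
    m, status = _de_matrix(n_per_group=100)
    de = de_mutant_vs_nonmutant(m, status)
    up, down = export_gene_lists(de, tmp_path / "up.txt", tmp_path / "down.txt")
    assert set(up) >= {f"g{i}" for i in range(5)}
    body = (tmp_path / "up.txt").read_text().splitlines()
    assert body[0] == "gene" and body[1:] == up
    sig = de[(de["padj"] < 0.05) & de["tested"]]
    assert set(up) | set(down) == set(sig["gene"])
    empty_up, empty_down = export_gene_lists(
        de, tmp_path / "u2.txt", tmp_path / "d2.txt", padj_cutoff=0.0
    )
    assert empty_up == [] and (tmp_path / "u2.txt").read_text() == "gene\n"
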