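"""Linking genotype to phenotype within cells: mutant-cell assignment,
mutation-fraction ("regulon") regression and mutant-vs-non-mutant DE.

A cell is *mutant* for a target variant when at least one of its reads at
the variant position carries the alternate base (``min_alt_reads`` = 1 by
default); all other cells of the same sample are *non-mutant*.  From the
per-sample mutant percentages m the regulon regression fits, per tested
gene i,

    E_i = x_i + y_i * m + z_i * g

where E_i is the gene's normalized average expression per sample and g is
the normalized average expression of the gene carrying the target variant.
The p-value on y_i (two-sided t-test, n_samples - 3 df) says whether the
gene's expression tracks the mutant fraction; BH correction runs across
all tested genes.  Mutant-vs-non-mutant differential expression reuses the
rank-sum machinery of the markers module, with a |log2FC| >= 0.25
prefilter applied before BH so small expression differences do not dilute
the correction.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import ConsistencyError, ParameterError
from .matrix import CellGeneMatrix
from .markers import NormalizationParams, _ranksum_pvalues, normalize_cells

log = logging.getLogger(__name__)

__all__ = [
    "assign_mutant_cells",
    "mutation_percentage",
    "mutant_fraction_per_cluster",
    "average_expression_by_sample",
    "regulon_regression",
    "top_regulon_genes",
    "de_mutant_vs_nonmutant",
    "export_gene_lists",
]


def assign_mutant_cells(
    evidence: pd.DataFrame,
    variant_id: str,
    sample_cells: pd.Index,
    min_alt_reads: int = 1,
) -> pd.Series:
    """Boolean mutant status for every cell of the variant's sample.

    ``evidence`` holds per-cell allele read counts (columns: cell_id,
    variant_id, alt_read_count, total_read_count).  Cells without an
    evidence row are non-mutant.
    """
    sample_cells = pd.Index(sample_cells)
    ev = evidence[evidence["variant_id"] == variant_id]
    unknown = set(ev["cell_id"]) - set(sample_cells)
    if unknown:
        raise ConsistencyError(
            f"evidence references cells outside the sample: {sorted(unknown)[:5]}"
        )
    alt = ev.set_index("cell_id")["alt_read_count"].reindex(sample_cells, fill_value=0)
    return (alt >= min_alt_reads).rename("mutant")


def mutation_percentage(status: pd.Series, sample_of: pd.Series) -> pd.Series:
    """Percent mutant cells per sample: 100 * mutant / total.

    ``status`` covers the target variant's sample; every other sample in
    ``sample_of`` gets 0 (the variant is sample-specific).
    """
    samples = list(dict.fromkeys(sample_of))
    counts = sample_of.value_counts()
    if (counts.reindex(samples) == 0).any():
        raise ParameterError("empty sample in sample map")
    out = pd.Series(0.0, index=pd.Index(samples, name="sample"), name="mutation_pct")
    sample_of_status = sample_of.reindex(status.index)
    for sample, grp in status.groupby(sample_of_status):
        out[sample] = 100.0 * grp.sum() / counts[sample]
    return out


def mutant_fraction_per_cluster(status: pd.Series, clusters: pd.Series) -> pd.Series:
    """Mutant fraction among the sample's cells in each cluster.

    Clusters containing none of the sample's cells come out as NaN.
    """
    clusters = pd.Series(clusters)
    out = {}
    for cluster in sorted(clusters.unique()):
        cells = clusters.index[clusters == cluster]
        members = status.reindex(cells).dropna()
        out[cluster] = members.mean() if len(members) else np.nan
    return pd.Series(out, name="mutant_fraction")


def average_expression_by_sample(
    matrix: CellGeneMatrix, params: NormalizationParams | None = None
) -> pd.DataFrame:
    """Per-sample mean normalized expression (genes x samples), averaged
    over all QC-passing cells including zero-count ones."""
    norm = normalize_cells(matrix, params)
    out = {}
    for sample in matrix.samples:
        mask = (matrix.sample_of == sample).to_numpy()
        out[sample] = norm[mask, :].mean(axis=0)
    return pd.DataFrame(out, index=matrix.gene_ids)


def regulon_regression(
    expression: pd.DataFrame,
    m: pd.Series,
    g: pd.Series,
    genes: list[str] | None = None,
) -> pd.DataFrame:
    """OLS of per-sample average expression on mutation percentage and the
    mutated gene's expression.

    Parameters
    ----------
    expression
        Genes x samples table of normalized average expression (E).
    m
        Mutation percentage per sample.
    g
        Normalized average expression of the target-variant gene per sample.
    genes
        Genes to test (typically markers in at least one sample); defaults
        to all rows of ``expression``.

    Returns
    -------
    One row per tested gene: x (intercept), y (coefficient on m), z
    (coefficient on g), p_y (two-sided t-test on y, n - 3 df), padj
    (BH across tested genes), and an ``unidentifiable`` flag set when the
    design matrix [1, m, g] is rank-deficient (e.g. constant m, or m and g
    perfectly collinear).
    """
    genes = list(expression.index) if genes is None else [
        gene for gene in genes if gene in expression.index
    ]
    if not genes:
        raise ParameterError("no tested gene present in the expression table")
    samples = expression.columns
    n = len(samples)
    if n < 4:
        raise ParameterError("need at least 4 samples for a 3-parameter fit")
    X = np.column_stack(
        [np.ones(n), m.reindex(samples).to_numpy(), g.reindex(samples).to_numpy()]
    )
    E = expression.loc[genes, samples].to_numpy().T  # samples x genes

    if np.linalg.matrix_rank(X) < 3:
        out = pd.DataFrame(
            {
                "gene": genes,
                "x": np.nan,
                "y": np.nan,
                "z": np.nan,
                "p_y": np.nan,
                "padj": np.nan,
                "unidentifiable": True,
            }
        )
        log.warning("design matrix rank-deficient; all regulon fits unidentifiable")
        return out

    beta, _, _, _ = np.linalg.lstsq(X, E, rcond=None)
    resid = E - X @ beta
    df_resid = n - 3
    sigma2 = (resid**2).sum(axis=0) / df_resid
    xtx_inv = np.linalg.inv(X.T @ X)
    se_y = np.sqrt(np.maximum(sigma2 * xtx_inv[1, 1], 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        t_y = np.where(se_y > 0, beta[1] / se_y, np.inf * np.sign(beta[1]))
    p_y = 2.0 * stats.t.sf(np.abs(t_y), df_resid)
    p_y = np.clip(p_y, 0.0, 1.0)
    padj = multipletests(p_y, method="fdr_bh")[1]
    return pd.DataFrame(
        {
            "gene": genes,
            "x": beta[0],
            "y": beta[1],
            "z": beta[2],
            "p_y": p_y,
            "padj": padj,
            "unidentifiable": False,
        }
    )


def top_regulon_genes(fits: pd.DataFrame, n: int = 30) -> list[str]:
    """Top ``n`` genes by smallest BH-adjusted p on the mutation term."""
    ordered = fits.sort_values(["padj", "p_y", "gene"], kind="mergesort")
    return ordered["gene"].head(n).tolist()


def de_mutant_vs_nonmutant(
    matrix: CellGeneMatrix,
    status: pd.Series,
    prefilter: float = 0.25,
    params: NormalizationParams | None = None,
    always_include: list[str] | None = None,
    exact_max_n: int = 8,
) -> pd.DataFrame:
    """Differential expression between mutant and non-mutant cells of one
    sample.

    log2 fold-changes are computed on normalized means (with pseudocount);
    only genes with |log2FC| >= ``prefilter`` are rank-sum tested, and BH
    runs over the tested genes only — discarding small differences before
    correction keeps the adjustment lenient for real effects.  Genes in
    ``always_include`` (e.g. the gene carrying the target variant) bypass
    the prefilter.

    Returns one row per gene: log2FC, pval, padj, direction ('up'/'down'),
    tested (bool); untested genes carry NaN p-values.
    """
    p = params or NormalizationParams()
    status = status.reindex(matrix.cell_ids).dropna().astype(bool)
    sub = matrix.subset_cells(status.index)
    is_mut = status.to_numpy()
    if is_mut.sum() < 2 or (~is_mut).sum() < 2:
        raise ParameterError("need at least 2 mutant and 2 non-mutant cells")

    cpm = normalize_cells(
        sub, NormalizationParams(p.scale_target, log_transform=False, pseudocount=p.pseudocount)
    )
    mean_mut = cpm[is_mut].mean(axis=0)
    mean_non = cpm[~is_mut].mean(axis=0)
    log2fc = np.log2((mean_mut + p.pseudocount) / (mean_non + p.pseudocount))

    tested = np.abs(log2fc) >= prefilter
    if always_include:
        forced = sub.gene_ids.isin(always_include)
        tested = tested | forced

    pvals = np.full(sub.n_genes, np.nan)
    if tested.any():
        pvals[tested] = _ranksum_pvalues(
            cpm[is_mut][:, tested], cpm[~is_mut][:, tested], exact_max_n
        )
    padj = np.full(sub.n_genes, np.nan)
    if tested.any():
        padj[tested] = multipletests(pvals[tested], method="fdr_bh")[1]

    return pd.DataFrame(
        {
            "gene": sub.gene_ids,
            "log2FC": log2fc,
            "pval": pvals,
            "padj": padj,
            "direction": np.where(log2fc >= 0, "up", "down"),
            "tested": tested,
        }
    ).reset_index(drop=True)


def export_gene_lists(
    de: pd.DataFrame, out_up, out_down, padj_cutoff: float = 0.05
) -> tuple[list[str], list[str]]:
    """Write up- and down-regulated gene lists (one id per line, with a
    header) for external enrichment tools; returns the two lists."""
    sig = de[(de["padj"] < padj_cutoff) & de["tested"]]
    up = sig[sig["direction"] == "up"]["gene"].tolist()
    down = sig[sig["direction"] == "down"]["gene"].tolist()
    for path, genes in ((out_up, up), (out_down, down)):
        with open(path, "w") as fh:
            fh.write("gene\n")
            fh.writelines(f"{g}\n" for g in genes)
    return up, down
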