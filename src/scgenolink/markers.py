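"""Marker-gene detection with a rank score, and single-cell/bulk correlation.

Markers are genes differentially expressed between one group of cells (a
sample or a cluster) and all remaining cells, tested gene-wise with the
two-sided Wilcoxon rank-sum test on normalized expression and corrected
with Benjamini-Hochberg.  Each gene additionally gets a rank score

    rank = -log10(pval) * log2FC

combining significance with effect direction; top-marker lists are ordered
by absolute rank score.  Cross-dataset comparison works on natural-log
ranks of the top markers; comparison with bulk RNA-seq works on per-sample
pseudo-bulk counts normalized by median-of-ratios size factors.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import ParameterError
from .matrix import CellGeneMatrix

log = logging.getLogger(__name__)

__all__ = [
    "NormalizationParams",
    "normalize_cells",
    "wilcoxon_markers",
    "rank_score",
    "top_markers",
    "combined_top_markers",
    "rank_correlation",
    "pseudo_bulk",
    "size_factors_median_of_ratios",
    "correlate_with_bulk",
    "marker_sharing",
]

#: p-values are floored here before log10 so the rank score stays finite.
PVAL_FLOOR = 1e-300


@dataclasses.dataclass
class NormalizationParams:
    """Counts-per-target scaling followed by an optional log2(x + pc)."""

    scale_target: float = 1e6
    log_transform: bool = True
    pseudocount: float = 1.0

    def __post_init__(self) -> None:
        if not self.scale_target > 0:
            raise ParameterError("scale_target must be positive")


def normalize_cells(
    matrix: CellGeneMatrix, params: NormalizationParams | None = None
) -> np.ndarray:
    """Scale each cell to ``scale_target`` total reads (CPM by default),
    then log2(x + pseudocount) when ``log_transform`` is set.
    """
    p = params or NormalizationParams()
    totals = matrix.counts.sum(axis=1, keepdims=True).astype(float)
    if (totals == 0).any():
        raise ParameterError("zero-total cell cannot be normalized (run QC first)")
    scaled = matrix.counts * (p.scale_target / totals)
    if p.log_transform:
        return np.log2(scaled + p.pseudocount)
    return scaled


# ----------------------------------------------------------------------
# rank-sum testing


def _cpm(matrix: CellGeneMatrix, params: NormalizationParams) -> np.ndarray:
    return normalize_cells(
        matrix,
        NormalizationParams(params.scale_target, log_transform=False, pseudocount=params.pseudocount),
    )


def _ranksum_pvalues(x: np.ndarray, y: np.ndarray, exact_max_n: int) -> np.ndarray:
    """Two-sided rank-sum p-values per gene (columns of x and y).

    Uses exact enumeration of group assignments when both groups have at
    most ``exact_max_n`` observations (valid with ties), otherwise the
    tie-corrected normal approximation without continuity correction.
    """
    n1, n2 = x.shape[0], y.shape[0]
    if n1 <= exact_max_n and n2 <= exact_max_n:
        # enumerate all C(n1+n2, n1) assignments; 12870 at worst for 8+8
        method = stats.PermutationMethod(n_resamples=30_000, rng=0)
        out = np.empty(x.shape[1])
        for j in range(x.shape[1]):
            out[j] = stats.mannwhitneyu(
                x[:, j], y[:, j], alternative="two-sided", method=method
            ).pvalue
        return out
    res = stats.mannwhitneyu(
        x, y, alternative="two-sided", method="asymptotic", use_continuity=False, axis=0
    )
    return np.atleast_1d(res.pvalue)


def wilcoxon_markers(
    matrix: CellGeneMatrix,
    group: str,
    labels: pd.Series | None = None,
    params: NormalizationParams | None = None,
    exact_max_n: int = 8,
) -> pd.DataFrame:
    """Test every gene for differential expression, ``group`` vs rest.

    Parameters
    ----------
    matrix
        QC-filtered count matrix.
    group
        Label to contrast against all other cells.
    labels
        Per-cell labels (defaults to the matrix's sample map); pass cluster
        assignments for cluster-vs-rest contrasts.
    params
        Normalization used for ranking and fold-change means.
    exact_max_n
        Exact enumeration when both groups are at most this large.

    Returns
    -------
    DataFrame with columns gene, group, log2FC, pval, padj, rank_score,
    BH-corrected across all tested genes.
    """
    p = params or NormalizationParams()
    labels = matrix.sample_of if labels is None else labels.reindex(matrix.cell_ids)
    in_group = (labels == group).to_numpy()
    if not in_group.any():
        raise ParameterError(f"group '{group}' not present in labels")
    if in_group.sum() < 2 or (~in_group).sum() < 2:
        raise ParameterError("need at least 2 cells in the group and in the rest")

    cpm = _cpm(matrix, p)
    pvals = _ranksum_pvalues(cpm[in_group], cpm[~in_group], exact_max_n)
    mean_g = cpm[in_group].mean(axis=0)
    mean_r = cpm[~in_group].mean(axis=0)
    log2fc = np.log2((mean_g + p.pseudocount) / (mean_r + p.pseudocount))
    padj = multipletests(pvals, method="fdr_bh")[1]
    return pd.DataFrame(
        {
            "gene": matrix.gene_ids,
            "group": group,
            "log2FC": log2fc,
            "pval": pvals,
            "padj": padj,
            "rank_score": rank_score(pvals, log2fc),
        }
    ).reset_index(drop=True)


def rank_score(pval, log2fc, floor: float = PVAL_FLOOR):
    """``-log10(max(pval, floor)) * log2FC``; sign carries direction."""
    pval = np.asarray(pval, dtype=float)
    if (pval <= 0).any():
        log.warning("rank_score received p-values <= 0; flooring at %g", floor)
    floored = np.maximum(pval, floor)
    out = -np.log10(floored) * np.asarray(log2fc, dtype=float)
    return float(out) if out.ndim == 0 else out


def _ordered(records: pd.DataFrame) -> pd.DataFrame:
    df = records.assign(_abs=records["rank_score"].abs())
    return df.sort_values(
        ["_abs", "padj", "gene"], ascending=[False, True, True], kind="mergesort"
    )


def top_markers(records: pd.DataFrame, n: int = 100) -> list[str]:
    """Top ``n`` genes by absolute rank score (ties: padj asc, gene id asc)."""
    if len(records) < n:
        log.info("only %d records available for top-%d request", len(records), n)
    return _ordered(records)["gene"].head(n).tolist()


def combined_top_markers(
    records_a: pd.DataFrame, records_b: pd.DataFrame, n: int = 100
) -> list[str]:
    """Top ``n`` genes by the sum of absolute rank scores from two marker
    tables over the union of their genes (missing gene contributes 0).
    """
    sa = records_a.set_index("gene")["rank_score"].abs()
    sb = records_b.set_index("gene")["rank_score"].abs()
    combined = sa.add(sb, fill_value=0.0).sort_index()
    combined = combined.sort_values(ascending=False, kind="mergesort")
    return combined.head(n).index.tolist()


def rank_correlation(ranked_a: list[str], ranked_b: list[str]) -> float:
    """Pearson correlation of natural-log ranks over the union of two
    ordered top-marker lists.

    A gene missing from one list is assigned rank ``len(list) + 1`` there.
    """
    union = list(dict.fromkeys(list(ranked_a) + list(ranked_b)))
    if len(union) < 3:
        raise ParameterError("need at least 3 genes to correlate ranks")
    pos_a = {g: i + 1 for i, g in enumerate(ranked_a)}
    pos_b = {g: i + 1 for i, g in enumerate(ranked_b)}
    ra = np.log([pos_a.get(g, len(ranked_a) + 1) for g in union])
    rb = np.log([pos_b.get(g, len(ranked_b) + 1) for g in union])
    if ra.std() == 0 or rb.std() == 0:
        raise ParameterError("degenerate (constant) ranks")
    return float(stats.pearsonr(ra, rb).statistic)


# ----------------------------------------------------------------------
# pseudo-bulk and bulk correlation


def pseudo_bulk(matrix: CellGeneMatrix) -> pd.DataFrame:
    """Sum raw counts per gene over each sample's cells (genes x samples)."""
    out = {}
    for sample in matrix.samples:
        mask = (matrix.sample_of == sample).to_numpy()
        out[sample] = matrix.counts[mask, :].sum(axis=0)
    return pd.DataFrame(out, index=matrix.gene_ids)


def size_factors_median_of_ratios(table: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors (the DESeq2 estimator).

    For genes nonzero in every column, the reference is the gene-wise
    geometric mean; each column's factor is the median of its ratios to the
    reference.
    """
    counts = table.to_numpy(dtype=float)
    all_nonzero = (counts > 0).all(axis=1)
    if not all_nonzero.any():
        raise ParameterError(
            "no gene is nonzero in every column; add a pseudocount before "
            "computing size factors"
        )
    sub = counts[all_nonzero]
    log_geo_mean = np.log(sub).mean(axis=1, keepdims=True)
    factors = np.exp(np.median(np.log(sub) - log_geo_mean, axis=0))
    return pd.Series(factors, index=table.columns, name="size_factor")


def normalize_by_size_factors(table: pd.DataFrame) -> pd.DataFrame:
    return table / size_factors_median_of_ratios(table)


def correlate_with_bulk(
    pseudo: pd.DataFrame, bulk: pd.DataFrame, markers: list[str]
) -> pd.DataFrame:
    """Pearson correlations between all dataset columns on a marker panel.

    The pseudo-bulk and bulk tables are combined on shared genes, jointly
    normalized with median-of-ratios size factors, restricted to the marker
    list, then correlated pairwise (pseudo-bulk columns keep their names,
    bulk columns get a ``bulk:`` prefix).
    """
    shared = pseudo.index.intersection(bulk.index)
    combined = pd.concat(
        [pseudo.loc[shared], bulk.loc[shared].add_prefix("bulk:")], axis=1
    )
    normalized = normalize_by_size_factors(combined)
    present = [g for g in markers if g in normalized.index]
    dropped = len(markers) - len(present)
    if dropped:
        log.info("dropped %d markers absent from the combined table", dropped)
    if len(present) < 3:
        raise ParameterError("fewer than 3 markers available for correlation")
    return normalized.loc[present].corr(method="pearson")


def marker_sharing(top_lists: dict[str, list[str]]) -> pd.DataFrame:
    """Symmetric matrix of pairwise shared-marker counts between samples."""
    samples = list(top_lists)
    out = pd.DataFrame(0, index=samples, columns=samples, dtype=int)
    for i, a in enumerate(samples):
        for b in samples[i:]:
            shared = len(set(top_lists[a]) & set(top_lists[b]))
            out.loc[a, b] = out.loc[b, a] = shared
    return out
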