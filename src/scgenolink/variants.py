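"""Variant tables from per-sample VCFs: depth filtering, bulk corroboration,
sample specificity and target-variant selection.

Expressed-variant calls from full-length scRNA-seq carry many false
positives at low read support, so single-cell records are kept only with
variant depth > 4 (reads containing the variant base) and total depth > 7
(all reads at the position), and must be corroborated by a bulk record from
the same sample passing variant depth > 6 and total depth > 10 — all
strict inequalities.  A variant is sample-specific when it passes every
filter in exactly one patient sample and passes the single-cell depth
filter in no other sample.  The per-sample target variant is the
non-synonymous specific variant with the largest variant depth.

Variants are identified by ``chrom:pos:ref>alt``; genotype is carried as
metadata and ignored for cross-sample matching.  Functional consequence
(synonymous / non-synonymous) and dbSNP ids come from an annotation table,
never computed here.
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import FormatError, ParameterError

log = logging.getLogger(__name__)

__all__ = [
    "DepthFilterParams",
    "VARIANT_COLUMNS",
    "variant_key",
    "read_vcf",
    "read_and_merge_vcfs",
    "annotate_variants",
    "depth_quartiles",
    "filter_by_depth",
    "corroborate_with_bulk",
    "sample_specific_variants",
    "select_target_variant",
]

VARIANT_COLUMNS = [
    "chrom",
    "pos",
    "ref",
    "alt",
    "genotype",
    "variant_depth",
    "total_depth",
    "sample",
    "origin",
]


@dataclasses.dataclass
class DepthFilterParams:
    """Strict lower bounds on read support, per origin."""

    sc_variant_depth_gt: int = 4
    sc_total_depth_gt: int = 7
    bulk_variant_depth_gt: int = 6
    bulk_total_depth_gt: int = 10

    def __post_init__(self) -> None:
        for f in dataclasses.fields(self):
            if getattr(self, f.name) < 0:
                raise ParameterError(f"{f.name} must be non-negative")


def variant_key(chrom, pos, ref, alt) -> str:
    return f"{chrom}:{pos}:{ref}>{alt}"


def read_vcf(path, sample: str, origin: str) -> pd.DataFrame:
    """Read one single-sample VCF into a long variant table.

    Depth comes from the per-sample ``AD`` (allele depth) and ``DP`` (total
    depth) FORMAT fields; multi-allelic records are split into one row per
    alternate allele, each with its own allele depth.
    """
    from cyvcf2 import VCF

    if origin not in ("single_cell", "bulk"):
        raise ParameterError(f"origin must be single_cell or bulk, got {origin!r}")
    rows = []
    try:
        vcf = VCF(str(path))
    except Exception as exc:
        raise FormatError(f"cannot open VCF {path}: {exc}") from exc
    for record in vcf:
        ad = record.format("AD")
        dp = record.format("DP")
        if ad is None or dp is None:
            raise FormatError(
                f"{path}: record {record.CHROM}:{record.POS} lacks AD/DP depth fields"
            )
        gts = record.genotypes[0]
        sep = "|" if gts[-1] else "/"
        genotype = sep.join(str(a) for a in gts[:-1])
        for i, alt in enumerate(record.ALT):
            rows.append(
                {
                    "chrom": record.CHROM,
                    "pos": int(record.POS),
                    "ref": record.REF,
                    "alt": alt,
                    "genotype": genotype,
                    "variant_depth": int(ad[0][i + 1]),
                    "total_depth": int(np.asarray(dp).ravel()[0]),
                    "sample": sample,
                    "origin": origin,
                }
            )
    df = pd.DataFrame(rows, columns=VARIANT_COLUMNS)
    df["variant_id"] = [
        variant_key(c, p, r, a)
        for c, p, r, a in zip(df["chrom"], df["pos"], df["ref"], df["alt"])
    ]
    return df


def read_and_merge_vcfs(paths: dict[str, str | Path], origin: str) -> pd.DataFrame:
    """Merge per-sample VCFs (``sample -> path``) into one long table.

    The result is sorted by (chrom, pos, ref, alt, sample) so the merge is
    independent of input-file order.
    """
    tables = [read_vcf(path, sample, origin) for sample, path in paths.items()]
    merged = pd.concat(tables, ignore_index=True) if tables else pd.DataFrame(
        columns=VARIANT_COLUMNS + ["variant_id"]
    )
    return merged.sort_values(
        ["chrom", "pos", "ref", "alt", "sample"], kind="mergesort"
    ).reset_index(drop=True)


def annotate_variants(table: pd.DataFrame, annotation: pd.DataFrame) -> pd.DataFrame:
    """Attach ``is_nonsynonymous`` and ``dbsnp_id`` from an annotation table
    keyed by ``variant_id`` (columns: variant_id, consequence[, dbsnp_id]).
    Unannotated variants are treated as synonymous.
    """
    ann = annotation.set_index("variant_id")
    out = table.copy()
    cons = ann["consequence"].reindex(out["variant_id"]).to_numpy()
    out["is_nonsynonymous"] = pd.Series(cons).isin(
        ["missense", "nonsynonymous", "non_synonymous", "stop_gained"]
    ).to_numpy()
    if "dbsnp_id" in ann.columns:
        out["dbsnp_id"] = ann["dbsnp_id"].reindex(out["variant_id"]).to_numpy()
    return out


def depth_quartiles(table: pd.DataFrame) -> pd.DataFrame:
    """Q1/Q2/Q3 of variant and total depth per sample (and origin).

    Quantiles use linear interpolation between order statistics.  This is
    exploratory output for choosing depth cutoffs by inspection; the depth
    filters themselves take fixed thresholds.
    """
    rows = []
    for (sample, origin), grp in table.groupby(["sample", "origin"], sort=True):
        for depth_type in ("variant_depth", "total_depth"):
            q1, q2, q3 = np.quantile(grp[depth_type].to_numpy(), [0.25, 0.5, 0.75])
            rows.append(
                {
                    "sample": sample,
                    "origin": origin,
                    "depth_type": depth_type,
                    "q1": q1,
                    "q2": q2,
                    "q3": q3,
                }
            )
    return pd.DataFrame(rows)


def filter_by_depth(
    table: pd.DataFrame, params: DepthFilterParams | None = None
) -> pd.DataFrame:
    """Keep rows exceeding the origin-specific depth thresholds (strict >)."""
    p = params or DepthFilterParams()
    sc = table["origin"] == "single_cell"
    keep_sc = (
        sc
        & (table["variant_depth"] > p.sc_variant_depth_gt)
        & (table["total_depth"] > p.sc_total_depth_gt)
    )
    keep_bulk = (
        ~sc
        & (table["variant_depth"] > p.bulk_variant_depth_gt)
        & (table["total_depth"] > p.bulk_total_depth_gt)
    )
    return table[keep_sc | keep_bulk].reset_index(drop=True)


def corroborate_with_bulk(
    sc_filtered: pd.DataFrame, bulk_filtered: pd.DataFrame
) -> pd.DataFrame:
    """Keep single-cell rows whose (variant, sample) has a passing bulk row."""
    bulk_keys = set(zip(bulk_filtered["variant_id"], bulk_filtered["sample"]))
    keep = [
        (v, s) in bulk_keys
        for v, s in zip(sc_filtered["variant_id"], sc_filtered["sample"])
    ]
    return sc_filtered[keep].reset_index(drop=True)


def sample_specific_variants(
    corroborated: pd.DataFrame,
    sc_filtered: pd.DataFrame,
    control_samples: list[str] | tuple[str, ...] = (),
    max_other_samples: int = 0,
) -> dict[str, pd.DataFrame]:
    """Per-sample lists of sample-specific variants.

    A variant is specific to patient sample ``s`` when it is corroborated in
    ``s`` and passes the single-cell depth filter in at most
    ``max_other_samples`` other samples (default 0: strictly nowhere else).
    Control samples never receive specific variants.
    """
    passing_samples = sc_filtered.groupby("variant_id")["sample"].agg(set)
    out: dict[str, pd.DataFrame] = {}
    for sample, grp in corroborated.groupby("sample"):
        if sample in control_samples:
            continue
        rows = []
        for _, row in grp.iterrows():
            others = passing_samples.get(row["variant_id"], set()) - {sample}
            if len(others) <= max_other_samples:
                rows.append(row)
        if rows:
            out[sample] = pd.DataFrame(rows).reset_index(drop=True)
    return out


def select_target_variant(candidates: pd.DataFrame) -> pd.Series:
    """Pick the target variant: maximum variant depth among non-synonymous
    candidates; ties broken by total depth (desc) then chrom/pos (asc).
    """
    if "is_nonsynonymous" not in candidates.columns:
        raise ParameterError("candidates must carry an is_nonsynonymous flag")
    nonsyn = candidates[candidates["is_nonsynonymous"].astype(bool)]
    if nonsyn.empty:
        raise ParameterError(
            "no non-synonymous candidate variant; manual review required"
        )
    ordered = nonsyn.sort_values(
        ["variant_depth", "total_depth", "chrom", "pos"],
        ascending=[False, False, True, True],
        kind="mergesort",
    )
    return ordered.iloc[0]
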