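"""End-to-end orchestration of the analysis stages with one config and seed.

Stage order follows the analysis workflow: simulate (or point the config
at real inputs laid out the same way), qc, markers, cluster, variants,
link.  Each stage reads only files written by its prerequisites, writes
TSV outputs plus a JSON manifest (parameters, seed, input checksums,
package version — no timestamps, so reruns are byte-comparable), and
fails with an actionable error naming the missing prerequisite stage when
run out of order.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cluster import cluster_marker_heatmap, graph_cluster, pca_with_elbow, tsne_embed
from .errors import DependencyError, ParameterError
from .linkage import (
    assign_mutant_cells,
    average_expression_by_sample,
    de_mutant_vs_nonmutant,
    mutant_fraction_per_cluster,
    mutation_percentage,
    regulon_regression,
    top_regulon_genes,
)
from .markers import (
    NormalizationParams,
    correlate_with_bulk,
    marker_sharing,
    normalize_cells,
    pseudo_bulk,
    top_markers,
    wilcoxon_markers,
)
from .matrix import read_matrix, write_matrix, write_well_list
from .qc import QCThresholds, apply_qc, biotype_composition, qc_summary
from .simulate import SimConfig, simulate_dataset, write_fixture
from .variants import (
    DepthFilterParams,
    annotate_variants,
    corroborate_with_bulk,
    depth_quartiles,
    filter_by_depth,
    read_and_merge_vcfs,
    sample_specific_variants,
    select_target_variant,
)

log = logging.getLogger(__name__)

STAGES = ["simulate", "qc", "markers", "cluster", "variants", "link"]

__all__ = ["PipelineConfig", "run", "STAGES"]


@dataclasses.dataclass
class PipelineConfig:
    """All stage parameters in one structured object.

    Defaults are the pipeline's canonical thresholds: QC 10,000 reads /
    300 genes per cell and 100 reads / 3 cells per gene; single-cell depth
    filters >4 variant / >7 total with bulk corroboration at >6 / >10;
    top-100 marker lists; top-30 heatmap panels; DE prefilter 0.25.
    """

    workdir: str = "pipeline_out"
    seed: int = 0
    control_samples: tuple[str, ...] = ("C1", "C2")
    sim: dict = dataclasses.field(default_factory=dict)
    bulk_noise_sigma: float = 0.3
    qc: QCThresholds = dataclasses.field(default_factory=QCThresholds)
    norm: NormalizationParams = dataclasses.field(default_factory=NormalizationParams)
    depth: DepthFilterParams = dataclasses.field(default_factory=DepthFilterParams)
    max_pcs: int = 30
    elbow_tol: float = 1e-3
    n_neighbors: int = 15
    resolution: float = 1.0
    perplexity: float = 30.0
    top_n_markers: int = 100
    heatmap_top_n: int = 30
    marker_padj_cutoff: float = 0.05
    de_prefilter: float = 0.25
    de_padj_cutoff: float = 0.05
    min_alt_reads: int = 1
    plots: bool = False

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        for key, sub_cls in (("qc", QCThresholds), ("norm", NormalizationParams),
                             ("depth", DepthFilterParams)):
            if key in raw and isinstance(raw[key], dict):
                raw[key] = sub_cls(**raw[key])
        if "control_samples" in raw:
            raw["control_samples"] = tuple(raw["control_samples"])
        unknown = set(raw) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ParameterError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def sim_config(self) -> SimConfig:
        return SimConfig(**{**self.sim, "seed": self.seed})


# ----------------------------------------------------------------------
# helpers


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_manifest(workdir: Path, stage: str, cfg: PipelineConfig, inputs: list[Path]) -> None:
    manifest = {
        "stage": stage,
        "seed": cfg.seed,
        "version": __version__,
        "params": cfg.to_dict(),
        "inputs": {str(p.relative_to(workdir)): _sha256(p) for p in inputs if p.is_file()},
    }
    with open(workdir / f"manifest_{stage}.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)


def _require(path: Path, produced_by: str) -> Path:
    if not path.exists():
        raise DependencyError(
            f"missing {path}; run the '{produced_by}' stage first"
        )
    return path


def _load_filtered(workdir: Path):
    mdir = _require(workdir / "qc" / "matrix", "qc")
    return read_matrix(mdir, well_list=_require(workdir / "qc" / "well_list.tsv", "qc"))


# ----------------------------------------------------------------------
# stages


def stage_simulate(cfg: PipelineConfig) -> None:
    workdir = Path(cfg.workdir)
    dataset = simulate_dataset(cfg.sim_config(), bulk_noise_sigma=cfg.bulk_noise_sigma)
    paths = write_fixture(dataset, workdir / "fixture")
    _write_manifest(workdir, "simulate", cfg, [paths["well_list"], paths["truth"]])


def stage_qc(cfg: PipelineConfig) -> None:
    workdir = Path(cfg.workdir)
    fixture = workdir / "fixture"
    raw = read_matrix(
        _require(fixture / "matrix", "simulate"),
        well_list=_require(fixture / "well_list.tsv", "simulate"),
    )
    filtered = apply_qc(raw, cfg.qc)
    out = workdir / "qc"
    out.mkdir(parents=True, exist_ok=True)
    write_matrix(filtered, out / "matrix")
    write_well_list(filtered.sample_of, out / "well_list.tsv")
    table, genes_per_cell = qc_summary(raw, filtered)
    table.to_csv(out / "qc_summary.tsv", sep="\t")
    genes_per_cell.rename_axis("cell_id").to_csv(out / "genes_per_cell.tsv", sep="\t")
    bio_path = fixture / "gene_biotypes.tsv"
    if bio_path.exists():
        biotypes = pd.read_csv(bio_path, sep="\t").set_index("gene")["biotype"]
        biotype_composition(filtered, biotypes).to_csv(out / "biotype_composition.tsv", sep="\t")
    _write_manifest(workdir, "qc", cfg, [out / "qc_summary.tsv"])


def stage_markers(cfg: PipelineConfig) -> None:
    workdir = Path(cfg.workdir)
    matrix = _load_filtered(workdir)
    out = workdir / "markers"
    out.mkdir(parents=True, exist_ok=True)
    tops = {}
    for sample in matrix.samples:
        table = wilcoxon_markers(matrix, sample, params=cfg.norm)
        table.to_csv(out / f"{sample}.tsv", sep="\t", index=False)
        tops[sample] = top_markers(table, cfg.top_n_markers)
        with open(out / f"{sample}_top{cfg.top_n_markers}.txt", "w") as fh:
            fh.writelines(f"{g}\n" for g in tops[sample])
    marker_sharing(tops).to_csv(out / "marker_sharing.tsv", sep="\t")

    bulk_path = workdir / "fixture" / "bulk_counts.tsv"
    if bulk_path.exists():
        bulk = pd.read_csv(bulk_path, sep="\t", index_col=0)
        pb = pseudo_bulk(matrix)
        rows = {}
        for sample in matrix.samples:
            corr = correlate_with_bulk(pb, bulk, tops[sample])
            rows[sample] = corr.loc[sample, f"bulk:{sample}"]
        pd.Series(rows, name="pearson_r").rename_axis("sample").to_csv(
            out / "bulk_correlation.tsv", sep="\t"
        )
    _write_manifest(workdir, "markers", cfg, [out / "marker_sharing.tsv"])


def stage_cluster(cfg: PipelineConfig) -> None:
    workdir = Path(cfg.workdir)
    matrix = _load_filtered(workdir)
    out = workdir / "cluster"
    out.mkdir(parents=True, exist_ok=True)
    norm = normalize_cells(matrix, cfg.norm)
    scores, evr, k = pca_with_elbow(norm, max_pcs=cfg.max_pcs, tol=cfg.elbow_tol)
    pcs = scores[:, :k]
    pd.DataFrame(
        scores, index=matrix.cell_ids, columns=[f"PC{i+1}" for i in range(scores.shape[1])]
    ).to_csv(out / "pcs.tsv", sep="\t")
    pd.Series(evr, name="explained_variance_ratio").to_csv(out / "scree.tsv", sep="\t")

    labels = graph_cluster(pcs, cfg.n_neighbors, cfg.resolution, cfg.seed)
    clusters = pd.Series(labels, index=matrix.cell_ids, name="cluster")
    clusters.rename_axis("cell_id").to_csv(out / "clusters.tsv", sep="\t")

    coords = tsne_embed(pcs, cfg.perplexity, cfg.seed)
    pd.DataFrame(coords, index=matrix.cell_ids, columns=["tsne1", "tsne2"]).to_csv(
        out / "tsne.tsv", sep="\t"
    )

    heat, panel = cluster_marker_heatmap(matrix, clusters, cfg.heatmap_top_n, cfg.norm)
    heat.to_csv(out / "cluster_marker_rank_scores.tsv", sep="\t")

    if cfg.plots:
        from .plotting import plot_heatmap, plot_tsne

        plot_tsne(coords, matrix.sample_of, out / "tsne_by_sample.png")
        plot_tsne(coords, clusters.astype(str), out / "tsne_by_cluster.png")
        plot_heatmap(heat, out / "cluster_marker_heatmap.png")
    _write_manifest(workdir, "cluster", cfg, [out / "clusters.tsv"])


def stage_variants(cfg: PipelineConfig) -> None:
    workdir = Path(cfg.workdir)
    fixture = workdir / "fixture"
    vcf_dir = _require(fixture / "vcf", "simulate")
    matrix = _load_filtered(workdir)
    samples = matrix.samples
    sc_paths = {s: _require(vcf_dir / f"sc_{s}.vcf", "simulate") for s in samples}
    bulk_paths = {s: _require(vcf_dir / f"bulk_{s}.vcf", "simulate") for s in samples}

    sc = read_and_merge_vcfs(sc_paths, "single_cell")
    bulk = read_and_merge_vcfs(bulk_paths, "bulk")
    annotation = pd.read_csv(
        _require(fixture / "annotation.tsv", "simulate"), sep="\t", keep_default_na=False
    )
    out = workdir / "variants"
    out.mkdir(parents=True, exist_ok=True)
    depth_quartiles(pd.concat([sc, bulk], ignore_index=True)).to_csv(
        out / "depth_quartiles.tsv", sep="\t", index=False
    )
    sc_f = filter_by_depth(sc, cfg.depth)
    bulk_f = filter_by_depth(bulk, cfg.depth)
    corroborated = corroborate_with_bulk(sc_f, bulk_f)
    corroborated.to_csv(out / "corroborated.tsv", sep="\t", index=False)
    specific = sample_specific_variants(corroborated, sc_f, cfg.control_samples)

    targets = []
    for sample, table in sorted(specific.items()):
        annotated = annotate_variants(table, annotation)
        annotated.to_csv(out / f"specific_{sample}.tsv", sep="\t", index=False)
        target = select_target_variant(annotated)
        gene_of = annotation.set_index("variant_id")["gene"]
        targets.append(
            {
                "sample": sample,
                "variant_id": target["variant_id"],
                "chrom": target["chrom"],
                "pos": target["pos"],
                "ref": target["ref"],
                "alt": target["alt"],
                "genotype": target["genotype"],
                "variant_depth": target["variant_depth"],
                "total_depth": target["total_depth"],
                "gene": gene_of.get(target["variant_id"], ""),
                "dbsnp_id": target.get("dbsnp_id", ""),
                "n_specific_variants": len(table),
            }
        )
    pd.DataFrame(targets).to_csv(out / "targets.tsv", sep="\t", index=False)
    _write_manifest(workdir, "variants", cfg, [out / "targets.tsv"])


def stage_link(cfg: PipelineConfig) -> None:
    workdir = Path(cfg.workdir)
    matrix = _load_filtered(workdir)
    targets = pd.read_csv(
        _require(workdir / "variants" / "targets.tsv", "variants"), sep="\t",
        keep_default_na=False,
    )
    evidence = pd.read_csv(_require(workdir / "fixture" / "evidence.tsv", "simulate"), sep="\t")
    clusters_path = workdir / "cluster" / "clusters.tsv"
    clusters = (
        pd.read_csv(clusters_path, sep="\t", index_col=0)["cluster"]
        if clusters_path.exists()
        else None
    )

    # regulon gene universe: markers (padj < cutoff) in at least one sample
    marker_dir = _require(workdir / "markers", "markers")
    universe: set[str] = set()
    for sample in matrix.samples:
        tab = pd.read_csv(_require(marker_dir / f"{sample}.tsv", "markers"), sep="\t")
        universe |= set(tab.loc[tab["padj"] < cfg.marker_padj_cutoff, "gene"])
    if not universe:
        universe = set(matrix.gene_ids)
        log.warning("no significant markers found; regulon tests all genes")

    expression = average_expression_by_sample(matrix, cfg.norm)
    out = workdir / "link"
    out.mkdir(parents=True, exist_ok=True)
    links = []
    for _, target in targets.iterrows():
        sample = target["sample"]
        cells = matrix.cells_of(sample)
        status = assign_mutant_cells(
            evidence[evidence["cell_id"].isin(cells)],
            target["variant_id"],
            cells,
            cfg.min_alt_reads,
        )
        status.rename_axis("cell_id").astype(int).to_csv(
            out / f"status_{sample}.tsv", sep="\t"
        )
        m = mutation_percentage(status, matrix.sample_of)
        if clusters is not None:
            mutant_fraction_per_cluster(status, clusters).rename_axis("cluster").to_csv(
                out / f"mutant_fraction_per_cluster_{sample}.tsv", sep="\t"
            )

        target_gene = target["gene"]
        g = expression.loc[target_gene] if target_gene in expression.index else None
        n_regulon_sig = 0
        if g is not None:
            fits = regulon_regression(expression, m, g, sorted(universe))
            fits.to_csv(out / f"regulon_{sample}.tsv", sep="\t", index=False)
            top30 = top_regulon_genes(fits, 30)
            with open(out / f"regulon_{sample}_top30.txt", "w") as fh:
                fh.writelines(f"{gname}\n" for gname in top30)
            n_regulon_sig = int((fits["padj"] < cfg.de_padj_cutoff).sum())
        else:
            log.warning("target gene %r not in expression table; regulon skipped", target_gene)

        de = de_mutant_vs_nonmutant(
            matrix.subset_cells(cells),
            status,
            prefilter=cfg.de_prefilter,
            params=cfg.norm,
            always_include=[target_gene] if target_gene else None,
        )
        de.to_csv(out / f"de_{sample}.tsv", sep="\t", index=False)
        n_de_sig = int(((de["padj"] < cfg.de_padj_cutoff) & de["tested"]).sum())

        links.append(
            {
                "sample": sample,
                "variant_id": target["variant_id"],
                "gene": target_gene,
                "mutation_pct": m[sample],
                "n_regulon_significant": n_regulon_sig,
                "n_de_significant": n_de_sig,
            }
        )
    pd.DataFrame(links).to_csv(out / "links.tsv", sep="\t", index=False)
    _write_manifest(workdir, "link", cfg, [out / "links.tsv"])


_STAGE_FN = {
    "simulate": stage_simulate,
    "qc": stage_qc,
    "markers": stage_markers,
    "cluster": stage_cluster,
    "variants": stage_variants,
    "link": stage_link,
}


def run(stage: str, cfg: PipelineConfig) -> None:
    """Run one stage, or all of them in order (``stage='all'``)."""
    Path(cfg.workdir).mkdir(parents=True, exist_ok=True)
    log.info(
        "thresholds: qc=%s depth=%s top_n=%d heatmap_n=%d de_prefilter=%g seed=%d",
        cfg.qc, cfg.depth, cfg.top_n_markers, cfg.heatmap_top_n, cfg.de_prefilter, cfg.seed,
    )
    if stage == "all":
        for s in STAGES:
            log.info("stage %s", s)
            _STAGE_FN[s](cfg)
        return
    if stage not in _STAGE_FN:
        raise ParameterError(f"unknown stage {stage!r}; choose from {STAGES + ['all']}")
    _STAGE_FN[stage](cfg)
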