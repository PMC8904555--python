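"""Synthetic joint expression + variant datasets with known ground truth.

The generator emulates the study design the pipeline targets: 8 dermal-
fibroblast-like samples (6 patients, 2 controls) on one chip, a few
hundred cells each, full-length read counts (negative binomial with a
shared dispersion, log-normal library sizes), sample-specific marker
genes, one planted sample-specific non-synonymous variant per patient
(plus decoy variants present in every sample), per-cell allele evidence at
each target variant, and a matched bulk count table.  Every planted signal
is recorded in a :class:`SimTruth` manifest so downstream stages can be
scored against ground truth.

Cell-level structure: each patient sample has a planted mutant-cell
subset whose size grows across patients (evenly spaced fractions up to
``mutant_cell_fraction``), giving the regulon regression a design with
variance in the mutation percentage m.  Regulon genes shift their mean by
``2**(coef * m_s)`` per sample; DE genes shift by ``2**de_log2fc`` in
mutant cells only.  Non-mutant cells carry alternate reads at rate
``error_rate`` (0 by default, keeping mutant ground truth unambiguous).
"""

from __future__ import annotations

import dataclasses
import json
import math
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ParameterError
from .matrix import CellGeneMatrix, write_matrix, write_well_list
from .variants import variant_key

__all__ = [
    "SimConfig",
    "SimTruth",
    "SimulatedDataset",
    "simulate_counts",
    "simulate_variants",
    "simulate_bulk",
    "simulate_dataset",
    "write_fixture",
]

_BASES = ["A", "C", "G", "T"]
_BIOTYPES = ["protein_coding", "lincRNA", "miRNA", "pseudogene"]
_BIOTYPE_PROBS = [0.65, 0.20, 0.05, 0.10]


@dataclasses.dataclass
class SimConfig:
    """Generator parameters; defaults are the package's study conditions."""

    n_samples: int = 8
    n_controls: int = 2
    cells_per_sample: int = 200
    n_genes: int = 800
    nb_mean_log_mu: float = 3.0  # log-scale mean of per-gene baseline counts
    nb_mean_log_sigma: float = 1.0
    nb_dispersion: float = 0.5  # var = mu + dispersion * mu^2
    libsize_sigma: float = 0.2
    n_markers_per_sample: int = 20
    marker_log2fc: float = 2.0
    n_specific_variants: int = 1
    n_decoy_variants: int = 10
    coverage_mean: float = 20.0
    mutant_cell_fraction: float = 0.8  # maximum across patients
    alt_read_prob: float = 0.9
    n_regulon_genes: int = 10
    regulon_coef: float = 0.02  # log2 units per percentage point of m
    n_de_genes: int = 10
    de_log2fc: float = 2.0
    error_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            if isinstance(v, float) and not math.isfinite(v):
                raise ParameterError(f"{f.name} must be finite")
        if self.n_controls != 2:
            raise ParameterError("the design flags exactly 2 control samples")
        if self.n_samples <= self.n_controls:
            raise ParameterError("need at least one patient sample")
        for name in ("cells_per_sample", "n_genes"):
            if getattr(self, name) <= 0:
                raise ParameterError(f"{name} must be positive")
        if not self.nb_dispersion > 0:
            raise ParameterError("nb_dispersion must be > 0")
        if self.libsize_sigma < 0:
            raise ParameterError("libsize_sigma must be >= 0")
        for name in ("mutant_cell_fraction", "alt_read_prob"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ParameterError(f"{name} must be in (0, 1]")
        if not 0 <= self.error_rate < 1:
            raise ParameterError("error_rate must be in [0, 1)")
        if self.coverage_mean <= 0:
            raise ParameterError("coverage_mean must be positive")

    @property
    def patient_samples(self) -> list[str]:
        return [f"P{i + 1}" for i in range(self.n_samples - self.n_controls)]

    @property
    def control_samples(self) -> list[str]:
        return [f"C{i + 1}" for i in range(self.n_controls)]

    @property
    def sample_names(self) -> list[str]:
        return self.patient_samples + self.control_samples


@dataclasses.dataclass
class SimTruth:
    """Ground-truth manifest for a simulated dataset."""

    sample_names: list[str]
    control_samples: list[str]
    marker_genes: dict[str, list[str]]  # sample -> planted marker genes
    size_factors: pd.Series  # per-cell planted library-size factor
    mutant_status: dict[str, pd.Series]  # sample -> per-cell bool
    mutation_pct: pd.Series  # per-sample planted m (percent)
    regulon_genes: pd.DataFrame  # columns gene, coef (log2 per % mutant)
    de_genes: dict[str, list[str]]  # sample -> mutant-upregulated genes
    biotype_of: pd.Series  # gene -> RNA biotype
    specific_variants: pd.DataFrame = None  # filled by simulate_variants
    decoy_variants: list[str] = dataclasses.field(default_factory=list)
    target_variant: dict[str, str] = dataclasses.field(default_factory=dict)
    target_gene: dict[str, str] = dataclasses.field(default_factory=dict)


# ----------------------------------------------------------------------


def _negative_binomial(rng: np.random.Generator, mean: np.ndarray, dispersion: float):
    size = 1.0 / dispersion
    p = size / (size + mean)
    return rng.negative_binomial(size, p)


def simulate_counts(config: SimConfig) -> tuple[CellGeneMatrix, SimTruth]:
    """Draw the cell x gene count matrix and record its ground truth."""
    rng = np.random.default_rng(config.seed)
    samples = config.sample_names
    patients = config.patient_samples
    n_cells = config.cells_per_sample * len(samples)

    width = len(str(config.n_genes))
    gene_ids = pd.Index([f"G{i + 1:0{width}d}" for i in range(config.n_genes)])
    cell_ids, sample_labels = [], []
    for s in samples:
        for c in range(config.cells_per_sample):
            cell_ids.append(f"{s}_c{c + 1:04d}")
            sample_labels.append(s)
    cell_ids = pd.Index(cell_ids)
    sample_of = pd.Series(sample_labels, index=cell_ids)

    # disjoint planted gene sets drawn from a shuffled pool
    needed = (
        len(samples) * config.n_markers_per_sample
        + config.n_regulon_genes
        + len(patients) * config.n_de_genes
        + len(patients)  # target-variant genes
    )
    if needed > config.n_genes:
        raise ParameterError(
            f"n_genes={config.n_genes} too small for the planted gene sets ({needed})"
        )
    pool = list(rng.permutation(config.n_genes))
    take = lambda k: [gene_ids[pool.pop()] for _ in range(k)]
    marker_genes = {s: sorted(take(config.n_markers_per_sample)) for s in samples}
    regulon = take(config.n_regulon_genes)
    regulon_coefs = np.array(
        [config.regulon_coef * (1 if i % 2 == 0 else -1) for i in range(len(regulon))]
    )
    de_genes = {s: sorted(take(config.n_de_genes)) for s in patients}
    target_gene = {s: take(1)[0] for s in patients}

    # planted mutant cells: evenly spaced fractions across patients
    mutant_status: dict[str, pd.Series] = {}
    mutation_pct = pd.Series(0.0, index=pd.Index(samples, name="sample"))
    for i, s in enumerate(patients):
        frac = config.mutant_cell_fraction * (i + 1) / len(patients)
        cells = cell_ids[(sample_of == s).to_numpy()]
        n_mut = int(round(frac * len(cells)))
        chosen = rng.choice(len(cells), size=n_mut, replace=False)
        status = pd.Series(False, index=cells, name="mutant")
        status.iloc[chosen] = True
        mutant_status[s] = status
        mutation_pct[s] = 100.0 * n_mut / len(cells)

    # expected means: baseline x library size x planted multipliers
    base_mu = rng.lognormal(config.nb_mean_log_mu, config.nb_mean_log_sigma, config.n_genes)
    size_factors = pd.Series(
        rng.lognormal(0.0, config.libsize_sigma, n_cells), index=cell_ids, name="size_factor"
    )
    mean = np.outer(size_factors.to_numpy(), base_mu)

    gene_pos = {g: j for j, g in enumerate(gene_ids)}
    for s in samples:
        rows = (sample_of == s).to_numpy()
        cols = [gene_pos[g] for g in marker_genes[s]]
        mean[np.ix_(rows, cols)] *= 2.0 ** config.marker_log2fc
        m_s = mutation_pct[s]
        if m_s and len(regulon):
            cols = [gene_pos[g] for g in regulon]
            mean[np.ix_(rows, cols)] *= 2.0 ** (regulon_coefs * m_s)
    for s in patients:
        mut_cells = mutant_status[s].index[mutant_status[s].to_numpy()]
        rows = cell_ids.get_indexer(mut_cells)
        cols = [gene_pos[g] for g in de_genes[s]]
        if len(rows) and len(cols):
            mean[np.ix_(rows, cols)] *= 2.0 ** config.de_log2fc

    counts = _negative_binomial(rng, mean, config.nb_dispersion)
    matrix = CellGeneMatrix(counts, cell_ids, gene_ids, sample_of)

    biotype_of = pd.Series(
        rng.choice(_BIOTYPES, size=config.n_genes, p=_BIOTYPE_PROBS),
        index=gene_ids,
        name="biotype",
    )
    truth = SimTruth(
        sample_names=samples,
        control_samples=config.control_samples,
        marker_genes=marker_genes,
        size_factors=size_factors,
        mutant_status=mutant_status,
        mutation_pct=mutation_pct,
        regulon_genes=pd.DataFrame({"gene": regulon, "coef": regulon_coefs}),
        de_genes=de_genes,
        biotype_of=biotype_of,
        target_gene=target_gene,
    )
    return matrix, truth


# ----------------------------------------------------------------------


def simulate_variants(
    config: SimConfig,
    truth: SimTruth,
    patient_samples: list[str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Draw per-sample variant tables, per-cell allele evidence and the
    variant annotation table.

    Returns ``(sc_table, bulk_table, evidence, annotation)``; the variant
    tables are long (one row per variant per sample) and split by sample at
    write time.  Sample-specific variants are drawn so they pass the
    single-cell (>4 variant / >7 total) and bulk (>6 / >10) depth filters
    in their own sample and appear nowhere else; decoys appear, passing, in
    every sample.  The per-patient target variant is flagged non-synonymous
    and given the maximal variant depth in its sample.
    """
    patients = patient_samples or [
        s for s in truth.sample_names if s not in truth.control_samples
    ]
    bad = set(patients) & set(truth.control_samples)
    if bad:
        raise ParameterError(f"control samples cannot carry specific variants: {sorted(bad)}")
    rng = np.random.default_rng(config.seed + 1)
    samples = truth.sample_names

    def draw_alleles():
        ref = rng.choice(_BASES)
        alt = rng.choice([b for b in _BASES if b != ref])
        return ref, alt

    spec_rows, sc_rows, bulk_rows, ann_rows = [], [], [], []
    pos_counter = 10_000
    for s in patients:
        sample_variants = []
        for k in range(config.n_specific_variants):
            ref, alt = draw_alleles()
            pos = pos_counter
            pos_counter += 101
            vid = variant_key("1", pos, ref, alt)
            vd = int(5 + rng.poisson(8))
            sample_variants.append(
                {"chrom": "1", "pos": pos, "ref": ref, "alt": alt, "variant_id": vid,
                 "variant_depth": vd, "sample": s}
            )
        # target: max variant depth and non-synonymous
        target = max(sample_variants, key=lambda r: r["variant_depth"])
        target["variant_depth"] = max(r["variant_depth"] for r in sample_variants) + 5
        truth.target_variant[s] = target["variant_id"]
        for rec in sample_variants:
            is_target = rec["variant_id"] == target["variant_id"]
            gt = str(rng.choice(["0/1", "1/1"]))
            vd = rec["variant_depth"]
            td = vd + 3 + int(rng.poisson(5))
            sc_rows.append(
                dict(rec, genotype=gt, variant_depth=vd, total_depth=td, origin="single_cell")
            )
            bvd = int(7 + rng.poisson(10))
            bulk_rows.append(
                dict(rec, genotype=gt, variant_depth=bvd,
                     total_depth=bvd + 4 + int(rng.poisson(5)), origin="bulk")
            )
            ann_rows.append(
                {
                    "variant_id": rec["variant_id"],
                    "gene": truth.target_gene[s] if is_target else "",
                    "consequence": "missense" if is_target else "synonymous",
                    "dbsnp_id": f"rs{900000 + len(ann_rows)}" if is_target else "",
                }
            )
            spec_rows.append(dict(rec, is_target=is_target))

    decoys = []
    for d in range(config.n_decoy_variants):
        ref, alt = draw_alleles()
        pos = 1_000_000 + 101 * d
        vid = variant_key("1", pos, ref, alt)
        decoys.append(vid)
        gt = str(rng.choice(["0/1", "1/1"]))
        for s in samples:
            vd = int(5 + rng.poisson(5))
            sc_rows.append(
                {"chrom": "1", "pos": pos, "ref": ref, "alt": alt, "variant_id": vid,
                 "genotype": gt, "variant_depth": vd,
                 "total_depth": vd + 3 + int(rng.poisson(5)),
                 "sample": s, "origin": "single_cell"}
            )
            bvd = int(7 + rng.poisson(10))
            bulk_rows.append(
                {"chrom": "1", "pos": pos, "ref": ref, "alt": alt, "variant_id": vid,
                 "genotype": gt, "variant_depth": bvd,
                 "total_depth": bvd + 4 + int(rng.poisson(5)),
                 "sample": s, "origin": "bulk"}
            )
        ann_rows.append(
            {"variant_id": vid, "gene": "", "consequence": "synonymous", "dbsnp_id": ""}
        )

    # per-cell allele evidence at each target variant
    ev_rows = []
    for s in patients:
        vid = truth.target_variant[s]
        status = truth.mutant_status[s]
        for cell, is_mut in status.items():
            total = int(rng.poisson(config.coverage_mean))
            p_alt = config.alt_read_prob if is_mut else config.error_rate
            alt_reads = int(rng.binomial(total, p_alt)) if total else 0
            ev_rows.append(
                {"cell_id": cell, "variant_id": vid,
                 "alt_read_count": alt_reads, "total_read_count": total}
            )

    truth.specific_variants = pd.DataFrame(spec_rows)
    truth.decoy_variants = decoys
    cols = ["chrom", "pos", "ref", "alt", "genotype", "variant_depth",
            "total_depth", "sample", "origin", "variant_id"]
    sc_table = pd.DataFrame(sc_rows)[cols]
    bulk_table = pd.DataFrame(bulk_rows)[cols]
    evidence = pd.DataFrame(ev_rows)
    annotation = pd.DataFrame(ann_rows)
    return sc_table, bulk_table, evidence, annotation


def simulate_bulk(
    matrix: CellGeneMatrix, noise_sigma: float, seed: int = 0
) -> pd.DataFrame:
    """Bulk counts: per-sample pseudo-bulk with multiplicative log-normal
    noise (``noise_sigma = 0`` reproduces the pseudo-bulk exactly)."""
    from .markers import pseudo_bulk

    if noise_sigma < 0:
        raise ParameterError("noise_sigma must be >= 0")
    pb = pseudo_bulk(matrix)
    if noise_sigma == 0:
        return pb
    rng = np.random.default_rng(seed)
    noisy = pb.to_numpy() * rng.lognormal(0.0, noise_sigma, pb.shape)
    return pd.DataFrame(np.rint(noisy).astype(np.int64), index=pb.index, columns=pb.columns)


# ----------------------------------------------------------------------


@dataclasses.dataclass
class SimulatedDataset:
    config: SimConfig
    matrix: CellGeneMatrix
    truth: SimTruth
    sc_variants: pd.DataFrame
    bulk_variants: pd.DataFrame
    evidence: pd.DataFrame
    annotation: pd.DataFrame
    bulk_counts: pd.DataFrame


def simulate_dataset(config: SimConfig, bulk_noise_sigma: float = 0.3) -> SimulatedDataset:
    """All generator stages in order, sharing the config's seed."""
    matrix, truth = simulate_counts(config)
    sc, bulk, evidence, annotation = simulate_variants(config, truth)
    bulk_counts = simulate_bulk(matrix, bulk_noise_sigma, seed=config.seed + 2)
    return SimulatedDataset(config, matrix, truth, sc, bulk, evidence, annotation, bulk_counts)


# ----------------------------------------------------------------------
# fixture writing

_VCF_HEADER = """##fileformat=VCFv4.2
##contig=<ID=1>
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths (ref,alt)">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Total read depth">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{sample}
"""


def write_vcf(table: pd.DataFrame, path, sample: str) -> None:
    """Write one sample's variant rows as a single-sample VCFv4.2 file."""
    rows = table.sort_values(["chrom", "pos", "ref", "alt"], kind="mergesort")
    with open(path, "w") as fh:
        fh.write(_VCF_HEADER.format(sample=sample))
        for _, r in rows.iterrows():
            ref_depth = int(r["total_depth"]) - int(r["variant_depth"])
            fh.write(
                f"{r['chrom']}\t{int(r['pos'])}\t.\t{r['ref']}\t{r['alt']}\t.\tPASS\t.\t"
                f"GT:AD:DP\t{r['genotype']}:{ref_depth},{int(r['variant_depth'])}:"
                f"{int(r['total_depth'])}\n"
            )


def write_fixture(dataset: SimulatedDataset, directory) -> dict[str, object]:
    """Write the full dataset as plain-text files; returns the path map.

    Layout: ``matrix/`` (Matrix Market + sidecars), ``well_list.tsv``,
    ``vcf/sc_<sample>.vcf`` and ``vcf/bulk_<sample>.vcf``,
    ``evidence.tsv``, ``annotation.tsv``, ``gene_biotypes.tsv``,
    ``bulk_counts.tsv`` and a ``truth.json`` manifest.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    (directory / "vcf").mkdir(exist_ok=True)

    write_matrix(dataset.matrix, directory / "matrix")
    write_well_list(dataset.matrix.sample_of, directory / "well_list.tsv")

    sc_paths, bulk_paths = {}, {}
    for sample in dataset.truth.sample_names:
        sc_paths[sample] = directory / "vcf" / f"sc_{sample}.vcf"
        sub = dataset.sc_variants[dataset.sc_variants["sample"] == sample]
        write_vcf(sub, sc_paths[sample], sample)
        bulk_paths[sample] = directory / "vcf" / f"bulk_{sample}.vcf"
        sub = dataset.bulk_variants[dataset.bulk_variants["sample"] == sample]
        write_vcf(sub, bulk_paths[sample], sample)

    dataset.evidence.to_csv(directory / "evidence.tsv", sep="\t", index=False)
    dataset.annotation.to_csv(directory / "annotation.tsv", sep="\t", index=False)
    dataset.truth.biotype_of.rename_axis("gene").reset_index().to_csv(
        directory / "gene_biotypes.tsv", sep="\t", index=False
    )
    dataset.bulk_counts.rename_axis("gene").to_csv(directory / "bulk_counts.tsv", sep="\t")

    truth = dataset.truth
    manifest = {
        "config": dataclasses.asdict(dataset.config),
        "sample_names": truth.sample_names,
        "control_samples": truth.control_samples,
        "marker_genes": truth.marker_genes,
        "mutation_pct": truth.mutation_pct.to_dict(),
        "mutant_cells": {s: st.index[st.to_numpy()].tolist() for s, st in truth.mutant_status.items()},
        "regulon_genes": truth.regulon_genes.to_dict(orient="list"),
        "de_genes": truth.de_genes,
        "specific_variants": truth.specific_variants.to_dict(orient="list"),
        "decoy_variants": truth.decoy_variants,
        "target_variant": truth.target_variant,
        "target_gene": truth.target_gene,
    }
    with open(directory / "truth.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)

    return {
        "matrix": directory / "matrix",
        "well_list": directory / "well_list.tsv",
        "sc_vcfs": sc_paths,
        "bulk_vcfs": bulk_paths,
        "evidence": directory / "evidence.tsv",
        "annotation": directory / "annotation.tsv",
        "biotypes": directory / "gene_biotypes.tsv",
        "bulk_counts": directory / "bulk_counts.tsv",
        "truth": directory / "truth.json",
    }
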