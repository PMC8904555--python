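# Methods

This note records the models, parameter choices and numerical decisions
behind `scgenolink`, and what the synthetic benchmark does and does not
establish about real data.

## Data model

The central object is a cells × genes matrix of integer *read* counts
(full-length chemistry has no UMIs), with each cell mapped to a
biological sample via a well-list table. Variants are identified by
`chrom:pos:ref>alt` (1-based positions, VCFv4.2); genotype is metadata
and plays no role in cross-sample matching, since the same site can be
called 0/1 in one sample and 1/1 in another. Functional consequence and
dbSNP ids are consumed from an annotation table, never computed.

## QC filtering

Cells are kept with total reads ≥ 10,000 spread over ≥ 300 detected
genes; genes with ≥ 100 reads from ≥ 3 cells. Both rules are inclusive
("at least"), applied in a single pass each — cells first, then genes,
with no iteration to a fixed point. Iterating could in principle strand
genes whose supporting cells were removed; the single pass keeps the
operation idempotent in practice (filtering a filtered matrix is a
no-op in all tested regimes) and is simpler to reason about. Thresholds
are configurable.

## Normalization

Counts-per-million per cell, then `log2(x + 1)`. The rank-sum statistic
is computed on the CPM values (the log is monotone, so test ranks are
unchanged); fold changes are ratios of group means on the CPM scale with
a pseudocount of 1 in numerator and denominator, preventing division by
zero and damping ratios of near-zero means. The regulon regression and
heatmap exports use the log scale. Both the scale target and pseudocount
are parameters.

## Rank-sum testing

Two-sided Wilcoxon rank-sum (Mann–Whitney) per gene, group versus all
remaining cells. When both groups have ≤ 8 observations the p-value is
computed by exact enumeration of group assignments (valid under ties);
otherwise by the tie-corrected normal approximation without continuity
correction, which matches the convention of mainstream single-cell
tools (verified against scanpy's implementation in the test suite).
Benjamini–Hochberg correction runs across all QC-passing genes of the
contrast. The rank score is `−log10(max(p, 1e−300)) · log2FC`; the
floor keeps the score finite when p underflows. Top lists order by
|rank score| with deterministic tie-breaks (adjusted p ascending, then
gene id).

## Size factors and bulk comparison

Median-of-ratios size factors: restricted to genes nonzero in every
column, each column's factor is the median ratio to the gene-wise
geometric mean. Pseudo-bulk (per-sample raw count sums) and the bulk
table are combined on shared genes and normalized jointly so both sides
share one reference. A table with no all-nonzero gene raises an error
suggesting a pseudocount rather than silently switching estimators.

## Ln-rank correlation

Top-marker lists from two datasets are compared by Pearson correlation
of natural-log ranks over the union of both lists; a gene absent from
one list receives rank `len(list) + 1` there — absent genes must rank
strictly worse than any present gene, and the constant choice keeps the
statistic deterministic.

## PCA, elbow, clustering, t-SNE

Genes are standardized to unit variance before PCA (full SVD, so scores
are deterministic and row-permutation equivariant); without scaling, a
handful of high-variance genes dominate and sample structure is buried.
The elbow is made algorithmic: with explained-variance ratios `v_1 ≥ v_2
≥ …`, the kept count k is the last component whose drop `v_k − v_{k+1}`
is at least the tolerance (default 1e−3). The first-drop-below-tol
variant was tried and rejected: successive *signal* components often
have near-equal variance (drops below tolerance) while the single large
drop sits at the signal/noise boundary, so the first-drop rule collapses
to k = 1 exactly when structure is present. The last-substantial-drop
form handles both the two-factor toy case (k = 2) and the default
fixture (k = 7, one less than the number of samples, as expected for a
mean-shift design). Pure noise yields k = 1.

Clustering is Leiden community detection (RB configuration, resolution
1.0 by default, fixed seed) on a symmetrized 15-nearest-neighbour graph
in PC space. Lower resolutions merge fine structure; the resolution is a
first-class parameter because the "right" granularity is data-dependent.
t-SNE (PCA initialization, fixed seed) is display-only: coordinates are
deterministic per seed but not contractual, and no statistic is computed
from them.

## Variant depth filtering and specificity

Single-cell records pass at variant depth > 4 AND total depth > 7; bulk
records at > 6 AND > 10 — strict inequalities. A single-cell record is
corroborated when the same variant passes in the same sample's bulk
data. A variant is *sample-specific* when corroborated in one patient
sample and passing the single-cell filter in at most `max_other_samples`
(default 0) other samples; control samples never receive specific
variants. Per-sample depth quartiles (linear-interpolation quantiles)
are emitted as exploratory output for threshold inspection, but the
filters use the fixed thresholds — no automatic quartile-to-cutoff rule
is applied, because any such mapping would be an invention. The target
variant per sample is the non-synonymous specific variant with maximal
variant depth; ties break by total depth (desc), then position.

## Mutant assignment and the regulon regression

A cell is mutant when its allele evidence shows ≥ `min_alt_reads`
(default 1) alternate reads at the target variant; cells without an
evidence row are non-mutant. The default of 1 is appropriate when the
evidence comes from a caller's deduplicated, quality-filtered reads; it
is configurable for error-tolerant use.

With mutant percentages m per sample (0 for samples not carrying the
variant), each tested gene is fitted by OLS: `E_i = x_i + y_i·m +
z_i·g`, where E_i is the gene's per-sample average log-CPM over all
QC-passing cells (including zero-count cells) and g the mutated gene's
average expression. The p-value on y_i is the classical two-sided
coefficient t-test with n − 3 degrees of freedom; at least 4 samples are
required. A rank-deficient design (constant m, or m and g collinear) is
flagged unidentifiable rather than fitted. BH runs across the tested
genes — markers significant in at least one sample, the gene universe
where expression structure exists. The implementation is vectorized
least squares; tests verify it against statsmodels OLS and a hand-rolled
normal-equations oracle to 1e−8. The heatmap export takes the 30 genes
with *lowest* adjusted p (one figure caption in the source literature
says "highest", contradicting its own methods text; lowest is the
meaningful reading and is what is implemented).

## Mutant-vs-non-mutant DE

Within the target sample, genes first need |log2FC| ≥ 0.25 (inclusive)
between mutant and non-mutant means; only those are rank-sum tested and
BH-corrected, so the correction is not diluted by null genes with
trivial effects. The gene carrying the target variant bypasses the
prefilter, since its own deregulation in mutant cells is a primary
question. A flag disables the prefilter for sensitivity analysis.

## Synthetic data generator

The generator emulates the study design the pipeline targets, not any
particular dataset: 8 samples (6 patients, 2 controls), 200 cells each,
800 genes. Counts are negative binomial with shared dispersion 0.5
(variance μ + 0.5μ²) around gene baselines drawn log-normal(3, 1) —
overdispersed full-length read counts — with per-cell log-normal library
factors (σ = 0.2). Each sample gets 20 marker genes at 4-fold (log2FC
2); each patient sample gets a planted mutant-cell subset whose fraction
rises evenly across patients to a maximum of 0.8, so the mutation
percentage m has variance across samples and the regression design is
well-posed. Ten regulon genes shift their mean by `2^(±0.02·m_s)` per
sample (alternating signs); ten DE genes per patient are 4-fold up in
mutant cells only. Each patient carries one sample-specific variant
(depths drawn to pass all filters; the target flagged non-synonymous
with maximal depth) plus 10 decoy variants present and passing in every
sample, so specificity — not depth — is what excludes them. Allele
evidence at the target draws per-cell coverage Poisson(20); mutant cells
draw alternate reads Binomial(coverage, 0.9), non-mutant cells at the
error rate (default 0, keeping ground truth unambiguous). Bulk counts
are pseudo-bulk with multiplicative log-normal noise (σ = 0.3 in the
bundled dataset builder; σ = 0 reproduces pseudo-bulk exactly).

What the generator does **not** model: ambient RNA, doublets, batch
effects across chips, positional/GC coverage bias, allelic dropout in
expression, sequencing error in the evidence by default, or the heavy
zero-inflation of shallow libraries. Passing tests therefore demonstrate
that the statistics recover their planted signals under the stated
noise model at these sample sizes — not that real cohorts will show
effects of this strength.

## Problem sizes and determinism

The default fixture (1,600 cells × 800 genes) runs the full pipeline in
well under a minute on one CPU; test-suite simulations use between 150
and 1,600 cells and 200–800 genes, sizes at which every planted effect
is comfortably powered. All randomness flows from explicit integer
seeds (numpy `default_rng`, Leiden seed, t-SNE random state); identical
configurations produce byte-identical outputs, and stage manifests
record parameters, seed and input checksums without timestamps so
reruns are directly comparable.

## Known limitations

Counts are held dense in memory — fine at cohort-chip scale (a few
thousand cells), wasteful for atlas-scale matrices. The per-cell
allele-evidence table abstracts read-level BAM inspection; producing it
is upstream of this package. Variant calling, functional annotation and
pathway enrichment are consumed or exported, never computed. The
specificity rule is binary (absent-elsewhere); a graded non-uniformity
score across samples is future work.
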