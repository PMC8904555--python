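"""Link a target variant to expression: regulon regression and DE.

Cells with any alternate-allele read are mutant.  Per tested gene i the
regression E_i = x_i + y_i*m + z_i*g asks whether per-sample average
expression tracks the mutant percentage m (g = expression of the mutated
gene); mutant-vs-non-mutant DE retests the same link inside one sample.
"""

from scgenolink.linkage import (
    assign_mutant_cells,
    average_expression_by_sample,
    de_mutant_vs_nonmutant,
    mutation_percentage,
    regulon_regression,
    top_regulon_genes,
)
from scgenolink.simulate import SimConfig, simulate_dataset

ds = simulate_dataset(SimConfig(seed=0))
sample = "P6"
vid = ds.truth.target_variant[sample]
cells = ds.matrix.cells_of(sample)
status = assign_mutant_cells(
    ds.evidence[ds.evidence["cell_id"].isin(cells)], vid, cells
)
m = mutation_percentage(status, ds.matrix.sample_of)
print(f"{sample}: {status.sum()}/{len(status)} mutant cells "
      f"({m[sample]:.1f}% — planted {ds.truth.mutation_pct[sample]:.1f}%)")

E = average_expression_by_sample(ds.matrix)
fits = regulon_regression(E, ds.truth.mutation_pct, E.loc[ds.truth.target_gene[sample]])
planted = set(ds.truth.regulon_genes["gene"])
top = top_regulon_genes(fits, len(planted))
print(f"planted regulon genes in the smallest-padj ranks: "
      f"{len(planted & set(top))}/{len(planted)}")

de = de_mutant_vs_nonmutant(ds.matrix.subset_cells(cells), status).set_index("gene")
hits = de.loc[ds.truth.de_genes[sample]]
print(f"planted mutant-upregulated genes at padj<0.05 and |log2FC|>=1: "
      f"{((hits['padj'] < 0.05) & (hits['log2FC'].abs() >= 1)).sum()}/{len(hits)}")
print(
    "\nThe regression finds genes tracking the mutation gradient across"
    " samples; the DE contrast confirms the effect within the mutated"
    " sample's own cells."
)
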