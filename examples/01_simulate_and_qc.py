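"""Simulate the 8-sample study design and apply QC filtering.

Cells need >= 10,000 reads over >= 300 genes; genes need >= 100 reads
from >= 3 cells.
"""

from scgenolink.qc import apply_qc, compare_gene_sets, qc_summary
from scgenolink.simulate import SimConfig, simulate_counts

matrix, truth = simulate_counts(SimConfig(seed=0))
filtered = apply_qc(matrix)
table, genes_per_cell = qc_summary(matrix, filtered)

print(table)
print(f"\nmedian detected genes per cell: {genes_per_cell.median():.0f}")
venn = compare_gene_sets(matrix.gene_ids, filtered.gene_ids)
print(f"genes kept: {venn['overlap']} of {venn['union']}")
print(
    "\nEach row is one sample: dispensed cells vs cells surviving the"
    " read/gene thresholds; the gene overlap shows how many genes the"
    " QC rules retained."
)
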