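"""Clonal-expansion statistics on a simulated T cell repertoire.

Simulates paired alpha/beta contigs with power-law clone sizes across five
T/NK subtypes, builds clonotypes, and prints each subtype's expanded ratio
(fraction of cells in clones of >= 3 cells), the count of large expanded
clones, and the cross-subtype expansion correlation matrix.
"""

from neomrd import tcr
from neomrd.simulate import SimulationConfig, simulate_clonotype_table

rep = simulate_clonotype_table(SimulationConfig(seed=42))
table = tcr.build_clonotypes(rep.contigs, rep.annotations)
print(f"{len(table)} cells in {table.clone_sizes().size} clonotypes "
      f"({table.n_ambiguous_dropped} ambiguous cells dropped)\n")

for subtype in sorted(rep.annotations["subtype"].unique()):
    stats = tcr.expanded_ratio(table, subtype, threshold=3)
    big = tcr.expanded_clones(table, subtype, min_size=10)
    print(f"{subtype:<18} expanded ratio {stats.expanded_ratio:5.2f}"
          f"({stats.n_cells} cells, {len(big)} clones of >= 10 cells)")

print("\nexpansion correlation (log1p per-clonotype counts):")
print(tcr.expansion_correlation(table).round(2).to_string())
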