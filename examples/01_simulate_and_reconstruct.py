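"""Simulate the HG3-like cell line and reconstruct its clonal tree.

Generates 60 ARMS-style single-cell-clone genotypes from a three-lineage
clonal history (trunk mutation CAV1-like in every clone) and rebuilds the
lineage structure by perfect phylogeny.
"""

from clonelines import (assign_stages, build_clonal_tree, hg3_config,
                        hg3_tree, simulate_single_cell_clones)

tree = hg3_tree()
matrix, labels = simulate_single_cell_clones(tree, hg3_config(seed=0))

rec = build_clonal_tree(matrix)
print(f"clones genotyped : {matrix.n_clones} x {matrix.n_mutations} sites")
print(f"lineages found   : {rec.n_lineages}")
print(f"trunk mutations  : {sorted(rec.tree.trunk_mutations)}")
print(f"mutation classes : {dict(sorted(rec.mutation_classes.items()))}")
print(f"unassigned       : {len(rec.unassigned)}")
stages = assign_stages(rec)
n_late = sum(1 for lineage, stage in stages.values() if stage > 0)
print(f"late-stage clones: {n_late}")
print(rec.tree.to_newick())
# Three lineages diverging from one trunk ("mother clone") mutation, with a
# later stage inside one lineage, and every clone placed on the tree — the
# clonal structure the genotype matrix encodes.
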