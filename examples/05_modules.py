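"""Nested modules via topological overlap and threshold cuts.

A planted two-level network (cliques coupled strongly within
top-level modules, weakly between them) is clustered by average
linkage on d = 1 - OT and cut at the default descending thresholds:
the 0.95 cut recovers the top-level modules, the 0.7 cut the
sub-cliques, and lower cuts fragment further — nested modules peeled
level by level.
"""

from bigramnet import module_hierarchy
from bigramnet.hierarchy import to_newick
from bigramnet.synthetic import planted_modular_network

net, top_of, sub_of = planted_modular_network(n_top=3, cliques_per_top=2)
hierarchy = module_hierarchy(net)

for t in sorted(hierarchy.partitions, reverse=True):
    sizes = sorted((len(m) for m in hierarchy.partitions[t]), reverse=True)
    print(f"cut at {t:.2f}: {len(sizes):2d} modules, sizes {sizes}")

print("\ndendrogram (newick):", to_newick(hierarchy.dendrogram)[:80], "...")
# 3 modules at 0.95 (the planted top level), 6 at 0.7 (the planted
# cliques): each lower cut refines the one above it.
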