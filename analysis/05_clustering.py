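#!/usr/bin/env python
"""Hierarchical clustering of the reference agents (single linkage).

Clusters the 18 agents on z-scored descriptors with Euclidean distance
and single linkage. Finding: agent 12 — the only hydroxylated analog,
with elevated PSA and an extra H-bond donor/acceptor — is the last
singleton to join the tree, i.e. the most dissimilar compound; the
remaining 17 agents (including lomustine) form one tight supercluster.
"""

from pathlib import Path

from nitroscreen import builtin_table1, cluster

OUT = Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(exist_ok=True)

tree = cluster(builtin_table1(), standardize=True)
tree.to_merge_frame().to_csv(OUT / "cluster_merges.csv", index=False)
(OUT / "dendrogram.nwk").write_text(tree.to_newick() + "\n")

print(f"single-linkage tree over {len(tree.labels)} agents "
      f"({len(tree.merges)} merges)")
if tree.dropped_fields:
    print(f"  zero-variance fields dropped before z-scoring: {tree.dropped_fields}")
print(f"  most dissimilar agent (last-merging singleton): {tree.last_merging_singleton()}")
last = tree.merges[-1]
print(f"  final merge height: {last[2]:.3f} (next-highest: {tree.merges[-2][2]:.3f})")
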