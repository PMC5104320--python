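"""Decompose a small regulatory pathway into all of its sub-paths.

Builds the linear pathway A -> B -> D -| C (two activations, one inhibition)
and enumerates every constituent sub-path, including the overlapping ones.
A chain of three relations always yields six sub-paths: the three single
relations, the two two-relation overlaps, and the full chain.
"""

from subpathways import count_subpaths, enumerate_subpaths
from subpathways.graph import GeneNode, NodeKind, PathwayGraph, SemanticClass, make_edge

g = PathwayGraph(pathway_id="demo", title="worked example")
for name in "ABDC":
    g.add_node(GeneNode(node_id=name, kind=NodeKind.GENE, gene_ids=(name,)))
g.add_edge(make_edge("A", "B", SemanticClass.ACTIVATION_LIKE))
g.add_edge(make_edge("B", "D", SemanticClass.ACTIVATION_LIKE))
g.add_edge(make_edge("D", "C", SemanticClass.INHIBITION_LIKE))

subpaths = enumerate_subpaths(g)
print(f"{count_subpaths(g)} sub-paths of pathway A -> B -> D -| C:")
for sp in subpaths:
    print(" ", sp.label())
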