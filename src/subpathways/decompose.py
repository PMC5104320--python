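"""Decomposition of a pathway graph into all constituent sub-paths.

A sub-path is a simple directed path of one or more relations between gene
nodes; every prefix, suffix and interior segment of a longer path is itself a
sub-path.  Enumeration is a depth-first search from every gene node that
emits each simple path encountered ("find all paths from a node to every
other node").  Neutral (binding/association, dissociation) edges are
traversable in both directions; unknown-class edges and non-gene nodes are
never traversed.  Cycles are handled by the simple-path constraint: no node
is revisited within one sub-path.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator

from .graph import NodeKind, PathwayGraph, RelationEdge, SemanticClass


@dataclass(frozen=True)
class SubPath:
    nodes: tuple[str, ...]
    edges: tuple[RelationEdge, ...]
    pathway_id: str = ""

    def __post_init__(self) -> None:
        if len(self.nodes) < 2 or len(self.edges) != len(self.nodes) - 1:
            raise ValueError("sub-path needs >=2 nodes and len(nodes)-1 edges")
        if len(set(self.nodes)) != len(self.nodes):
            raise ValueError("sub-path repeats a node")

    @property
    def classes(self) -> tuple[SemanticClass, ...]:
        return tuple(e.semantic_class for e in self.edges)

    def label(self) -> str:
        """Human-readable chain, e.g. ``A -> B -| C`` / ``A -- B`` (binding)."""
        sym = {
            SemanticClass.ACTIVATION_LIKE: "->",
            SemanticClass.INHIBITION_LIKE: "-|",
            SemanticClass.NEUTRAL: "--",
        }
        parts = [self.nodes[0]]
        for node, edge in zip(self.nodes[1:], self.edges):
            parts += [sym[edge.semantic_class], node]
        return " ".join(parts)


def _adjacency(g: PathwayGraph) -> dict[str, list[tuple[str, RelationEdge]]]:
    """Traversal arcs between gene nodes; neutral edges go both ways."""
    adj: dict[str, list[tuple[str, RelationEdge]]] = {}
    for edge in g.edges:
        if edge.semantic_class == SemanticClass.UNKNOWN:
            continue
        for end in (edge.source, edge.target):
            node = g.nodes.get(end)
            if node is None or node.kind != NodeKind.GENE:
                break
        else:
            adj.setdefault(edge.source, []).append((edge.target, edge))
            if not edge.directed:
                adj.setdefault(edge.target, []).append((edge.source, edge))
    return adj


def iter_subpaths(
    g: PathwayGraph, max_len: int | None = None
) -> Iterator[SubPath]:
    """Stream every simple path of >=1 edge between gene nodes.

    ``max_len`` bounds the number of edges per sub-path (None = unbounded).
    Output order is deterministic: lexicographic by node-id sequence, with
    parallel edges of differing semantic class emitted as distinct sub-paths
    in class order.
    """
    adj = _adjacency(g)
    for node in adj.values():
        node.sort(key=lambda ne: (ne[0], ne[1].semantic_class.value,
                                  ne[1].kegg_subtypes))

    def dfs(path_nodes: list[str], path_edges: list[RelationEdge],
            visited: set[str]) -> Iterator[SubPath]:
        if len(path_edges) >= 1:
            yield SubPath(tuple(path_nodes), tuple(path_edges), g.pathway_id)
        if max_len is not None and len(path_edges) >= max_len:
            return
        for nxt, edge in adj.get(path_nodes[-1], ()):
            if nxt in visited:
                continue
            visited.add(nxt)
            yield from dfs(path_nodes + [nxt], path_edges + [edge], visited)
            visited.remove(nxt)

    for start in sorted(adj):
        yield from dfs([start], [], {start})


def enumerate_subpaths(
    g: PathwayGraph, max_len: int | None = None
) -> list[SubPath]:
    """Materialized :func:`iter_subpaths`, sorted lexicographically."""
    paths = list(iter_subpaths(g, max_len=max_len))
    paths.sort(key=lambda sp: (sp.nodes, sp.classes))
    return paths


def count_subpaths(g: PathwayGraph, max_len: int | None = None) -> int:
    """Number of sub-paths, computed streaming (no materialization)."""
    return sum(1 for _ in iter_subpaths(g, max_len=max_len))


def write_subpaths_tsv(subpaths: list[SubPath], path) -> None:
    with open(path, "w") as fh:
        fh.write("pathway_id\tnodes\tedge_classes\n")
        for sp in subpaths:
            fh.write(f"{sp.pathway_id}\t{'|'.join(sp.nodes)}\t"
                     f"{'|'.join(c.value for c in sp.classes)}\n")
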