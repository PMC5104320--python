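"""Core pathway-graph containers.

A molecular pathway is modelled as a directed graph: nodes are genes, gene
groups, compounds or links to other pathway maps; edges are typed regulatory
relations (activation, inhibition, expression, binding, ...).  Every edge
carries both the raw KGML subtype names and a collapsed semantic class that
drives the Boolean matching semantics downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterable


class SemanticClass(str, Enum):
    """Collapsed regulatory meaning of a relation.

    ACTIVATION_LIKE relations are functional when source and target are both
    up-regulated (logical AND); INHIBITION_LIKE when exactly one is
    up-regulated (XOR); NEUTRAL relations (binding/association, dissociation)
    are functional regardless of expression status; UNKNOWN relations have no
    defined semantics and are excluded from sub-path matching.
    """

    ACTIVATION_LIKE = "ACTIVATION_LIKE"
    INHIBITION_LIKE = "INHIBITION_LIKE"
    NEUTRAL = "NEUTRAL"
    UNKNOWN = "UNKNOWN"


class NodeKind(str, Enum):
    GENE = "gene"
    GROUP = "group"
    COMPOUND = "compound"
    MAP = "map"
    OTHER = "other"


@dataclass(frozen=True)
class GeneNode:
    node_id: str
    kind: NodeKind
    gene_ids: tuple[str, ...] = ()
    label: str = ""
    # KGML graphics x/y pass-through (layout only, never interpreted)
    xy: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.kind == NodeKind.GENE and not self.gene_ids:
            raise ValueError(f"gene node {self.node_id!r} has no gene ids")
        if self.kind == NodeKind.COMPOUND and self.gene_ids:
            raise ValueError(f"compound node {self.node_id!r} carries gene ids")


@dataclass(frozen=True)
class RelationEdge:
    source: str
    target: str
    kegg_subtypes: tuple[str, ...]
    semantic_class: SemanticClass
    directed: bool = True

    def key(self) -> tuple[str, str, SemanticClass]:
        """Identity used when aggregating relations across sub-paths.

        NEUTRAL edges are undirected, so their endpoint pair is normalised.
        """
        if not self.directed and self.source > self.target:
            return (self.target, self.source, self.semantic_class)
        return (self.source, self.target, self.semantic_class)


@dataclass
class PathwayGraph:
    pathway_id: str
    title: str = ""
    nodes: dict[str, GeneNode] = field(default_factory=dict)
    edges: list[RelationEdge] = field(default_factory=list)
    source_format: str = "KGML"

    def add_node(self, node: GeneNode) -> None:
        if node.node_id in self.nodes:
            raise ValueError(f"duplicate node id {node.node_id!r}")
        self.nodes[node.node_id] = node

    def add_edge(self, edge: RelationEdge) -> None:
        for end in (edge.source, edge.target):
            if end not in self.nodes:
                raise ValueError(
                    f"relation {edge.source}->{edge.target} references "
                    f"missing entry {end!r} in pathway {self.pathway_id}"
                )
        self.edges.append(edge)

    def gene_nodes(self) -> Iterable[GeneNode]:
        return (n for n in self.nodes.values() if n.kind == NodeKind.GENE)

    def copy(self) -> "PathwayGraph":
        return PathwayGraph(
            pathway_id=self.pathway_id,
            title=self.title,
            nodes=dict(self.nodes),
            edges=list(self.edges),
            source_format=self.source_format,
        )


def make_edge(
    source: str,
    target: str,
    semantic_class: SemanticClass | str,
    kegg_subtypes: Iterable[str] = (),
) -> RelationEdge:
    """Convenience constructor; NEUTRAL edges are created undirected."""
    cls = SemanticClass(semantic_class)
    return RelationEdge(
        source=source,
        target=target,
        kegg_subtypes=tuple(kegg_subtypes),
        semantic_class=cls,
        directed=cls != SemanticClass.NEUTRAL,
    )


def replace_edge_endpoint(edge: RelationEdge, old: str, new: str) -> RelationEdge:
    src = new if edge.source == old else edge.source
    tgt = new if edge.target == old else edge.target
    return replace(edge, source=src, target=tgt)
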