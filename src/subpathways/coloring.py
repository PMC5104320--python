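"""Mapping sub-path calls back onto pathway edges as colors.

An edge (single relation) inherits the phenotype inclination of the selected
sub-paths it belongs to: green when only phenotype-1 sub-paths contain it,
red for phenotype-2 only, black when it sits in sub-paths of both calls or in
a shared (functional-in-both) sub-path, yellow always for binding/association
and dissociation relations, grey for edges in no selected sub-path.  The
same rules, applied across pathways, color the integrated cross-pathway
network built from the union of selected single relations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .graph import GeneNode, NodeKind, PathwayGraph, SemanticClass
from .stats import SubPathCall, SubPathStats

logger = logging.getLogger(__name__)

GREEN, RED, BLACK, GREY, YELLOW = "green", "red", "black", "grey", "yellow"


@dataclass
class EdgeColorMap:
    """Total map from edge identity (source, target, class) to color."""

    entries: dict[tuple, str] = field(default_factory=dict)

    def get(self, edge) -> str:
        return self.entries.get(edge.key(), GREY)


def _edge_calls(stats: list[SubPathStats]) -> dict[tuple, set[SubPathCall]]:
    calls: dict[tuple, set[SubPathCall]] = {}
    for st in stats:
        if st.call == SubPathCall.NONE:
            continue
        for edge in st.subpath.edges:
            calls.setdefault(edge.key(), set()).add(st.call)
    return calls


def _color_for(key: tuple, cls: SemanticClass, calls: dict) -> str:
    if cls == SemanticClass.NEUTRAL:
        return YELLOW
    got = calls.get(key, set())
    if SubPathCall.SHARED in got or (
            SubPathCall.PHENOTYPE1 in got and SubPathCall.PHENOTYPE2 in got):
        return BLACK
    if SubPathCall.PHENOTYPE1 in got:
        return GREEN
    if SubPathCall.PHENOTYPE2 in got:
        return RED
    return GREY


def color_edges(stats: list[SubPathStats], g: PathwayGraph) -> EdgeColorMap:
    """Color every edge of ``g`` from the calls of the sub-paths through it."""
    calls = _edge_calls(stats)
    cmap = EdgeColorMap()
    for edge in g.edges:
        cmap.entries[edge.key()] = _color_for(edge.key(), edge.semantic_class, calls)
    return cmap


def build_integrated_network(
    stats_by_pathway: dict[str, list[SubPathStats]],
    gene_filter: set[str] | None = None,
) -> tuple[PathwayGraph, EdgeColorMap]:
    """Union network of the unique single relations of all selected sub-paths.

    Relations are deduplicated by (source, target, semantic class) across
    pathways; ``gene_filter`` optionally restricts to edges incident to the
    given node ids.  Colors follow the per-edge rules with calls pooled
    across pathways.
    """
    pooled: list[SubPathStats] = [s for stats in stats_by_pathway.values() for s in stats]
    calls = _edge_calls(pooled)

    g = PathwayGraph(pathway_id="integrated", title="integrated network",
                     source_format="derived")
    cmap = EdgeColorMap()
    seen: set[tuple] = set()
    for st in pooled:
        if st.call == SubPathCall.NONE:
            continue
        for edge in st.subpath.edges:
            key = edge.key()
            if key in seen:
                continue
            if gene_filter and not ({edge.source, edge.target} & gene_filter):
                continue
            seen.add(key)
            for end in (edge.source, edge.target):
                if end not in g.nodes:
                    g.add_node(GeneNode(node_id=end, kind=NodeKind.GENE,
                                        gene_ids=(end,), label=end))
            g.add_edge(edge)
            cmap.entries[key] = _color_for(key, edge.semantic_class, calls)
    if not seen:
        logger.warning("no selected sub-paths; integrated network is empty")
    return g, cmap
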