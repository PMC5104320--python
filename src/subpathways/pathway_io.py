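"""KGML parsing, graph normalisation and annotated network export.

KGML (KEGG Markup Language) encodes a pathway as ``<entry>`` elements (genes,
gene groups, compounds, links to other maps) and ``<relation>`` elements with
one or more ``<subtype>`` children naming the regulatory mechanism.  Parsing
maps each subtype list onto a single semantic class (activation-like,
inhibition-like, neutral or unknown) that drives the Boolean sub-path
semantics downstream.

Networks are written as GraphML and as Cytoscape-compatible JSON with a
per-edge ``color`` attribute; reading a written GraphML file recovers the
identical topology, classes and colors.
"""

from __future__ import annotations

import json
import logging
import pathlib
from typing import Iterable, Mapping

import networkx as nx
from lxml import etree

from .graph import (
    GeneNode,
    NodeKind,
    PathwayGraph,
    RelationEdge,
    SemanticClass,
    replace_edge_endpoint,
)

logger = logging.getLogger(__name__)

#: KGML subtype names with activation semantics when no arrow subtype decides.
_ACTIVATION_SUBTYPES = frozenset(
    ["activation", "expression", "indirect effect",
     "phosphorylation", "dephosphorylation"]
)
#: Subtype names with inhibition semantics.  Ubiquitination is inhibition-like
#: even when accompanied by an activation arrow.
_INHIBITION_SUBTYPES = frozenset(["inhibition", "ubiquitination"])
_NEUTRAL_SUBTYPES = frozenset(["binding/association", "dissociation"])

_ENTRY_KINDS = {
    "gene": NodeKind.GENE,
    "group": NodeKind.GROUP,
    "compound": NodeKind.COMPOUND,
    "map": NodeKind.MAP,
}


def classify_relation(kegg_subtypes: Iterable[str]) -> SemanticClass:
    """Collapse a KGML subtype list onto one semantic class.

    Precedence: inhibition/ubiquitination, then activation-like subtypes
    (activation, expression, indirect effect, phosphorylation,
    dephosphorylation), then binding/association and dissociation (neutral,
    undirected).  A phosphorylation subtype paired with an arrow subtype takes
    the arrow's class; alone it counts as activation.  Anything unmapped,
    including compound-mediated relations, is UNKNOWN and excluded from
    matching.
    """
    names = {s.strip().lower() for s in kegg_subtypes}
    if names & _INHIBITION_SUBTYPES:
        return SemanticClass.INHIBITION_LIKE
    if names & _ACTIVATION_SUBTYPES:
        return SemanticClass.ACTIVATION_LIKE
    if names & _NEUTRAL_SUBTYPES:
        return SemanticClass.NEUTRAL
    return SemanticClass.UNKNOWN


def _entry_gene_ids(name: str) -> tuple[str, ...]:
    # KGML names are space-separated "hsa:1956"-style identifiers
    return tuple(tok.split(":", 1)[-1] for tok in name.split() if tok and tok != "undefined")


def parse_kgml(path: str | pathlib.Path) -> PathwayGraph:
    """Parse a KGML XML file into a :class:`PathwayGraph`.

    Every ``<entry>`` becomes a node (map and compound entries retained with
    their kind); every ``<relation>`` becomes an edge in document order.
    Raises a parse error naming the file on malformed XML and a structural
    error naming the relation if an endpoint entry is missing.
    """
    path = pathlib.Path(path)
    try:
        tree = etree.parse(str(path))
    except etree.XMLSyntaxError as exc:
        raise ValueError(f"malformed KGML in {path}: {exc}") from exc
    root = tree.getroot()

    g = PathwayGraph(
        pathway_id=root.get("name", path.stem).split(":")[-1],
        title=root.get("title", ""),
        source_format="KGML",
    )
    groups: dict[str, list[str]] = {}
    for entry in root.iter("entry"):
        eid = entry.get("id")
        etype = entry.get("type", "other")
        kind = _ENTRY_KINDS.get(etype, NodeKind.OTHER)
        gene_ids = _entry_gene_ids(entry.get("name", "")) if kind == NodeKind.GENE else ()
        graphics = entry.find("graphics")
        label = ""
        xy = None
        if graphics is not None:
            label = (graphics.get("name") or "").split(",")[0].strip()
            if graphics.get("x") is not None and graphics.get("y") is not None:
                xy = (float(graphics.get("x")), float(graphics.get("y")))
        if kind == NodeKind.GENE and not gene_ids:
            kind = NodeKind.OTHER
        g.add_node(GeneNode(node_id=eid, kind=kind, gene_ids=gene_ids,
                            label=label or entry.get("name", ""), xy=xy))
        if kind == NodeKind.GROUP:
            groups[eid] = [c.get("id") for c in entry.iter("component")]

    g.group_members = groups  # type: ignore[attr-defined]

    for rel in root.iter("relation"):
        e1, e2 = rel.get("entry1"), rel.get("entry2")
        subtypes = tuple(st.get("name", "") for st in rel.iter("subtype"))
        cls = classify_relation(subtypes)
        if e1 not in g.nodes or e2 not in g.nodes:
            raise ValueError(
                f"relation {e1}->{e2} ({','.join(subtypes) or rel.get('type')}) "
                f"references a missing entry in {path}"
            )
        g.add_edge(RelationEdge(
            source=e1, target=e2, kegg_subtypes=subtypes,
            semantic_class=cls, directed=cls != SemanticClass.NEUTRAL,
        ))
    return g


def normalize_graph(g: PathwayGraph, expand_groups: bool = True) -> PathwayGraph:
    """Resolve group entries and strip compound nodes.

    With ``expand_groups`` every group node is replaced by its member gene
    nodes, each member inheriting all edges incident to the group.  Compound
    nodes (no gene content) are removed along with their edges; chains through
    a compound are not bridged.  Map-type entries are kept as terminal
    annotation nodes (decomposition never traverses them).  Idempotent.
    """
    out = PathwayGraph(pathway_id=g.pathway_id, title=g.title,
                       source_format=g.source_format)
    members: Mapping[str, list[str]] = getattr(g, "group_members", {})

    for node in g.nodes.values():
        if node.kind == NodeKind.COMPOUND:
            continue
        if node.kind == NodeKind.GROUP and expand_groups:
            if not members.get(node.node_id):
                logger.warning("group %s has no members; dropped", node.node_id)
            continue
        out.add_node(node)

    edges: list[RelationEdge] = []
    for edge in g.edges:
        expanded = [edge]
        if expand_groups:
            for end in (edge.source, edge.target):
                node = g.nodes[end]
                if node.kind == NodeKind.GROUP:
                    expanded = [
                        replace_edge_endpoint(e, end, m)
                        for e in expanded
                        for m in members.get(end, [])
                        if m in out.nodes
                    ]
        for e in expanded:
            if e.source in out.nodes and e.target in out.nodes:
                edges.append(e)
    # deterministic: document order preserved, group members in component order
    out.edges = edges
    out.group_members = {}  # type: ignore[attr-defined]
    return out


DEFAULT_EDGE_COLOR = "grey"
NEUTRAL_EDGE_COLOR = "yellow"
_VALID_COLORS = {"green", "red", "black", "grey", "yellow"}


def _edge_color(edge: RelationEdge, colors: Mapping | None) -> str:
    if colors:
        for key in (edge, edge.key()):
            if key in colors:
                return colors[key]
    if edge.semantic_class == SemanticClass.NEUTRAL:
        return NEUTRAL_EDGE_COLOR
    return DEFAULT_EDGE_COLOR


def to_networkx(g: PathwayGraph, edge_colors: Mapping | None = None) -> nx.MultiDiGraph:
    nxg = nx.MultiDiGraph(pathway_id=g.pathway_id, title=g.title)
    for node in g.nodes.values():
        nxg.add_node(node.node_id, kind=node.kind.value,
                     gene_ids=" ".join(node.gene_ids), label=node.label)
    for edge in g.edges:
        color = _edge_color(edge, edge_colors)
        if color not in _VALID_COLORS:
            raise ValueError(f"invalid edge color {color!r}")
        nxg.add_edge(edge.source, edge.target,
                     kegg_subtypes=" | ".join(edge.kegg_subtypes),
                     semantic_class=edge.semantic_class.value,
                     directed=edge.directed, color=color)
    return nxg


def write_network(
    g: PathwayGraph,
    path: str | pathlib.Path,
    edge_colors: Mapping | None = None,
) -> None:
    """Write GraphML (``<path>.graphml``) and Cytoscape JSON (``<path>.cyjs``).

    ``edge_colors`` maps a :class:`RelationEdge` (or its ``key()``) to a color
    in {green, red, black, grey, yellow}; uncolored neutral edges default to
    yellow and everything else to grey.
    """
    path = pathlib.Path(path)
    base = path.with_suffix("") if path.suffix in {".graphml", ".cyjs"} else path
    nxg = to_networkx(g, edge_colors)
    nx.write_graphml(nxg, str(base.with_suffix(".graphml")))
    cy = nx.cytoscape_data(nxg)
    with open(base.with_suffix(".cyjs"), "w") as fh:
        json.dump(cy, fh, indent=1, sort_keys=True)


def read_graphml(path: str | pathlib.Path) -> tuple[PathwayGraph, dict]:
    """Read a GraphML file written by :func:`write_network`.

    Returns the graph and an edge->color mapping keyed like ``edge.key()``.
    """
    nxg = nx.read_graphml(str(path), force_multigraph=True)
    g = PathwayGraph(pathway_id=nxg.graph.get("pathway_id", ""),
                     title=nxg.graph.get("title", ""))
    for nid, data in nxg.nodes(data=True):
        g.add_node(GeneNode(
            node_id=nid, kind=NodeKind(data.get("kind", "other")),
            gene_ids=tuple(data.get("gene_ids", "").split()),
            label=data.get("label", ""),
        ))
    colors: dict = {}
    for u, v, data in nxg.edges(data=True):
        edge = RelationEdge(
            source=u, target=v,
            kegg_subtypes=tuple(s for s in data.get("kegg_subtypes", "").split(" | ") if s),
            semantic_class=SemanticClass(data["semantic_class"]),
            directed=bool(data.get("directed", True)),
        )
        g.add_edge(edge)
        colors[edge.key()] = data.get("color", DEFAULT_EDGE_COLOR)
    return g, colors
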