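"""Synthetic pathways and expression cohorts with known ground truth.

Three generators cover the test surface without any download:

* :func:`make_fig_dummy` — two tiny frozen pathway/profile pairs.  The
  binary grids are constraint-derived instantiations consistent with every
  documented claim about the corresponding worked examples (which sub-path is
  functional in which sample); they are frozen data, byte-identical across
  runs.
* :func:`make_planted_cohort` — a two-phenotype continuous cohort in which a
  known regulatory chain is imposed on a chosen fraction of phenotype-1
  samples, with per-bit flip noise and pure-noise filler genes; after entropy
  discretization the planted sub-path should surface as discriminant.
* :func:`make_random_pathway` — small random typed digraphs for
  oracle-compatible enumeration tests.

Every generator is a pure function of its arguments and seed.  Fixtures can
be written back to the same KGML-subset XML and expression TSV the pipeline
reads (self-hosting test data).
"""

from __future__ import annotations

import pathlib
from dataclasses import dataclass, field

import numpy as np

from .decompose import SubPath
from .expression import BinaryExpressionMatrix, LabeledExpressionMatrix
from .graph import GeneNode, NodeKind, PathwayGraph, SemanticClass, make_edge

_ACT = SemanticClass.ACTIVATION_LIKE
_INH = SemanticClass.INHIBITION_LIKE


def _gene_chain_graph(pathway_id: str, chain: list[tuple[str, str, SemanticClass]],
                      extra_nodes: list[str] = ()) -> PathwayGraph:
    g = PathwayGraph(pathway_id=pathway_id, title=pathway_id)
    seen = []
    for src, tgt, _ in chain:
        for n in (src, tgt):
            if n not in seen:
                seen.append(n)
    for n in list(seen) + list(extra_nodes):
        g.add_node(GeneNode(node_id=n, kind=NodeKind.GENE, gene_ids=(n,), label=n))
    for src, tgt, cls in chain:
        subtype = "activation" if cls == _ACT else (
            "inhibition" if cls == _INH else "binding/association")
        g.add_edge(make_edge(src, tgt, cls, (subtype,)))
    return g


def make_fig_dummy(which: str) -> tuple[PathwayGraph, BinaryExpressionMatrix]:
    """Frozen worked-example fixtures.

    ``fig11``: pathway A -> B -> D -| C over six samples (S1-S3 phenotype 1,
    S4-S6 phenotype 2).  The grid is the unique-style instantiation under the
    constraints: A->B->D-|C functional exactly in {S1, S3}; A->B->D in
    {S1, S3, S5, S6}; D-|C in all phenotype-1 and no phenotype-2 samples;
    B->D-|C exactly in the phenotype-1 samples (perfect discriminator).

    ``fig1``: pathway A -> B -| C -> D over five samples (S1-S3 phenotype 1,
    S4-S5 phenotype 2), built so that A->B-|C is functional exactly in
    {S1, S2} and no single gene separates the phenotypes.
    """
    if which == "fig11":
        g = _gene_chain_graph("dummy11", [("A", "B", _ACT), ("B", "D", _ACT),
                                          ("D", "C", _INH)])
        bits = np.array([
            [1, 0, 1, 0, 1, 1],   # A
            [1, 1, 1, 0, 1, 1],   # B
            [0, 0, 0, 0, 1, 1],   # C
            [1, 1, 1, 0, 1, 1],   # D
        ], dtype=np.uint8)
        b = BinaryExpressionMatrix(
            gene_ids=["A", "B", "C", "D"],
            sample_ids=["S1", "S2", "S3", "S4", "S5", "S6"],
            bits=bits, labels=np.array([1, 1, 1, 2, 2, 2]),
        )
        return g, b
    if which == "fig1":
        g = _gene_chain_graph("dummy1", [("A", "B", _ACT), ("B", "C", _INH),
                                         ("C", "D", _ACT)])
        bits = np.array([
            [1, 1, 1, 0, 1],   # A
            [1, 1, 0, 1, 1],   # B
            [0, 0, 1, 1, 1],   # C
            [0, 1, 1, 0, 1],   # D
        ], dtype=np.uint8)
        b = BinaryExpressionMatrix(
            gene_ids=["A", "B", "C", "D"],
            sample_ids=["S1", "S2", "S3", "S4", "S5"],
            bits=bits, labels=np.array([1, 1, 1, 2, 2]),
        )
        return g, b
    raise ValueError(f"unknown dummy fixture {which!r}")


@dataclass
class SyntheticCohortSpec:
    """Study conditions of a planted-signal cohort.

    ``planted_classes`` gives the semantic class of each chain edge; the
    chain runs over genes P1..P(k+1).  ``signal_fraction`` is the fraction of
    phenotype-1 samples on which the chain's functional pattern is imposed
    (``background_fraction`` the same for phenotype 2, default 0);
    ``noise_rate`` flips each planted-gene bit independently.  Non-signal
    samples sit near the chain's *inactive* state — the bitwise complement
    of the functional pattern (activation members down, inhibition target
    up), perturbed per gene by ``baseline_flip`` and resampled if the
    perturbation happens to realize a functional chain.  This mirrors a
    regulatory program that is switched on in one phenotype and off in the
    other, so each planted gene also carries the marginal differential
    expression that per-gene supervised discretization requires; with no
    noise the planted sub-path is perfectly phenotype-1 specific.
    """

    n_genes: int = 12
    n_samples_per_class: int = 20
    planted_classes: tuple[SemanticClass, ...] = (_ACT, _ACT, _INH)
    signal_fraction: float = 0.9
    background_fraction: float = 0.0
    noise_rate: float = 0.02
    baseline_flip: float = 0.10
    seed: int = 0
    mu_low: float = 0.0
    mu_high: float = 3.0
    sigma: float = 0.5

    def __post_init__(self) -> None:
        for name in ("signal_fraction", "background_fraction", "noise_rate",
                     "baseline_flip"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} outside [0, 1]")
        if self.noise_rate >= 0.5:
            raise ValueError("noise_rate >= 0.5 destroys any planted signal")
        if self.n_genes < len(self.planted_classes) + 1:
            raise ValueError("not enough genes for the planted chain")


def _functional_pattern(classes: tuple[SemanticClass, ...]) -> np.ndarray:
    """A bit assignment along the chain making every relation functional."""
    bits = [1]
    for cls in classes:
        if cls == _ACT:
            bits.append(1)            # activation: both up
        elif cls == _INH:
            bits.append(1 - bits[-1])  # inhibition: exactly one up
        else:
            bits.append(1)            # neutral: unconstrained
    return np.array(bits, dtype=np.uint8)


def _pattern_functional(bits: np.ndarray, classes: tuple[SemanticClass, ...]) -> bool:
    for k, cls in enumerate(classes):
        s, t = bits[k], bits[k + 1]
        ok = (s & t) if cls == _ACT else ((s ^ t) if cls == _INH else 1)
        if not ok:
            return False
    return True


def planted_subpath(spec: SyntheticCohortSpec) -> SubPath:
    k = len(spec.planted_classes)
    names = tuple(f"P{i+1}" for i in range(k + 1))
    edges = tuple(make_edge(names[i], names[i + 1], spec.planted_classes[i])
                  for i in range(k))
    return SubPath(nodes=names, edges=edges, pathway_id="planted")


def make_planted_cohort(
    spec: SyntheticCohortSpec,
) -> tuple[PathwayGraph, LabeledExpressionMatrix]:
    """Generate the pathway and continuous cohort for a planted chain.

    Continuous values per gene are a two-component Gaussian (low/high state)
    over the underlying bits, separated widely enough that entropy
    discretization recovers the bits; filler genes are fair-coin noise.
    """
    rng = np.random.default_rng(spec.seed)
    k = len(spec.planted_classes)
    chain_genes = [f"P{i+1}" for i in range(k + 1)]
    noise_genes = [f"N{i+1}" for i in range(spec.n_genes - len(chain_genes))]

    chain = [(chain_genes[i], chain_genes[i + 1], spec.planted_classes[i])
             for i in range(k)]
    g = _gene_chain_graph("planted", chain, extra_nodes=noise_genes)
    # a sparse random scaffold over the filler genes (more sub-paths to filter)
    for i in range(len(noise_genes) - 1):
        if rng.random() < 0.4:
            cls = _ACT if rng.random() < 0.7 else _INH
            g.add_edge(make_edge(noise_genes[i], noise_genes[i + 1], cls,
                                 ("activation" if cls == _ACT else "inhibition",)))

    n = 2 * spec.n_samples_per_class
    labels = np.array([1] * spec.n_samples_per_class + [2] * spec.n_samples_per_class)
    pattern = _functional_pattern(spec.planted_classes)

    inactive = 1 - pattern
    rejectable = any(c in (_ACT, _INH) for c in spec.planted_classes)
    chain_bits = np.zeros((k + 1, n), dtype=np.uint8)
    for j in range(n):
        frac = spec.signal_fraction if labels[j] == 1 else spec.background_fraction
        if rng.random() < frac:
            bits = pattern.copy()
        else:
            bits = inactive ^ (rng.random(k + 1) < spec.baseline_flip).astype(np.uint8)
            while rejectable and _pattern_functional(bits, spec.planted_classes):
                bits = inactive ^ (rng.random(k + 1) < spec.baseline_flip).astype(np.uint8)
        flips = rng.random(k + 1) < spec.noise_rate
        chain_bits[:, j] = bits ^ flips.astype(np.uint8)

    noise_bits = rng.integers(0, 2, size=(len(noise_genes), n)).astype(np.uint8)
    all_bits = np.vstack([chain_bits, noise_bits]) if noise_genes else chain_bits
    row_ids = chain_genes + noise_genes

    values = np.where(
        all_bits == 1,
        rng.normal(spec.mu_high, spec.sigma, size=all_bits.shape),
        rng.normal(spec.mu_low, spec.sigma, size=all_bits.shape),
    )
    m = LabeledExpressionMatrix(
        row_ids=row_ids,
        sample_ids=[f"S{j+1}" for j in range(n)],
        values=values, labels=labels,
    )
    return g, m


def make_random_pathway(
    n_nodes: int,
    edge_prob: float,
    class_mix: dict[SemanticClass, float] | None = None,
    seed: int = 0,
) -> PathwayGraph:
    """Random typed digraph over genes G1..Gn (neutral edges undirected)."""
    rng = np.random.default_rng(seed)
    mix = class_mix or {_ACT: 0.5, _INH: 0.3, SemanticClass.NEUTRAL: 0.2}
    classes = list(mix)
    weights = np.array([mix[c] for c in classes], dtype=float)
    weights /= weights.sum()

    g = PathwayGraph(pathway_id=f"rand{seed}", title="random pathway")
    names = [f"G{i+1}" for i in range(n_nodes)]
    for n in names:
        g.add_node(GeneNode(node_id=n, kind=NodeKind.GENE, gene_ids=(n,), label=n))
    for i, src in enumerate(names):
        for j, tgt in enumerate(names):
            if i == j:
                continue
            cls = classes[rng.choice(len(classes), p=weights)]
            take = rng.random() < edge_prob
            if not take:
                continue
            if cls == SemanticClass.NEUTRAL and i > j:
                continue  # one undirected edge per unordered pair
            g.add_edge(make_edge(src, tgt, cls))
    return g


def random_profile(gene_ids: list[str], seed: int = 0) -> dict[str, int]:
    rng = np.random.default_rng(seed)
    return {g: int(b) for g, b in zip(gene_ids, rng.integers(0, 2, len(gene_ids)))}


# ---------------------------------------------------------------------------
# self-hosting writers

_SUBTYPE_FOR_CLASS = {
    _ACT: "activation",
    _INH: "inhibition",
    SemanticClass.NEUTRAL: "binding/association",
    SemanticClass.UNKNOWN: "state change",
}


def write_kgml(g: PathwayGraph, path: str | pathlib.Path) -> None:
    """Write the graph as KGML-subset XML readable by ``parse_kgml``."""
    from lxml import etree

    root = etree.Element("pathway", name=f"path:{g.pathway_id}",
                         title=g.title or g.pathway_id)
    # entry ids keep the node ids so a parse round-trip is exact
    ids = {nid: nid for nid in g.nodes}
    for nid, node in g.nodes.items():
        name = " ".join(f"hsa:{gid}" for gid in node.gene_ids) or node.kind.value
        entry = etree.SubElement(root, "entry", id=ids[nid], name=name,
                                 type=node.kind.value)
        etree.SubElement(entry, "graphics", name=node.label or nid)
    for edge in g.edges:
        rel = etree.SubElement(root, "relation", entry1=ids[edge.source],
                               entry2=ids[edge.target], type="PPrel")
        subtypes = edge.kegg_subtypes or (_SUBTYPE_FOR_CLASS[edge.semantic_class],)
        for st in subtypes:
            etree.SubElement(rel, "subtype", name=st, value="")
    etree.ElementTree(root).write(str(path), pretty_print=True,
                                  xml_declaration=True, encoding="UTF-8")


def write_cohort(
    m: LabeledExpressionMatrix,
    expr_path: str | pathlib.Path,
    classes_path: str | pathlib.Path,
) -> None:
    """Write the continuous matrix and label table in pipeline input format."""
    with open(expr_path, "w") as fh:
        fh.write("gene_id\t" + "\t".join(m.sample_ids) + "\n")
        for rid, row in zip(m.row_ids, m.values):
            fh.write(rid + "\t" + "\t".join(f"{v:.6f}" for v in row) + "\n")
    with open(classes_path, "w") as fh:
        for s, c in zip(m.sample_ids, m.labels):
            fh.write(f"{s}\t{c}\n")
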