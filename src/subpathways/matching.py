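"""Boolean matching of sub-paths against binarized sample profiles.

Each relation is scored on the *measured* bits of its two genes — activation
is functional when source AND target are up, inhibition when exactly one of
the two is up (XOR), binding/association and dissociation are functional
regardless of expression status.  A sub-path is functional in a sample when
every one of its relations is functional there: the per-relation values are
folded left-to-right with AND.  No regulatory state is propagated along the
chain.

A node carrying several gene ids (an unexpanded multi-gene entry) takes the
OR of its member gene bits, mirroring the probe-collapsing rule.
"""

from __future__ import annotations

import logging
import pathlib
from dataclasses import dataclass

import numpy as np

from .decompose import SubPath
from .expression import BinaryExpressionMatrix
from .graph import PathwayGraph, SemanticClass

logger = logging.getLogger(__name__)


@dataclass
class SubPathMatrix:
    """Binary functional-status matrix, sub-paths x samples."""

    subpaths: list[SubPath]
    sample_ids: list[str]
    bits: np.ndarray
    labels: np.ndarray
    n_unevaluable: int = 0

    def __post_init__(self) -> None:
        self.bits = np.asarray(self.bits, dtype=np.uint8)
        self.labels = np.asarray(self.labels, dtype=int)
        if self.bits.shape != (len(self.subpaths), len(self.sample_ids)):
            raise ValueError("bits shape mismatch")


def eval_relation(cls: SemanticClass, src_bit: int, tgt_bit: int) -> int:
    """Truth value of one relation given measured source/target bits."""
    if cls == SemanticClass.ACTIVATION_LIKE:
        return src_bit & tgt_bit
    if cls == SemanticClass.INHIBITION_LIKE:
        return src_bit ^ tgt_bit
    if cls == SemanticClass.NEUTRAL:
        return 1
    raise ValueError("relations of UNKNOWN class have no matching semantics")


def _node_bits(
    node_id: str,
    b: BinaryExpressionMatrix,
    graph: PathwayGraph | None,
    index: dict[str, int],
) -> np.ndarray | None:
    """Sample bit-vector for a node: its own row, or OR over member genes."""
    if node_id in index:
        return b.bits[index[node_id]]
    if graph is not None and node_id in graph.nodes:
        rows = [index[g] for g in graph.nodes[node_id].gene_ids if g in index]
        if rows:
            return np.bitwise_or.reduce(b.bits[rows], axis=0)
    return None


def eval_subpath(
    sp: SubPath,
    profile: dict[str, int],
) -> int:
    """Functional status of one sub-path in one sample profile.

    ``profile`` maps gene/node id -> bit.  Raises ``KeyError`` for genes
    absent from the profile (callers exclude such sub-paths).
    """
    value = 1
    for (src, tgt), edge in zip(zip(sp.nodes, sp.nodes[1:]), sp.edges):
        value &= eval_relation(edge.semantic_class, profile[src], profile[tgt])
        if not value:
            return 0
    return value


def build_subpath_matrix(
    subpaths: list[SubPath],
    b: BinaryExpressionMatrix,
    graph: PathwayGraph | None = None,
) -> SubPathMatrix:
    """Evaluate every sub-path in every sample (vectorized over samples).

    Sub-paths touching a node with no measured gene are excluded and counted
    in ``n_unevaluable``.  Column order is identical to the input binary
    matrix.  Passing the pathway graph lets multi-gene nodes resolve to the
    OR of their member gene rows.
    """
    if not subpaths:
        logger.warning("empty sub-path list; empty matrix produced")
    index = {g: i for i, g in enumerate(b.gene_ids)}
    n_samples = len(b.sample_ids)
    rows: list[np.ndarray] = []
    kept: list[SubPath] = []
    skipped = 0
    cache: dict[str, np.ndarray | None] = {}
    for sp in subpaths:
        vecs = []
        for node in sp.nodes:
            if node not in cache:
                cache[node] = _node_bits(node, b, graph, index)
            vecs.append(cache[node])
        if any(v is None for v in vecs):
            skipped += 1
            continue
        value = np.ones(n_samples, dtype=np.uint8)
        for k, edge in enumerate(sp.edges):
            src, tgt = vecs[k], vecs[k + 1]
            if edge.semantic_class == SemanticClass.ACTIVATION_LIKE:
                value &= src & tgt
            elif edge.semantic_class == SemanticClass.INHIBITION_LIKE:
                value &= src ^ tgt
            # NEUTRAL contributes a constant 1
        rows.append(value)
        kept.append(sp)
    if skipped:
        logger.warning("%d sub-paths not evaluable (unmeasured genes)", skipped)
    bits = np.vstack(rows) if rows else np.zeros((0, n_samples), dtype=np.uint8)
    return SubPathMatrix(
        subpaths=kept, sample_ids=list(b.sample_ids), bits=bits,
        labels=b.labels.copy(), n_unevaluable=skipped,
    )


def write_subpath_matrix_tsv(m: SubPathMatrix, path: str | pathlib.Path) -> None:
    """TSV: row id = pathway id + node chain; second header line = labels."""
    with open(path, "w") as fh:
        fh.write("subpath\t" + "\t".join(m.sample_ids) + "\n")
        fh.write("phenotype\t" + "\t".join(map(str, m.labels)) + "\n")
        for sp, row in zip(m.subpaths, m.bits):
            rid = f"{sp.pathway_id}:{sp.label()}" if sp.pathway_id else sp.label()
            fh.write(rid + "\t" + "\t".join(map(str, row)) + "\n")


def write_subpath_matrix_arff(
    m: SubPathMatrix, path: str | pathlib.Path, relation: str = "subpaths"
) -> None:
    """ARFF export of the sub-path matrix for external ML tools.

    Instances are samples; attributes are sub-paths (binary) plus the nominal
    phenotype class.
    """
    def q(s: str) -> str:
        return "'" + s.replace("'", "\\'") + "'"

    with open(path, "w") as fh:
        fh.write(f"@RELATION {q(relation)}\n\n")
        for sp in m.subpaths:
            rid = f"{sp.pathway_id}:{sp.label()}" if sp.pathway_id else sp.label()
            fh.write(f"@ATTRIBUTE {q(rid)} {{0,1}}\n")
        classes = sorted(set(int(x) for x in m.labels))
        fh.write("@ATTRIBUTE 'phenotype' {" + ",".join(map(str, classes)) + "}\n")
        fh.write("\n@DATA\n")
        for j in range(len(m.sample_ids)):
            vals = [str(int(v)) for v in m.bits[:, j]] + [str(int(m.labels[j]))]
            fh.write(",".join(vals) + "\n")
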