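"""Supervised entropy-based binarization of gene-expression matrices.

Each gene is discretized independently against the two-phenotype labels: the
candidate cutpoints are the midpoints between consecutive distinct sorted
expression values, and the cutpoint maximizing the information gain

    IG(S, mu) = E(S) - E(S, mu)

is selected, where E(S) is the class entropy of the sample set (log base 2)
and E(S, mu) the size-weighted entropy of the two sub-groups split at mu.
Samples above the cutpoint are assigned 1 (up-regulated), samples at or below
it 0.  Multi-probe genes are collapsed by logical OR over their probe rows,
and independently discretized datasets can be merged sample-wise on the
intersection of their gene sets.
"""

from __future__ import annotations

import logging
import pathlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


@dataclass
class LabeledExpressionMatrix:
    """Continuous expression values with a two-class phenotype per sample."""

    row_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray  # rows x samples, float
    labels: np.ndarray  # per sample, values in {1, 2}

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        if self.values.shape != (len(self.row_ids), len(self.sample_ids)):
            raise ValueError("values shape does not match row/sample ids")
        if len(self.labels) != len(self.sample_ids):
            raise ValueError("one label per sample required")
        if len(np.unique(self.labels)) != 2:
            raise ValueError("exactly two phenotype classes required")
        if not np.all(np.isfinite(self.values)):
            bad = ~np.all(np.isfinite(self.values), axis=1)
            logger.warning("dropping %d rows with missing/non-finite values", bad.sum())
            self.values = self.values[~bad]
            self.row_ids = [r for r, b in zip(self.row_ids, bad) if not b]


@dataclass
class DiscretizationResult:
    cutpoint: float
    info_gain: float  # bits
    bits: np.ndarray
    constant: bool = False


@dataclass
class BinaryExpressionMatrix:
    """Per-gene 0/1 profiles over labeled samples, plus cutpoints."""

    gene_ids: list[str]
    sample_ids: list[str]
    bits: np.ndarray  # genes x samples, uint8
    labels: np.ndarray
    cutpoints: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.bits = np.asarray(self.bits, dtype=np.uint8)
        self.labels = np.asarray(self.labels, dtype=int)
        if not np.isin(self.bits, (0, 1)).all():
            raise ValueError("binary matrix entries must be 0/1")

    def row(self, gene_id: str) -> np.ndarray:
        return self.bits[self.gene_ids.index(gene_id)]


def _entropy(labels: np.ndarray) -> float:
    """Class entropy in bits; 0*log0 defined as 0."""
    if labels.size == 0:
        return 0.0
    _, counts = np.unique(labels, return_counts=True)
    p = counts / labels.size
    return float(-(p * np.log2(p)).sum())


def discretize_gene(values: np.ndarray, labels: np.ndarray) -> DiscretizationResult:
    """Choose the information-gain-maximizing cutpoint for one gene.

    Candidate cutpoints are midpoints between consecutive *distinct* sorted
    values; ties on information gain resolve to the smallest midpoint.  A
    constant gene has no valid midpoint and yields all-zero bits with zero
    gain, flagged via ``constant``.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels, dtype=int)
    distinct = np.unique(values)
    if distinct.size < 2:
        return DiscretizationResult(
            cutpoint=float(distinct[0]), info_gain=0.0,
            bits=np.zeros(values.size, dtype=np.uint8), constant=True,
        )
    midpoints = (distinct[:-1] + distinct[1:]) / 2.0
    e_total = _entropy(labels)
    n = values.size
    best_gain, best_mu = -1.0, float(midpoints[0])
    for mu in midpoints:
        above = values > mu
        n_above = int(above.sum())
        e_split = (
            (n - n_above) / n * _entropy(labels[~above])
            + n_above / n * _entropy(labels[above])
        )
        gain = e_total - e_split
        if gain > best_gain:  # strict: ties keep the smallest midpoint
            best_gain, best_mu = gain, float(mu)
    bits = (values > best_mu).astype(np.uint8)
    return DiscretizationResult(cutpoint=best_mu, info_gain=max(best_gain, 0.0), bits=bits)


def discretize_matrix(m: LabeledExpressionMatrix) -> BinaryExpressionMatrix:
    """Row-wise :func:`discretize_gene`, preserving row and sample order."""
    bits = np.empty((len(m.row_ids), len(m.sample_ids)), dtype=np.uint8)
    cutpoints: dict[str, float] = {}
    n_constant = 0
    for i, rid in enumerate(m.row_ids):
        res = discretize_gene(m.values[i], m.labels)
        bits[i] = res.bits
        cutpoints[rid] = res.cutpoint
        n_constant += res.constant
    if n_constant:
        logger.warning("%d constant rows discretized to all-zero", n_constant)
    return BinaryExpressionMatrix(
        gene_ids=list(m.row_ids), sample_ids=list(m.sample_ids),
        bits=bits, labels=m.labels.copy(), cutpoints=cutpoints,
    )


def collapse_probes(
    b: BinaryExpressionMatrix,
    probe2gene: dict[str, set[str] | list[str] | str],
) -> BinaryExpressionMatrix:
    """Collapse probe-level rows to gene level by logical OR.

    A probe mapping to several genes contributes its bits to every one of
    them; unmapped probes are dropped with a warning.  Gene rows are emitted
    in sorted gene-id order (deterministic).
    """
    gene_rows: dict[str, np.ndarray] = {}
    dropped = 0
    for i, probe in enumerate(b.gene_ids):
        genes = probe2gene.get(probe)
        if not genes:
            dropped += 1
            continue
        if isinstance(genes, str):
            genes = [genes]
        for gene in genes:
            if gene in gene_rows:
                gene_rows[gene] = gene_rows[gene] | b.bits[i]
            else:
                gene_rows[gene] = b.bits[i].copy()
    if dropped:
        logger.warning("%d probes had no gene mapping and were dropped", dropped)
    if not gene_rows:
        logger.warning("probe collapsing produced an empty matrix")
    gene_ids = sorted(gene_rows)
    bits = (
        np.vstack([gene_rows[g] for g in gene_ids])
        if gene_ids else np.zeros((0, len(b.sample_ids)), dtype=np.uint8)
    )
    return BinaryExpressionMatrix(
        gene_ids=gene_ids, sample_ids=list(b.sample_ids),
        bits=bits, labels=b.labels.copy(),
    )


def merge_datasets(datasets: list[BinaryExpressionMatrix]) -> BinaryExpressionMatrix:
    """Concatenate independently discretized cohorts sample-wise.

    Gene rows align on the intersection of gene ids (genes missing from any
    cohort are dropped and reported); duplicate sample ids get a dataset
    prefix.
    """
    if not datasets:
        raise ValueError("no datasets to merge")
    shared = set(datasets[0].gene_ids)
    for d in datasets[1:]:
        shared &= set(d.gene_ids)
    dropped = set().union(*(d.gene_ids for d in datasets)) - shared
    if dropped:
        logger.warning("merge dropped %d genes absent from some dataset", len(dropped))
    gene_ids = sorted(shared)

    sample_ids: list[str] = []
    seen: set[str] = set()
    blocks, label_blocks = [], []
    for k, d in enumerate(datasets):
        idx = [d.gene_ids.index(g) for g in gene_ids]
        blocks.append(d.bits[idx] if gene_ids else
                      np.zeros((0, len(d.sample_ids)), dtype=np.uint8))
        label_blocks.append(d.labels)
        for s in d.sample_ids:
            if s in seen:
                logger.warning("duplicate sample id %r renamed with prefix ds%d", s, k)
                s = f"ds{k}:{s}"
            seen.add(s)
            sample_ids.append(s)
    return BinaryExpressionMatrix(
        gene_ids=gene_ids, sample_ids=sample_ids,
        bits=np.hstack(blocks), labels=np.concatenate(label_blocks),
    )


# ---------------------------------------------------------------------------
# file IO

def read_expression(
    expr_path: str | pathlib.Path,
    classes_path: str | pathlib.Path,
) -> LabeledExpressionMatrix:
    """Read a TSV/CSV matrix (first column = row id, header = sample ids) and
    a two-column (sample_id, class) label table."""
    sep = "," if str(expr_path).endswith(".csv") else "\t"
    df = pd.read_csv(expr_path, sep=sep, index_col=0)
    cls = pd.read_csv(classes_path, sep=None, engine="python", header=None,
                      names=["sample_id", "cls"], dtype={"sample_id": str})
    cls = cls.set_index("sample_id")["cls"]
    labels = cls.reindex(df.columns)
    if labels.isna().any():
        missing = list(df.columns[labels.isna()])
        raise ValueError(f"samples without class labels: {missing}")
    return LabeledExpressionMatrix(
        row_ids=[str(r) for r in df.index],
        sample_ids=[str(c) for c in df.columns],
        values=df.to_numpy(dtype=float),
        labels=labels.to_numpy(dtype=int),
    )


def read_probe_map(path: str | pathlib.Path) -> dict[str, set[str]]:
    """Two-column TSV probe -> gene id; multiple rows per probe accumulate."""
    df = pd.read_csv(path, sep="\t", header=None, names=["probe", "gene"], dtype=str)
    mapping: dict[str, set[str]] = {}
    for probe, gene in zip(df["probe"], df["gene"]):
        mapping.setdefault(probe, set()).add(gene)
    return mapping


def write_binary_matrix(b: BinaryExpressionMatrix, path: str | pathlib.Path) -> None:
    df = pd.DataFrame(b.bits, index=b.gene_ids, columns=b.sample_ids)
    with open(path, "w") as fh:
        fh.write("gene_id\t" + "\t".join(b.sample_ids) + "\n")
        fh.write("phenotype\t" + "\t".join(map(str, b.labels)) + "\n")
        df.to_csv(fh, sep="\t", header=False)
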