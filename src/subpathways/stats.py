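"""Phenotype-differential scoring of sub-paths and pathway significance.

Each sub-path row of the functional-status matrix is summarized by a 2x2
contingency table (functional / non-functional x phenotype-1 / phenotype-2)
from which four filters derive:

* coverage — fraction of each phenotype's samples where the sub-path is
  functional (default minimum 0.25);
* a two-sided Fisher exact p-value (default), or the hypergeometric point
  probability of the observed table, with Benjamini-Hochberg adjustment
  (fdr = p * m / i followed by step-up monotonicity enforcement);
* polarity r = (a/(a+c) - b/(b+d)) / (a/(a+c) + b/(b+d)), in [-1, 1],
  positive when the sub-path leans phenotype-1 (default |r| > 0.5);
* an optional fold-change filter on the ratio of functional fractions
  (default off; 2.0 when on).

Sub-paths functional in >= 90% of the samples of *both* phenotypes are
called SHARED: no differential power, but they bridge discriminant segments
in the colored network.  Pathway-level significance is an EASE-style
one-tailed over-representation p-value on the unique single relations of the
selected sub-paths, and a permutation test (class-size-preserving label
shuffles) provides empirical false-discovery estimates.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, field
from enum import Enum

import numpy as np
from scipy import stats as sps

from .decompose import SubPath
from .matching import SubPathMatrix

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ContingencyCounts:
    """a/b: functional counts in phenotype 1/2; c/d: non-functional."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("negative contingency count")

    @property
    def coverage1(self) -> float:
        return self.a / (self.a + self.c) if self.a + self.c else 0.0

    @property
    def coverage2(self) -> float:
        return self.b / (self.b + self.d) if self.b + self.d else 0.0


class SubPathCall(str, Enum):
    PHENOTYPE1 = "PHENOTYPE1"
    PHENOTYPE2 = "PHENOTYPE2"
    SHARED = "SHARED"
    NONE = "NONE"


@dataclass
class SubPathStats:
    subpath: SubPath
    counts: ContingencyCounts
    coverage1: float
    coverage2: float
    p_value: float
    p_raw_bh: float  # paper-style raw p*m/i before step-up
    fdr: float
    polarity: float
    fold_change: float
    call: SubPathCall


@dataclass(frozen=True)
class PathwayCounts:
    """EASE contingency: functional vs total relations, in vs out of pathway."""

    a_p: int  # functional unique single relations in the pathway
    b_p: int  # total relations in the pathway
    c_p: int  # functional relations in all other pathways
    d_p: int  # total relations in all other pathways

    def __post_init__(self) -> None:
        if self.a_p > self.b_p or self.c_p > self.d_p:
            raise ValueError("functional relation count exceeds total")

    @property
    def n(self) -> int:
        return self.b_p + self.d_p


@dataclass
class FilterConfig:
    """Thresholds of the sub-path selection filters (published defaults)."""

    min_coverage: float = 0.25
    alpha: float = 0.05
    use_fdr: bool = True
    min_abs_polarity: float = 0.5
    shared_threshold: float = 0.90
    min_fold_change: float | None = None  # 2.0 when enabled
    pvalue_method: str = "fisher_two_sided"  # or "point_hypergeom"
    min_samples_per_class: int = 5

    def __post_init__(self) -> None:
        for name in ("min_coverage", "alpha", "min_abs_polarity", "shared_threshold"):
            v = getattr(self, name)
            if not 0 < v <= 1.01:
                raise ValueError(f"{name}={v} outside (0, 1]")
        if self.min_fold_change is not None and self.min_fold_change < 1:
            raise ValueError("min_fold_change must be >= 1")


def contingency(row: np.ndarray, labels: np.ndarray) -> ContingencyCounts:
    """2x2 counts of one sub-path row against the phenotype labels."""
    row = np.asarray(row).astype(bool)
    labels = np.asarray(labels)
    is1 = labels == 1
    return ContingencyCounts(
        a=int((row & is1).sum()), b=int((row & ~is1).sum()),
        c=int((~row & is1).sum()), d=int((~row & ~is1).sum()),
    )


def polarity(counts: ContingencyCounts) -> float:
    """Polarity rank r in [-1, 1]; >0 leans phenotype 1, <0 phenotype 2.

    r = (f1 - f2) / (f1 + f2) with f1, f2 the functional fractions per
    phenotype; defined as 0 when both fractions are 0.
    """
    f1, f2 = counts.coverage1, counts.coverage2
    if f1 + f2 == 0:
        return 0.0
    return (f1 - f2) / (f1 + f2)


def fold_change(counts: ContingencyCounts) -> float:
    """Ratio max(f1,f2)/min(f1,f2) of functional fractions; inf when the
    smaller is 0 and the larger positive; nan when both are 0."""
    f1, f2 = counts.coverage1, counts.coverage2
    lo, hi = min(f1, f2), max(f1, f2)
    if hi == 0:
        return float("nan")
    if lo == 0:
        return float("inf")
    return hi / lo


def subpath_pvalue(
    counts: ContingencyCounts, method: str = "fisher_two_sided"
) -> float:
    """Fisher exact two-sided p (default), or the single-table hypergeometric
    point probability.  Any zero margin yields p = 1."""
    a, b, c, d = counts.a, counts.b, counts.c, counts.d
    if min(a + b, c + d, a + c, b + d) == 0:
        return 1.0
    if method == "point_hypergeom":
        # P(X = a) with margins fixed: X ~ Hypergeom(N=a+b+c+d, K=a+b, n=a+c)
        return float(sps.hypergeom.pmf(a, a + b + c + d, a + b, a + c))
    if method == "fisher_two_sided":
        return float(sps.fisher_exact([[a, b], [c, d]], alternative="two-sided")[1])
    raise ValueError(f"unknown p-value method {method!r}")


def bh_adjust(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted values.

    Raw p*m/i in ascending-p rank order, then cumulative minimum from the
    largest rank down (monotone non-decreasing in rank), capped at 1.  Tied
    p-values share the outcome because step-up equalizes them.
    """
    p = np.asarray(pvalues, dtype=float)
    m = p.size
    if m == 0:
        return p.copy()
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adjusted, 1.0)
    return out


def bh_raw(pvalues: np.ndarray) -> np.ndarray:
    """The raw p*m/i values without step-up (reported alongside)."""
    p = np.asarray(pvalues, dtype=float)
    m = p.size
    if m == 0:
        return p.copy()
    order = np.argsort(p, kind="stable")
    ranks = np.empty(m)
    ranks[order] = np.arange(1, m + 1)
    # ties take the largest rank in their group (standard convention)
    for val in np.unique(p):
        mask = p == val
        ranks[mask] = ranks[mask].max()
    return p * m / ranks


def classify_subpaths(m: SubPathMatrix, cfg: FilterConfig | None = None) -> list[SubPathStats]:
    """Score and call every sub-path row of the matrix.

    SHARED when both coverages reach ``shared_threshold``; otherwise
    PHENOTYPE1 (resp. 2) when polarity exceeds +``min_abs_polarity`` (resp.
    falls below the negative), the matching coverage reaches ``min_coverage``,
    the significance filter passes, and the optional fold-change filter
    passes; NONE otherwise.  With fewer than ``min_samples_per_class``
    samples in either class the p/fdr filter is skipped with a warning.
    """
    cfg = cfg or FilterConfig()
    labels = np.asarray(m.labels)
    n1, n2 = int((labels == 1).sum()), int((labels == 2).sum())
    use_p = min(n1, n2) >= cfg.min_samples_per_class
    if not use_p and m.bits.shape[0]:
        logger.warning(
            "fewer than %d samples in a class (%d vs %d): p-value filter skipped",
            cfg.min_samples_per_class, n1, n2)

    all_counts = [contingency(row, labels) for row in m.bits]
    pvals = np.array([subpath_pvalue(c, cfg.pvalue_method) for c in all_counts])
    fdrs = bh_adjust(pvals)
    raws = bh_raw(pvals)

    out: list[SubPathStats] = []
    for sp, counts, p, fdr_v, raw in zip(m.subpaths, all_counts, pvals, fdrs, raws):
        pol = polarity(counts)
        fc = fold_change(counts)
        cov1, cov2 = counts.coverage1, counts.coverage2
        if cov1 >= cfg.shared_threshold and cov2 >= cfg.shared_threshold:
            call = SubPathCall.SHARED
        else:
            sig = True
            if use_p:
                sig = (fdr_v if cfg.use_fdr else p) < cfg.alpha
            fc_ok = True
            if cfg.min_fold_change is not None:
                fc_ok = fc >= cfg.min_fold_change  # nan compares False
            if pol > cfg.min_abs_polarity and cov1 >= cfg.min_coverage and sig and fc_ok:
                call = SubPathCall.PHENOTYPE1
            elif pol < -cfg.min_abs_polarity and cov2 >= cfg.min_coverage and sig and fc_ok:
                call = SubPathCall.PHENOTYPE2
            else:
                call = SubPathCall.NONE
        out.append(SubPathStats(
            subpath=sp, counts=counts, coverage1=cov1, coverage2=cov2,
            p_value=float(p), p_raw_bh=float(raw), fdr=float(fdr_v),
            polarity=pol, fold_change=fc, call=call,
        ))
    return out


def pathway_pvalue(pc: PathwayCounts) -> float:
    """EASE-style one-tailed over-representation p-value.

    The in-pathway functional count is decremented by one (the conservative
    EASE correction), and the p-value is the upper-tail hypergeometric
    probability of drawing >= a_p - 1 functional relations in b_p draws from
    n = b_p + d_p relations of which (a_p - 1) + c_p are functional.  A
    pathway with a single functional relation gets p = 1.
    """
    if pc.a_p == 0:
        return 1.0
    k = pc.a_p - 1
    total_functional = k + pc.c_p
    # P(X >= k) = sf(k - 1)
    return float(sps.hypergeom.sf(k - 1, pc.n, total_functional, pc.b_p))


@dataclass
class PathwayRanking:
    pathway_id: str
    p_value: float
    counts: PathwayCounts
    n_phenotype1: int
    n_phenotype2: int
    n_shared: int


def functional_relations(
    stats: list[SubPathStats],
    calls: tuple[SubPathCall, ...] = (
        SubPathCall.PHENOTYPE1, SubPathCall.PHENOTYPE2, SubPathCall.SHARED),
) -> set:
    """Unique single relations of the sub-paths whose call is in ``calls``,
    deduplicated by (source, target, semantic class) regardless of phenotype
    inclination."""
    rels = set()
    for st in stats:
        if st.call in calls:
            rels.update(e.key() for e in st.subpath.edges)
    return rels


def rank_pathways(
    per_pathway: dict[str, tuple[list[SubPathStats], int]],
    relation_source: tuple[SubPathCall, ...] = (
        SubPathCall.PHENOTYPE1, SubPathCall.PHENOTYPE2, SubPathCall.SHARED),
) -> list[PathwayRanking]:
    """Rank pathways by EASE p-value ascending, ties by pathway id.

    ``per_pathway`` maps pathway id -> (sub-path stats, total relation count
    of the pathway).  Functional relations of *all* other pathways form the
    background margin.
    """
    func = {pid: functional_relations(stats, relation_source)
            for pid, (stats, _) in per_pathway.items()}
    totals = {pid: total for pid, (_, total) in per_pathway.items()}
    rankings = []
    for pid, (stats, _) in per_pathway.items():
        a_p = len(func[pid])
        b_p = totals[pid]
        c_p = sum(len(func[q]) for q in per_pathway if q != pid)
        d_p = sum(totals[q] for q in per_pathway if q != pid)
        pc = PathwayCounts(a_p=min(a_p, b_p), b_p=b_p, c_p=min(c_p, d_p), d_p=d_p)
        rankings.append(PathwayRanking(
            pathway_id=pid, p_value=pathway_pvalue(pc), counts=pc,
            n_phenotype1=sum(s.call == SubPathCall.PHENOTYPE1 for s in stats),
            n_phenotype2=sum(s.call == SubPathCall.PHENOTYPE2 for s in stats),
            n_shared=sum(s.call == SubPathCall.SHARED for s in stats),
        ))
    rankings.sort(key=lambda r: (r.p_value, r.pathway_id))
    return rankings


@dataclass
class PermutationResult:
    n_perm: int
    observed_selected: int
    mean_null_selected: float
    empirical_fdr: float  # mean null selected / observed selected; nan if 0 observed
    null_frequency: np.ndarray = field(repr=False)  # per sub-path


def permutation_fdr(
    m: SubPathMatrix,
    cfg: FilterConfig | None = None,
    n_perm: int = 1000,
    seed: int = 0,
) -> PermutationResult:
    """Label-shuffling robustness test.

    Each permutation shuffles the phenotype labels (class sizes preserved by
    construction) and re-runs the selection; the empirical FDR of the
    observed discriminant set is the mean null selected count over the
    observed selected count, and each sub-path additionally gets its null
    selection frequency.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    cfg = cfg or FilterConfig()
    rng = np.random.default_rng(seed)
    discriminant = (SubPathCall.PHENOTYPE1, SubPathCall.PHENOTYPE2)

    observed = classify_subpaths(m, cfg)
    obs_sel = sum(s.call in discriminant for s in observed)

    null_counts = np.zeros(len(m.subpaths))
    total = np.zeros(n_perm)
    base = SubPathMatrix(subpaths=m.subpaths, sample_ids=m.sample_ids,
                         bits=m.bits, labels=m.labels)
    for k in range(n_perm):
        base.labels = rng.permutation(m.labels)
        null = classify_subpaths(base, cfg)
        sel = np.array([s.call in discriminant for s in null])
        null_counts += sel
        total[k] = sel.sum()
    mean_null = float(total.mean())
    if obs_sel == 0:
        logger.warning("no observed selections; empirical FDR not applicable")
        fdr = float("nan")
    else:
        fdr = mean_null / obs_sel
    return PermutationResult(
        n_perm=n_perm, observed_selected=obs_sel,
        mean_null_selected=mean_null, empirical_fdr=fdr,
        null_frequency=null_counts / n_perm,
    )


def write_stats_tsv(stats: list[SubPathStats], path) -> None:
    cols = ("pathway_id\tsubpath\ta\tb\tc\td\tcoverage1\tcoverage2\t"
            "p_value\tfdr\tpolarity\tfold_change\tcall\n")
    with open(path, "w") as fh:
        fh.write(cols)
        for s in stats:
            c = s.counts
            fh.write(
                f"{s.subpath.pathway_id}\t{s.subpath.label()}\t{c.a}\t{c.b}\t"
                f"{c.c}\t{c.d}\t{s.coverage1:.6g}\t{s.coverage2:.6g}\t"
                f"{s.p_value:.6g}\t{s.fdr:.6g}\t{s.polarity:.6g}\t"
                f"{s.fold_change:.6g}\t{s.call.value}\n")


def write_ranking_tsv(rankings: list[PathwayRanking], path) -> None:
    with open(path, "w") as fh:
        fh.write("pathway_id\tp_value\ta_p\tb_p\tn_phenotype1\tn_phenotype2\tn_shared\n")
        for r in rankings:
            fh.write(f"{r.pathway_id}\t{r.p_value:.6g}\t{r.counts.a_p}\t"
                     f"{r.counts.b_p}\t{r.n_phenotype1}\t{r.n_phenotype2}\t{r.n_shared}\n")
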