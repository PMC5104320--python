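"""End-to-end driver: discretize -> decompose -> match -> filter -> rank -> export.

`run` reads a directory of KGML pathways, a continuous expression matrix and
per-sample phenotype labels, and writes the sub-path functional matrix
(TSV + ARFF), a per-sub-path stats table, a p-value-ranked pathway table,
per-pathway colored networks (GraphML + Cytoscape JSON) and a run report
with stage counts.  All randomness (the optional permutation test) is seeded
through the config, so identical config + seed reproduce byte-identical
outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import pathlib
from dataclasses import dataclass, field

from . import coloring, decompose, expression, matching, pathway_io, stats

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    pathway_dir: str
    expr_path: str
    classes_path: str
    output_dir: str
    probe_map_path: str | None = None
    filters: stats.FilterConfig = field(default_factory=stats.FilterConfig)
    max_path_len: int | None = None
    n_permutations: int | None = None
    seed: int = 0


@dataclass
class RunReport:
    n_pathways: int = 0
    n_genes: int = 0
    n_samples: int = 0
    n_subpaths_enumerated: int = 0
    n_subpaths_evaluable: int = 0
    n_selected_phenotype1: int = 0
    n_selected_phenotype2: int = 0
    n_shared: int = 0
    thresholds: dict = field(default_factory=dict)
    permutation: dict | None = None

    def validate(self) -> None:
        assert self.n_subpaths_evaluable <= self.n_subpaths_enumerated
        selected = (self.n_selected_phenotype1 + self.n_selected_phenotype2
                    + self.n_shared)
        assert selected <= self.n_subpaths_evaluable


def run(cfg: RunConfig) -> RunReport:
    out = pathlib.Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    pathway_files = sorted(pathlib.Path(cfg.pathway_dir).glob("*.xml")) + \
        sorted(pathlib.Path(cfg.pathway_dir).glob("*.kgml"))
    if not pathway_files:
        raise FileNotFoundError(f"no pathways found in {cfg.pathway_dir}")

    m = expression.read_expression(cfg.expr_path, cfg.classes_path)
    binary = expression.discretize_matrix(m)
    if cfg.probe_map_path:
        binary = expression.collapse_probes(
            binary, expression.read_probe_map(cfg.probe_map_path))

    report = RunReport(
        n_genes=len(binary.gene_ids), n_samples=len(binary.sample_ids),
        thresholds=dataclasses.asdict(cfg.filters),
    )

    all_stats: list[stats.SubPathStats] = []
    per_pathway: dict[str, tuple[list[stats.SubPathStats], int]] = {}
    stats_by_pathway: dict[str, list[stats.SubPathStats]] = {}
    graphs: dict[str, object] = {}
    matrices: list[matching.SubPathMatrix] = []

    for pf in pathway_files:
        g = pathway_io.parse_kgml(pf)
        g = pathway_io.normalize_graph(g)
        subpaths = decompose.enumerate_subpaths(g, max_len=cfg.max_path_len)
        spm = matching.build_subpath_matrix(subpaths, binary, graph=g)
        report.n_pathways += 1
        report.n_subpaths_enumerated += len(subpaths)
        report.n_subpaths_evaluable += len(spm.subpaths)
        st = stats.classify_subpaths(spm, cfg.filters)
        n_rel = sum(e.semantic_class != pathway_io.SemanticClass.UNKNOWN
                    for e in g.edges)
        per_pathway[g.pathway_id] = (st, n_rel)
        stats_by_pathway[g.pathway_id] = st
        graphs[g.pathway_id] = g
        all_stats.extend(st)
        matrices.append(spm)

    merged = _concat_matrices(matrices, binary)
    matching.write_subpath_matrix_tsv(merged, out / "subpath_matrix.tsv")
    matching.write_subpath_matrix_arff(merged, out / "subpath_matrix.arff")
    stats.write_stats_tsv(all_stats, out / "subpath_stats.tsv")

    rankings = stats.rank_pathways(per_pathway)
    stats.write_ranking_tsv(rankings, out / "pathway_ranking.tsv")

    for pid, g in graphs.items():
        cmap = coloring.color_edges(stats_by_pathway[pid], g)
        pathway_io.write_network(g, out / f"{pid}_colored",
                                 edge_colors=cmap.entries)
    ig, icmap = coloring.build_integrated_network(stats_by_pathway)
    if ig.edges:
        pathway_io.write_network(ig, out / "integrated_network",
                                 edge_colors=icmap.entries)

    for s in all_stats:
        if s.call == stats.SubPathCall.PHENOTYPE1:
            report.n_selected_phenotype1 += 1
        elif s.call == stats.SubPathCall.PHENOTYPE2:
            report.n_selected_phenotype2 += 1
        elif s.call == stats.SubPathCall.SHARED:
            report.n_shared += 1

    if cfg.n_permutations:
        perm = stats.permutation_fdr(merged, cfg.filters,
                                     n_perm=cfg.n_permutations, seed=cfg.seed)
        report.permutation = {
            "n_perm": perm.n_perm,
            "observed_selected": perm.observed_selected,
            "mean_null_selected": perm.mean_null_selected,
            "empirical_fdr": perm.empirical_fdr,
        }

    report.validate()
    with open(out / "run_report.json", "w") as fh:
        json.dump(dataclasses.asdict(report), fh, indent=1, sort_keys=True)
    logger.info("run complete: %d pathways, %d sub-paths, %d selected",
                report.n_pathways, report.n_subpaths_enumerated,
                report.n_selected_phenotype1 + report.n_selected_phenotype2)
    return report


def _concat_matrices(
    matrices: list[matching.SubPathMatrix],
    binary: expression.BinaryExpressionMatrix,
) -> matching.SubPathMatrix:
    import numpy as np

    subpaths = [sp for m in matrices for sp in m.subpaths]
    bits = (np.vstack([m.bits for m in matrices if m.bits.size or m.subpaths])
            if subpaths else np.zeros((0, len(binary.sample_ids)), dtype=np.uint8))
    return matching.SubPathMatrix(
        subpaths=subpaths, sample_ids=list(binary.sample_ids), bits=bits,
        labels=binary.labels.copy(),
        n_unevaluable=sum(m.n_unevaluable for m in matrices),
    )
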