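"""Full pipeline on a synthetic cohort with a known planted sub-path.

Generates a 12-gene, 40-sample two-phenotype cohort in which the chain
P1 -> P2 -> P3 -| P4 is switched on in 90% of phenotype-1 samples and off
elsewhere, runs discretization, decomposition, matching and filtering, and
finishes with a label-permutation robustness test.  The planted chain should
come out as a phenotype-1 discriminant with a near-zero null selection
frequency; the set-level empirical FDR estimates how many of the selected
sub-paths a label-shuffled null would produce.
"""

from subpathways import build_subpath_matrix, classify_subpaths, enumerate_subpaths
from subpathways.expression import discretize_matrix
from subpathways.stats import SubPathCall, permutation_fdr
from subpathways.synth import SyntheticCohortSpec, make_planted_cohort, planted_subpath

spec = SyntheticCohortSpec(signal_fraction=0.9, noise_rate=0.02, seed=42)
g, cohort = make_planted_cohort(spec)
binary = discretize_matrix(cohort)
m = build_subpath_matrix(enumerate_subpaths(g), binary, graph=g)
stats = classify_subpaths(m)

planted = planted_subpath(spec)
print(f"cohort: {len(cohort.row_ids)} genes x {len(cohort.sample_ids)} samples; "
      f"{len(m.subpaths)} sub-paths evaluated")
for s in stats:
    mark = "  <-- planted" if s.subpath.nodes == planted.nodes else ""
    print(f"{s.subpath.label():22s} polarity {s.polarity:+.2f}  "
          f"p {s.p_value:.2e}  fdr {s.fdr:.2e}  {s.call.value}{mark}")

res = permutation_fdr(m, n_perm=200, seed=1)
idx = next(i for i, sp in enumerate(m.subpaths) if sp.nodes == planted.nodes)
print(f"\npermutation test ({res.n_perm} label shuffles): "
      f"{res.observed_selected} observed discriminants, "
      f"mean {res.mean_null_selected:.2f} under the null "
      f"-> empirical FDR {res.empirical_fdr:.3f}")
print(f"planted sub-path selected in {res.null_frequency[idx]:.1%} of null shuffles")
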