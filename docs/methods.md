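# Methods

This note documents the models, numerical choices and limitations behind
`subpathways`, in the order the pipeline runs.

## Pathway model

A pathway is a typed directed multigraph.  Nodes are KGML entries: genes
(with one or more Entrez-style identifiers), gene groups, compounds, or
links to other pathway maps.  Edges are relations carrying their raw KGML
subtype names plus one collapsed *semantic class*:

| class            | KGML subtypes                                                | semantics        |
|------------------|--------------------------------------------------------------|------------------|
| activation-like  | activation, expression, indirect effect, (de)phosphorylation | src AND tgt      |
| inhibition-like  | inhibition, ubiquitination                                   | src XOR tgt      |
| neutral          | binding/association, dissociation                            | always functional|
| unknown          | anything else (incl. compound-mediated)                      | excluded         |

Subtype-combination tie-breaks: inhibition and ubiquitination dominate an
accompanying activation arrow; a bare (de)phosphorylation counts as
activation.  Compound-mediated relations get no invented semantics — they
are classified unknown and never traversed.  Normalisation expands each
group node into its members (every member inherits all group edges, in
component order, so edge order stays deterministic), removes compound nodes
without bridging through them, and keeps map nodes as terminal annotations
that decomposition never enters.  Normalisation is idempotent.

## Discretization

Supervised, per gene.  Values are sorted; candidate cutpoints are midpoints
between consecutive **distinct** values (duplicates yield no midpoint, so a
value can never sit exactly on a cutpoint; if it did, it would be assigned
0).  The cutpoint maximizing IG(S, μ) = E(S) − E(S, μ) is selected, with
entropies in log base 2 (only the argmax matters, so the base is a
reporting choice) and 0·log 0 ≡ 0.  Ties on IG resolve to the smallest
midpoint — deterministic output.  Constant genes have no midpoint: all-zero
bits, zero gain, flagged.  Rows with non-finite values are dropped with a
warning rather than imputed.  Multi-probe genes collapse by logical OR of
probe bits; a probe mapping to several genes contributes to all of them.
Independently discretized cohorts merge sample-wise on the intersection of
their gene sets (no re-discretization of the merged data).

A structural caveat: an exhaustive IG-argmax cutpoint is only informative
for genes whose *marginal* distribution differs between the phenotypes.  A
gene that matters only jointly (e.g. symmetric involvement in both classes)
gives the supervised search nothing to optimize, and with a few dozen
samples the argmax can legitimately sit inside a cluster of values rather
than in a between-state gap.  This is inherent to the criterion, not an
implementation artifact, and shapes the synthetic-cohort design below.

## Decomposition

Every simple directed path of ≥ 1 edge between gene nodes is a sub-path;
overlapping prefixes/suffixes/interior segments are emitted separately.
Neutral edges are traversed in both directions; parallel edges of different
classes yield distinct sub-paths.  Cycles are handled by the simple-path
constraint (no node revisited), the only finite reading of "all paths".
Enumeration streams from a DFS (counting never materializes paths) and the
materialized list is sorted lexicographically by node sequence — stable
across runs.  `max_len` (edges per sub-path) is unlimited by default; dense
pathways grow combinatorially, so the CLI exposes `--max-path-len`.

## Matching

Each relation is scored on the **measured** bits of its two genes — no
regulatory state propagates along the chain — and the per-relation truth
values are AND-folded left to right.  This resolves the apparent paradox of
an inhibition satisfied by a down-regulated source: the downstream relations
are still judged on measured bits.  A node with several gene ids takes the
OR of its member rows (consistent with probe collapsing).  Sub-paths
touching an unmeasured gene are excluded and counted, never imputed.
Matching is fully vectorized over samples and bit-for-bit reproducible.

## Selection statistics

Per sub-path, the 2×2 table (a, b, c, d) of functional/non-functional ×
phenotype-1/2 yields:

* coverage₁ = a/(a+c), coverage₂ = b/(b+d);
* polarity r = (cov₁ − cov₂)/(cov₁ + cov₂) ∈ [−1, 1], antisymmetric under
  phenotype swap, defined 0 when both coverages vanish (such rows fail the
  coverage filter anyway);
* fold change max/min of the coverages (∞ when one is zero, undefined when
  both are);
* a p-value.  The default is the standard two-sided Fisher exact test; the
  single-table hypergeometric point probability
  (a+b)!(c+d)!(a+c)!(b+d)! / (n! a! b! c! d!) is available as
  `point_hypergeom` — the two differ, and both are exposed because the
  point probability is sometimes quoted as if it were the two-tailed test.
  Any zero margin gives p = 1.
* Benjamini–Hochberg: raw p·m/i values are reported, but the *fdr* used for
  filtering applies the step-up (cumulative minimum from the largest rank,
  capped at 1), since raw p·m/i is not monotone and hence not a valid
  adjusted value.  Ties share the largest rank of their group.

Call logic: SHARED when both coverages reach the shared threshold (default
0.90); otherwise PHENOTYPE1/2 when the signed polarity clears ±0.5, the
matching coverage reaches 0.25, the significance filter (fdr by default,
α = 0.05) passes, and the optional fold-change filter (off by default, 2.0
when enabled) passes; NONE otherwise.  With fewer than five samples in
either class the exact test is unreliable, so the p/fdr filter is skipped
with a warning and coverage/polarity decide alone.

**Pathway significance.**  The unique single relations — keyed by (source,
target, class) — of all sub-paths passing the filters, regardless of
phenotype inclination, are counted per pathway (a_p) against the pathway's
total relations (b_p) and the same counts pooled over all other pathways
(c_p, d_p).  The p-value is the EASE-style one-tailed upper hypergeometric
tail after decrementing a_p by one, which deliberately zeroes out
single-relation pathways; a_p = 0 gives p = 1.  Pathways are ranked by
ascending p, ties broken by id.  Which calls feed a_p is configurable
(`relation_source`); the default takes discriminant and shared sub-paths.

**Permutation test.**  Labels are shuffled (a permutation of the label
vector preserves class sizes by construction), the selection re-run, and
two figures reported: the set-level empirical FDR = mean null selected
count / observed selected count (undefined when nothing is selected), and
each sub-path's null selection frequency.  Seeded generator throughout;
identical config + seed reproduce byte-identical pipeline outputs.

## Synthetic cohorts

`synth.make_planted_cohort` emulates a regulatory program switched **on** in
one phenotype and **off** in the other.  A chain (default
P1 → P2 → P3 ⊣ P4) is planted among filler noise genes; in
`signal_fraction` of phenotype-1 samples (default 0.9) the chain carries its
functional bit pattern, all other samples sit near the chain's *inactive*
state — the bitwise complement of that pattern (activation members down,
inhibition target up) — perturbed per gene at `baseline_flip` (default
0.10, a leaky off state) and resampled if the perturbation happens to make
the chain functional.  Each planted bit then flips with `noise_rate`
(default 0.02), and continuous values are drawn from two Gaussians
(μ_low = 0, μ_high = 3, σ = 0.5; states well separated relative to σ).
Filler genes are fair-coin bits.  The complement-state background is what
gives every planted gene the marginal differential expression that
supervised discretization needs (see the caveat above); with a fair-coin
background the per-gene cutpoint search has almost no class signal to work
with and the planted pattern does not survive binarization.

What the generator does **not** emulate: probe-level noise structure,
correlated genes outside the chain, batch effects, class imbalance, or
RNA-seq count distributions.  Passing the recovery tests therefore shows
the pipeline is correct and sensitive under clean two-state expression —
not that real cohorts will yield comparable recovery rates.

The frozen figure fixtures (`make_fig_dummy`) are binary grids derived once
by constraint satisfaction so that every documented functional-set claim
about the two worked examples holds exactly; they are data, identical on
every call.

## Problem sizes

The default test suite and the acceptance script run at desk scale: random
graphs ≤ 8 nodes against a brute-force enumerator (200 graphs), exact
Fisher/EASE checks against rational-arithmetic enumeration over small
tables, 500–1000 random genes against an exhaustive IG scan, 100 planted
cohorts of 40 samples for recovery, and 200–1000 label permutations on
matrices of ~10–50 sub-paths.  These sizes were chosen so the entire
verification runs in minutes on one CPU while still exercising every code
path; all of them scale up by parameter only.

## Known limitations

* Only two-phenotype designs; multi-class labels are rejected.
* No normalization, batch correction or missing-value imputation — inputs
  are taken as-is.
* Compound-mediated and otherwise unmapped relations are excluded rather
  than modelled; dissociation edges are allowed mid-path like binding.
* KGML is the only pathway input format (GraphML/Cytoscape JSON are
  outputs).
* Selection is a filter, not an inference: it yields highly predictive
  sub-paths, with no causal claim attached.
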