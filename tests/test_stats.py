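import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from conftest import (
    ease_upper_tail_enum,
    fisher_two_sided_enum,
    hypergeom_point,
)
from subpathways import synth
from subpathways.decompose import enumerate_subpaths
from subpathways.expression import discretize_matrix
from subpathways.matching import SubPathMatrix, build_subpath_matrix
from subpathways.stats import (
    ContingencyCounts,
    FilterConfig,
    PathwayCounts,
    SubPathCall,
    bh_adjust,
    bh_raw,
    classify_subpaths,
    contingency,
    fold_change,
    pathway_pvalue,
    permutation_fdr,
    polarity,
    rank_pathways,
    subpath_pvalue,
)

counts_st = st.tuples(st.integers(0, 15), st.integers(0, 15),
                      st.integers(0, 15), st.integers(0, 15)).filter(
    lambda t: t[0] + t[2] > 0 and t[1] + t[3] > 0)


class TestContingency:
    def test_direct_count(self):
        c = contingency([1, 1, 0, 0, 0], [1, 1, 1, 2, 2])
        assert (c.a, c.b, c.c, c.d) == (2, 0, 1, 2)

    def test_all_ones_row(self):
        c = contingency([1, 1, 1, 1], [1, 1, 2, 2])
        assert c.c == c.d == 0

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_per_sample_loop(self, seed):
        rng = np.random.default_rng(seed)
        row = rng.integers(0, 2, 20)
        labels = rng.permutation([1] * 12 + [2] * 8)
        c = contingency(row, labels)
        a = sum(1 for r, l in zip(row, labels) if r and l == 1)
        b = sum(1 for r, l in zip(row, labels) if r and l == 2)
        assert (c.a, c.b) == (a, b)
        assert c.a + c.b + c.c + c.d == 20


class TestPolarity:
    def test_perfect_phenotype1(self):
        assert polarity(ContingencyCounts(3, 0, 0, 3)) == 1.0

    def test_equal_coverages_zero(self):
        assert polarity(ContingencyCounts(2, 2, 2, 2)) == 0.0

    def test_literal_arithmetic(self):
        val = polarity(ContingencyCounts(5, 1, 5, 9))
        assert val == pytest.approx((0.5 - 0.1) / (0.5 + 0.1))

    def test_both_zero_defined_as_zero(self):
        assert polarity(ContingencyCounts(0, 0, 3, 3)) == 0.0

    @given(counts_st)
    @settings(max_examples=200, deadline=None)
    def test_phenotype_swap_antisymmetry_and_bounds(self, t):
        a, b, c, d = t
        x = polarity(ContingencyCounts(a, b, c, d))
        y = polarity(ContingencyCounts(b, a, d, c))
        assert x == pytest.approx(-y)
        assert -1 <= x <= 1


class TestFoldChange:
    def test_direct_ratio(self):
        assert fold_change(ContingencyCounts(6, 3, 4, 7)) == pytest.approx(2.0)

    def test_equal_fractions_is_one(self):
        assert fold_change(ContingencyCounts(3, 3, 3, 3)) == 1.0

    def test_zero_denominator_infinite(self):
        assert math.isinf(fold_change(ContingencyCounts(3, 0, 1, 4)))

    def test_both_zero_undefined(self):
        assert math.isnan(fold_change(ContingencyCounts(0, 0, 3, 3)))


class TestSubpathPvalue:
    def test_most_probable_table_is_one(self):
        assert subpath_pvalue(ContingencyCounts(5, 5, 5, 5)) == pytest.approx(1.0)

    def test_point_hypergeom_factorial_oracle(self):
        p = subpath_pvalue(ContingencyCounts(5, 0, 0, 5), method="point_hypergeom")
        assert p == pytest.approx(1 / math.comb(10, 5))

    def test_zero_margin_is_one(self):
        assert subpath_pvalue(ContingencyCounts(0, 0, 5, 5)) == 1.0

    @pytest.mark.parametrize("seed", range(25))
    def test_fisher_matches_exhaustive_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        a, b, c, d = (int(x) for x in rng.integers(0, 12, 4))
        if a + c == 0 or b + d == 0:
            return
        got = subpath_pvalue(ContingencyCounts(a, b, c, d))
        assert got == pytest.approx(fisher_two_sided_enum(a, b, c, d), abs=1e-9)

    @given(counts_st)
    @settings(max_examples=100, deadline=None)
    def test_phenotype_swap_invariance(self, t):
        a, b, c, d = t
        assert subpath_pvalue(ContingencyCounts(a, b, c, d)) == pytest.approx(
            subpath_pvalue(ContingencyCounts(b, a, d, c)), abs=1e-12)

    @given(counts_st)
    @settings(max_examples=100, deadline=None)
    def test_point_probability_matches_rational_oracle(self, t):
        a, b, c, d = t
        got = subpath_pvalue(ContingencyCounts(a, b, c, d), "point_hypergeom")
        assert got == pytest.approx(float(hypergeom_point(a, b, c, d)), abs=1e-12)


class TestBhAdjust:
    def test_raw_formula_direct_substitution(self):
        # p=0.01 at rank 10 of 100 -> raw adjusted 0.1
        p = np.concatenate([np.linspace(1e-4, 0.0099, 9), [0.01],
                            np.linspace(0.02, 1.0, 90)])
        raw = bh_raw(p)
        assert raw[9] == pytest.approx(0.01 * 100 / 10)

    def test_single_p_unchanged(self):
        assert bh_adjust([0.37])[0] == pytest.approx(0.37)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_statsmodels_reference(self, seed):
        from statsmodels.stats.multitest import multipletests
        rng = np.random.default_rng(seed)
        p = rng.random(50)
        expected = multipletests(p, method="fdr_bh")[1]
        assert np.allclose(bh_adjust(p), expected)

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=60))
    @settings(max_examples=100, deadline=None)
    def test_stepup_monotone_and_at_least_raw(self, ps):
        p = np.array(ps)
        adj = bh_adjust(p)
        order = np.argsort(p, kind="stable")
        assert np.all(np.diff(adj[order]) >= -1e-12)
        assert np.all(adj >= p - 1e-12)
        assert np.all(adj <= 1.0)


def _matrix_from_rows(rows, labels):
    rows = np.atleast_2d(np.array(rows, dtype=np.uint8))
    sps = []
    from subpathways.decompose import SubPath
    from subpathways.graph import SemanticClass, make_edge
    for i in range(rows.shape[0]):
        sps.append(SubPath(nodes=(f"G{i+1}", f"G{i+2}"),
                           edges=(make_edge(f"G{i+1}", f"G{i+2}",
                                            SemanticClass.ACTIVATION_LIKE),),
                           pathway_id="t"))
    return SubPathMatrix(subpaths=sps,
                         sample_ids=[f"s{j}" for j in range(rows.shape[1])],
                         bits=rows, labels=np.array(labels))


class TestClassifySubpaths:
    def test_fig11_perfect_discriminator_called_phenotype1(self, fig11):
        g, b = fig11
        m = build_subpath_matrix(enumerate_subpaths(g), b, graph=g)
        cfg = FilterConfig(use_fdr=False)
        by_nodes = {s.subpath.nodes: s for s in classify_subpaths(m, cfg)}
        s = by_nodes[("B", "D", "C")]
        assert s.polarity == 1.0
        assert s.call == SubPathCall.PHENOTYPE1

    def test_all_ones_row_is_shared(self):
        m = _matrix_from_rows([[1] * 10], [1] * 5 + [2] * 5)
        assert classify_subpaths(m)[0].call == SubPathCall.SHARED

    def test_shared_threshold_above_one_never_shared(self):
        m = _matrix_from_rows([[1] * 10], [1] * 5 + [2] * 5)
        cfg = FilterConfig(shared_threshold=1.01)
        assert classify_subpaths(m, cfg)[0].call != SubPathCall.SHARED

    def test_phenotype2_symmetry(self):
        row = [0] * 8 + [1] * 8
        m = _matrix_from_rows([row], [1] * 8 + [2] * 8)
        s = classify_subpaths(m, FilterConfig(use_fdr=False))[0]
        assert s.polarity == -1.0
        assert s.call == SubPathCall.PHENOTYPE2

    def test_small_classes_skip_pvalue_filter(self):
        # 3v3: Fisher p can never reach 0.05, polarity filter must decide
        m = _matrix_from_rows([[1, 1, 1, 0, 0, 0]], [1, 1, 1, 2, 2, 2])
        s = classify_subpaths(m, FilterConfig(use_fdr=False))[0]
        assert s.call == SubPathCall.PHENOTYPE1

    def test_fold_change_filter_blocks(self):
        row = [1] * 6 + [1, 1, 1, 0]  # f1=1.0, f2=0.75 -> fc 1.33
        m = _matrix_from_rows([row], [1] * 6 + [2] * 4)
        cfg = FilterConfig(min_fold_change=2.0, use_fdr=False,
                           shared_threshold=1.0)
        assert classify_subpaths(m, cfg)[0].call == SubPathCall.NONE

    def test_planted_cohort_recovered(self):
        spec = synth.SyntheticCohortSpec(seed=42)
        g, cohort = synth.make_planted_cohort(spec)
        b = discretize_matrix(cohort)
        m = build_subpath_matrix(enumerate_subpaths(g), b, graph=g)
        by_nodes = {s.subpath.nodes: s for s in classify_subpaths(m)}
        planted = synth.planted_subpath(spec)
        assert by_nodes[planted.nodes].call == SubPathCall.PHENOTYPE1


class TestPathwayPvalue:
    def test_single_functional_relation_killed_by_decrement(self):
        assert pathway_pvalue(PathwayCounts(1, 5, 10, 50)) == pytest.approx(1.0)

    def test_zero_functional(self):
        assert pathway_pvalue(PathwayCounts(0, 5, 10, 50)) == 1.0

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_exhaustive_upper_tail(self, seed):
        rng = np.random.default_rng(seed)
        b_p = int(rng.integers(1, 20))
        a_p = int(rng.integers(1, b_p + 1))
        d_p = int(rng.integers(1, 30))
        c_p = int(rng.integers(0, d_p + 1))
        got = pathway_pvalue(PathwayCounts(a_p, b_p, c_p, d_p))
        assert got == pytest.approx(ease_upper_tail_enum(a_p, b_p, c_p, d_p),
                                    abs=1e-9)

    def test_monotone_in_functional_count(self):
        ps = [pathway_pvalue(PathwayCounts(a, 20, 30, 100)) for a in range(1, 21)]
        assert all(x >= y - 1e-12 for x, y in zip(ps, ps[1:]))


class TestRankPathways:
    def _stats(self, rows, labels):
        return classify_subpaths(_matrix_from_rows(rows, labels),
                                 FilterConfig(use_fdr=False))

    def test_sorted_ascending_with_id_tiebreak(self):
        labels = [1] * 10 + [2] * 10
        strong = self._stats([[1] * 10 + [0] * 10] * 3, labels)
        weak = self._stats([[0] * 20], labels)
        ranked = rank_pathways({"pwB": (strong, 3), "pwA": (weak, 1),
                                "pwC": (weak, 1)})
        assert ranked[0].pathway_id == "pwB"
        assert [r.pathway_id for r in ranked[1:]] == ["pwA", "pwC"]  # tie: lexicographic
        assert {r.pathway_id for r in ranked} == {"pwA", "pwB", "pwC"}

    def test_carries_counts_and_calls(self):
        labels = [1] * 10 + [2] * 10
        stats = self._stats([[1] * 10 + [0] * 10], labels)
        r = rank_pathways({"pw": (stats, 1)})[0]
        assert r.counts.a_p == 1 and r.counts.b_p == 1
        assert r.n_phenotype1 == 1


class TestPermutationFdr:
    def test_zero_permutations_rejected(self, fig11):
        g, b = fig11
        m = build_subpath_matrix(enumerate_subpaths(g), b, graph=g)
        with pytest.raises(ValueError):
            permutation_fdr(m, n_perm=0)

    def test_pure_noise_empirical_fdr_near_one(self):
        rng = np.random.default_rng(0)
        rows = rng.integers(0, 2, size=(40, 24))
        m = _matrix_from_rows(rows, [1] * 12 + [2] * 12)
        res = permutation_fdr(m, FilterConfig(use_fdr=False), n_perm=100, seed=3)
        if res.observed_selected:
            assert res.empirical_fdr > 0.5
        else:
            assert math.isnan(res.empirical_fdr)

    def test_planted_signal_low_fdr(self):
        spec = synth.SyntheticCohortSpec(seed=5)
        g, cohort = synth.make_planted_cohort(spec)
        b = discretize_matrix(cohort)
        m = build_subpath_matrix(enumerate_subpaths(g), b, graph=g)
        res = permutation_fdr(m, n_perm=200, seed=9)
        planted = synth.planted_subpath(spec)
        idx = next(i for i, sp in enumerate(m.subpaths)
                   if sp.nodes == planted.nodes)
        assert res.observed_selected > 0
        assert res.null_frequency[idx] < 0.05
        assert res.empirical_fdr < 0.05

    def test_deterministic_given_seed(self, fig11):
        g, b = fig11
        m = build_subpath_matrix(enumerate_subpaths(g), b, graph=g)
        r1 = permutation_fdr(m, n_perm=50, seed=7)
        r2 = permutation_fdr(m, n_perm=50, seed=7)
        assert r1.mean_null_selected == r2.mean_null_selected
        assert np.array_equal(r1.null_frequency, r2.null_frequency)
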