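import itertools
import math
from fractions import Fraction

import numpy as np
import pytest

from subpathways import synth
from subpathways.graph import PathwayGraph, SemanticClass


@pytest.fixture
def fig11():
    return synth.make_fig_dummy("fig11")


@pytest.fixture
def fig1():
    return synth.make_fig_dummy("fig1")


# ---------------------------------------------------------------------------
# independent oracles, deliberately naive

def brute_force_subpaths(g: PathwayGraph, max_len=None):
    """All simple paths between every ordered node pair, by plain recursion
    over the raw edge list (independent of the package's DFS)."""
    arcs = []  # (src, tgt, edge)
    for e in g.edges:
        if e.semantic_class == SemanticClass.UNKNOWN:
            continue
        if any(g.nodes[x].kind.value != "gene" for x in (e.source, e.target)):
            continue
        arcs.append((e.source, e.target, e))
        if not e.directed:
            arcs.append((e.target, e.source, e))

    found = set()

    def extend(nodes, edges):
        if len(edges) >= 1:
            found.add((tuple(nodes), tuple(ed.semantic_class for ed in edges),
                       tuple(id(ed) for ed in edges)))
        if max_len is not None and len(edges) >= max_len:
            return
        for s, t, e in arcs:
            if s == nodes[-1] and t not in nodes:
                extend(nodes + [t], edges + [e])

    for n in g.nodes:
        extend([n], [])
    return {(ns, cs) for ns, cs, _ in found}


TRUTH = {
    SemanticClass.ACTIVATION_LIKE: {(0, 0): 0, (0, 1): 0, (1, 0): 0, (1, 1): 1},
    SemanticClass.INHIBITION_LIKE: {(0, 0): 0, (0, 1): 1, (1, 0): 1, (1, 1): 0},
    SemanticClass.NEUTRAL: {(0, 0): 1, (0, 1): 1, (1, 0): 1, (1, 1): 1},
}


def naive_eval_subpath(sp, profile):
    """Per-relation truth-table lookup, AND-folded."""
    val = 1
    for k, edge in enumerate(sp.edges):
        src, tgt = sp.nodes[k], sp.nodes[k + 1]
        val = val and TRUTH[edge.semantic_class][(profile[src], profile[tgt])]
    return int(val)


def exhaustive_ig_scan(values, labels):
    """(best_gain, best_midpoint, all (mu, gain)) by direct enumeration."""
    values = list(map(float, values))
    labels = list(labels)

    def entropy(subset):
        n = len(subset)
        if n == 0:
            return 0.0
        out = 0.0
        for c in set(subset):
            p = subset.count(c) / n
            out -= p * math.log2(p)
        return out

    distinct = sorted(set(values))
    e_total = entropy(labels)
    results = []
    for lo, hi in zip(distinct, distinct[1:]):
        mu = (lo + hi) / 2
        above = [l for v, l in zip(values, labels) if v > mu]
        below = [l for v, l in zip(values, labels) if v <= mu]
        e_split = (len(below) * entropy(below) + len(above) * entropy(above)) / len(values)
        results.append((mu, e_total - e_split))
    if not results:
        return 0.0, distinct[0], []
    best_gain = max(g for _, g in results)
    best_mu = min(mu for mu, g in results if g == best_gain)
    return best_gain, best_mu, results


def hypergeom_point(a, b, c, d):
    n = a + b + c + d
    return Fraction(math.comb(a + b, a) * math.comb(c + d, c), math.comb(n, a + c))


def fisher_two_sided_enum(a, b, c, d):
    """Sum of probabilities of all same-margin tables no more probable than
    the observed one (exact rational arithmetic)."""
    r1, r2, c1 = a + b, c + d, a + c
    obs = hypergeom_point(a, b, c, d)
    total = Fraction(0)
    for k in range(max(0, c1 - r2), min(r1, c1) + 1):
        p = hypergeom_point(k, r1 - k, c1 - k, r2 - (c1 - k))
        if p <= obs:
            total += p
    return float(total)


def ease_upper_tail_enum(a_p, b_p, c_p, d_p):
    """P(X >= a_p - 1), X hypergeometric over n relations with
    (a_p - 1) + c_p functional, b_p drawn; exact rational sum."""
    if a_p == 0:
        return 1.0
    k0 = a_p - 1
    n = b_p + d_p
    K = k0 + c_p
    total = Fraction(0)
    for k in range(k0, min(K, b_p) + 1):
        if n - K >= b_p - k >= 0:
            total += Fraction(math.comb(K, k) * math.comb(n - K, b_p - k),
                              math.comb(n, b_p))
    return float(total)


def all_small_tables(max_total):
    """Every 2x2 table of non-negative counts with grand total <= max_total
    and both class margins positive."""
    for n in range(2, max_total + 1):
        for a, b, c in itertools.product(range(n + 1), repeat=3):
            d = n - a - b - c
            if d < 0:
                continue
            if a + c == 0 or b + d == 0:
                continue
            yield a, b, c, d


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
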