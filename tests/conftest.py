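"""Shared fixtures and independent oracles.

The oracles deliberately avoid the library code paths they check: exact
rational/decimal arithmetic for the closed-form statistics, exhaustive
counting for the hypergeometric tail, per-pair set intersection for the
co-occurrence counts, and memoization-free recursion for the DAG
contributions.
"""

from __future__ import annotations

import itertools
from decimal import Decimal, getcontext
from fractions import Fraction
from math import comb

import networkx as nx
import pytest

from comorisk.io import OntologyGraph

getcontext().prec = 60


# ---------------------------------------------------------------------------
# oracles

def oracle_rr(c, n, p_i, p_j, variant="modified") -> Fraction:
    if c == 0:
        return Fraction(0)
    denom = p_i * p_j - c if variant == "modified" else p_i * p_j
    return Fraction(c * n, denom)


def oracle_phi(c, n, p_i, p_j, variant="modified") -> Decimal:
    d = p_i * p_j - c if variant == "modified" else p_i * p_j
    radicand = Decimal(d * (n - p_i) * (n - p_j))
    return Decimal(c * n - p_i * p_j) / radicand.sqrt()


def oracle_katz(rr: Decimal, c, n, p_i, p_j, z="2.56"):
    sigma = (Decimal(1) / c + Decimal(1) / (p_i * p_j)
             - Decimal(1) / n - Decimal(1) / (n * n)).sqrt()
    zs = Decimal(z) * sigma
    return sigma, rr * (-zs).exp(), rr * zs.exp()


def oracle_t(phi: Decimal, n_obs: int) -> Decimal:
    return phi * Decimal(n_obs - 2).sqrt() / (Decimal(1) - phi * phi).sqrt()


def oracle_hypergeom_tail(n_u, m, n_q, k) -> Fraction:
    """P(X >= k) by exact summation of the hypergeometric mass."""
    total = comb(n_u, n_q)
    acc = sum(comb(m, i) * comb(n_u - m, n_q - i)
              for i in range(k, min(m, n_q) + 1))
    return Fraction(acc, total)


def oracle_pair_counts(records):
    """Per-pair patient-set intersections, independent of aggregate_counts."""
    carriers: dict[str, set[str]] = {}
    for pid, did in records.records:
        carriers.setdefault(did, set()).add(pid)
    counts = {}
    for a, b in itertools.combinations(sorted(carriers), 2):
        c = len(carriers[a] & carriers[b])
        if c:
            counts[(a, b)] = c
    return len(records.patients), {d: len(s) for d, s in carriers.items()}, counts


def oracle_wang_contribution(og: OntologyGraph, focus: str, t: str) -> float:
    """Memoization-free recursive D_A(t) over the ancestor closure."""
    closure = {focus} | nx.descendants(og.graph, focus)
    assert t in closure

    def rec(term):
        if term == focus:
            return 1.0
        return max(og.edge_weight(child, term) * rec(child)
                   for child in og.graph.predecessors(term) if child in closure)

    return rec(t)


def oracle_wang_similarity(og: OntologyGraph, a: str, b: str) -> float:
    ta = {a} | nx.descendants(og.graph, a)
    tb = {b} | nx.descendants(og.graph, b)
    da = {t: oracle_wang_contribution(og, a, t) for t in ta}
    db = {t: oracle_wang_contribution(og, b, t) for t in tb}
    shared = ta & tb
    return sum(da[t] + db[t] for t in shared) / (sum(da.values()) + sum(db.values()))


def oracle_bh(pvals):
    """Hand transcription of the step-up rule: sort ascending, take
    min_{j>=i} p_(j)*m/j, cap at 1, restore input order."""
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    adjusted = [0.0] * m
    running = 1.0
    for rank in range(m, 0, -1):
        idx = order[rank - 1]
        running = min(running, pvals[idx] * m / rank)
        adjusted[idx] = running
    return adjusted


# ---------------------------------------------------------------------------
# fixtures

@pytest.fixture
def chain_ontology() -> OntologyGraph:
    """A is_a B is_a R with the default is_a weight 0.7."""
    g = nx.DiGraph()
    g.add_edge("A", "B", relation="is_a")
    g.add_edge("B", "R", relation="is_a")
    return OntologyGraph(g)


@pytest.fixture
def diamond_ontology() -> OntologyGraph:
    """A below two parents P1, P2, both below root R."""
    g = nx.DiGraph()
    for child, parent in [("A", "P1"), ("A", "P2"), ("P1", "R"), ("P2", "R")]:
        g.add_edge(child, parent, relation="is_a")
    return OntologyGraph(g)


@pytest.fixture
def small_genesets():
    from comorisk.io import GeneSetMap

    universe = frozenset(f"g{i}" for i in range(10))
    return GeneSetMap(universe, {
        "D1": frozenset({"g0", "g1", "g2"}),
        "D2": frozenset({"g1", "g2", "g3"}),
        "D3": frozenset({"g8", "g9"}),
    })
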