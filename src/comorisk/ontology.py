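"""Wang-style semantic similarity between ontology terms.

A term A is represented by its ancestor DAG: A plus every ancestor, with
the induced edges.  Each term t in that DAG contributes D_A(t) to the
semantics of A:

    D_A(A) = 1
    D_A(t) = max{ w_e * D_A(t') : t' a child of t inside the DAG }

where w_e in (0, 1) is the contribution factor of the edge linking t to its
child t' (by relation type: is_a 0.7, part_of 0.6 by default).  The semantic
value DV(A) = sum of all contributions, and the similarity of A and B is

    S(A, B) = sum_{t in T_A ∩ T_B} (D_A(t) + D_B(t)) / (DV(A) + DV(B))

which is symmetric, lies in [0, 1], equals 1 at A = B and 0 exactly when the
two ancestor DAGs are disjoint.  The max over children is restricted to the
ancestor closure of the focus term; children outside it cannot contribute.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import pandas as pd

from .errors import LookupError_
from .io import OntologyGraph


@dataclass(frozen=True)
class AncestorDag:
    """Focus term, its ancestor closure T_A, and the contribution map D_A."""

    focus: str
    terms: frozenset[str]
    edges: frozenset[tuple[str, str, str]]
    contributions: dict[str, float]

    def semantic_value(self) -> float:
        return sum(self.contributions.values())


@dataclass(frozen=True)
class SimilarityResult:
    pair: tuple[str, str]
    dv_a: float
    dv_b: float
    shared_terms: frozenset[str]
    s_sim: float


def ancestor_dag(og: OntologyGraph, term: str) -> AncestorDag:
    """Build DAG_A for ``term``: reachability over child->parent edges plus
    the contribution of every ancestor, evaluated in topological order so
    each value is final when read."""
    if term not in og.graph:
        raise LookupError_(f"unknown ontology term {term!r}")
    terms = {term} | nx.descendants(og.graph, term)  # edges run child->parent
    sub = og.graph.subgraph(terms)
    contributions: dict[str, float] = {}
    for t in nx.topological_sort(sub):  # children before parents
        if t == term:
            contributions[t] = 1.0
        else:
            contributions[t] = max(
                og.edge_weight(child, t) * contributions[child]
                for child in sub.predecessors(t)
            )
    edges = frozenset(
        (c, p, d.get("relation", "other")) for c, p, d in sub.edges(data=True)
    )
    return AncestorDag(term, frozenset(terms), edges, contributions)


def semantic_value(dag: AncestorDag) -> float:
    """DV(A) = Σ_t D_A(t); at least 1 since the focus contributes 1."""
    return dag.semantic_value()


def _similarity_from_dags(dag_a: AncestorDag, dag_b: AncestorDag) -> SimilarityResult:
    shared = dag_a.terms & dag_b.terms
    dv_a, dv_b = dag_a.semantic_value(), dag_b.semantic_value()
    s = sum(dag_a.contributions[t] + dag_b.contributions[t] for t in shared) / (dv_a + dv_b)
    return SimilarityResult(
        pair=(dag_a.focus, dag_b.focus),
        dv_a=dv_a, dv_b=dv_b,
        shared_terms=frozenset(shared),
        s_sim=s,
    )


def semantic_similarity(og: OntologyGraph, a: str, b: str) -> SimilarityResult:
    """S(A, B) over the two ancestor DAGs; symmetric, in [0, 1]."""
    return _similarity_from_dags(ancestor_dag(og, a), ancestor_dag(og, b))


def similarity_matrix(og: OntologyGraph, terms: list[str]) -> pd.DataFrame:
    """Symmetric similarity matrix over ``terms`` (row/column order = input
    order); each ancestor DAG is built once and cached."""
    dags = {t: ancestor_dag(og, t) for t in dict.fromkeys(terms)}
    mat = pd.DataFrame(0.0, index=list(terms), columns=list(terms))
    for i, a in enumerate(terms):
        mat.iloc[i, i] = 1.0
        for j in range(i + 1, len(terms)):
            b = terms[j]
            s = 1.0 if a == b else _similarity_from_dags(dags[a], dags[b]).s_sim
            mat.iloc[i, j] = s
            mat.iloc[j, i] = s
    return mat


def write_similarity_pairs(results: list[SimilarityResult], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("term_a\tterm_b\tdv_a\tdv_b\tn_shared\ts_sim\n")
        for r in sorted(results, key=lambda r: r.pair):
            fh.write("\t".join([
                r.pair[0], r.pair[1], format(r.dv_a, ".12g"), format(r.dv_b, ".12g"),
                str(len(r.shared_terms)), format(r.s_sim, ".12g"),
            ]) + "\n")


def read_similarity_pairs(path) -> list[SimilarityResult]:
    frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    return [
        SimilarityResult(
            pair=(str(row.term_a), str(row.term_b)),
            dv_a=float(row.dv_a), dv_b=float(row.dv_b),
            shared_terms=frozenset(),
            s_sim=float(row.s_sim),
        )
        for row in frame.itertuples(index=False)
    ]


def write_similarity_matrix(mat: pd.DataFrame, path) -> None:
    mat.to_csv(path, sep="\t", float_format="%.12g", index_label="term")
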