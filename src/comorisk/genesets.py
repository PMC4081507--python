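"""Disease-disease association from shared gene or pathway annotations.

Two annotation sets are compared by their overlap count, the Jaccard index
|A∩B|/|A∪B|, and an over-representation p-value from the hypergeometric
distribution, P(X >= k) for an overlap of k between a query of size n drawn
from a universe of N genes of which M are annotated.  Raw p-values are
adjusted with the Benjamini-Hochberg step-up procedure within one call.

Disease mode and pathway mode share every code path; ``set_kind`` only
labels outputs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .errors import DomainError, ValidationError
from .io import GeneSetMap

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class EnrichmentInput:
    """Counts for one hypergeometric over-representation test.

    universe_size N, annotated M (genes tied to the target set), query_size
    n (genes of interest inside the universe), overlap k (query genes that
    are annotated).
    """

    universe_size: int
    annotated: int
    query_size: int
    overlap: int

    def __post_init__(self):
        n_u, m, n_q, k = self.universe_size, self.annotated, self.query_size, self.overlap
        if not (0 <= m <= n_u and 0 <= n_q <= n_u):
            raise ValidationError("need 0 <= M <= N and 0 <= n <= N")
        if not 0 <= k <= min(m, n_q):
            raise ValidationError("need 0 <= k <= min(M, n)")


@dataclass(frozen=True)
class AssociationRecord:
    """A scored association between two sets (or a query and a set)."""

    pair: tuple[str, str]
    shared_count: int
    jaccard: float
    p_raw: float
    p_adj: float
    shared_elements: frozenset[str]


def shared_count(set_a, set_b) -> int:
    """Number of shared elements |A ∩ B|."""
    return len(frozenset(set_a) & frozenset(set_b))


def jaccard(set_a, set_b) -> float:
    """Jaccard index |A∩B| / |A∪B|, in [0, 1]; symmetric."""
    a, b = frozenset(set_a), frozenset(set_b)
    union = a | b
    if not union:
        raise DomainError("Jaccard index undefined for two empty sets")
    return len(a & b) / len(union)


def hypergeom_pvalue(inp: EnrichmentInput) -> float:
    """Upper-tail hypergeometric probability P(X >= k).

    Equals 1 − Σ_{i<k} C(M,i) C(N−M, n−i) / C(N,n), evaluated through the
    survival function for numerical stability at large counts.
    """
    if inp.overlap == 0:
        return 1.0
    p = float(hypergeom.sf(inp.overlap - 1, inp.universe_size, inp.annotated, inp.query_size))
    return min(max(p, 0.0), 1.0)


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise DomainError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _pair_enrichment(gsmap: GeneSetMap, id_a: str, id_b: str) -> EnrichmentInput:
    """The query is the smaller set (tie -> lexicographically first id)."""
    set_a, set_b = gsmap.sets[id_a], gsmap.sets[id_b]
    if len(set_a) < len(set_b) or (len(set_a) == len(set_b) and id_a < id_b):
        query, target = set_a, set_b
    else:
        query, target = set_b, set_a
    return EnrichmentInput(
        universe_size=len(gsmap.universe),
        annotated=len(target),
        query_size=len(query),
        overlap=len(set_a & set_b),
    )


def associate_sets(gsmap: GeneSetMap, fdr_threshold: float | None = None) -> list[AssociationRecord]:
    """Score every unordered pair of sets sharing at least one element.

    Each record carries the Jaccard index, the hypergeometric p of one set's
    members against the other over the map's universe, and the BH-adjusted p
    across all emitted pairs.  Pairs with no shared element are omitted;
    ``fdr_threshold`` optionally drops records with p_adj above it.
    """
    ids = sorted(gsmap.sets)
    if len(ids) < 2:
        raise DomainError("need at least two sets to associate")
    pairs, raws = [], []
    for idx, id_a in enumerate(ids):
        for id_b in ids[idx + 1:]:
            shared = gsmap.sets[id_a] & gsmap.sets[id_b]
            if not shared:
                continue
            pairs.append((id_a, id_b, shared))
            raws.append(hypergeom_pvalue(_pair_enrichment(gsmap, id_a, id_b)))
    adjusted = bh_fdr(raws)
    records = [
        AssociationRecord(
            pair=(id_a, id_b),
            shared_count=len(shared),
            jaccard=jaccard(gsmap.sets[id_a], gsmap.sets[id_b]),
            p_raw=p_raw,
            p_adj=float(p_adj),
            shared_elements=frozenset(shared),
        )
        for (id_a, id_b, shared), p_raw, p_adj in zip(pairs, raws, adjusted)
    ]
    if fdr_threshold is not None:
        records = [r for r in records if r.p_adj <= fdr_threshold]
    return records


def query_gene_list(genes, gsmap: GeneSetMap, label: str = "query") -> list[AssociationRecord]:
    """Enrich a gene list against every set in the map.

    Genes outside the universe are dropped (count logged); one record per
    set with overlap >= 1, BH-adjusted across the emitted records.
    """
    query = frozenset(genes)
    if not query:
        raise DomainError("empty gene list")
    inside = query & gsmap.universe
    dropped = len(query) - len(inside)
    if dropped:
        logger.info("query_gene_list: dropped %d genes outside the universe", dropped)
    if not inside:
        raise DomainError("no query gene is present in the universe")
    hits, raws = [], []
    for sid in sorted(gsmap.sets):
        members = gsmap.sets[sid]
        shared = inside & members
        if not shared:
            continue
        hits.append((sid, shared, members))
        raws.append(hypergeom_pvalue(EnrichmentInput(
            universe_size=len(gsmap.universe),
            annotated=len(members),
            query_size=len(inside),
            overlap=len(shared),
        )))
    adjusted = bh_fdr(raws)
    return [
        AssociationRecord(
            pair=(label, sid),
            shared_count=len(shared),
            jaccard=jaccard(inside, members),
            p_raw=p_raw,
            p_adj=float(p_adj),
            shared_elements=frozenset(shared),
        )
        for (sid, shared, members), p_raw, p_adj in zip(hits, raws, adjusted)
    ]


def bipartite_incidence(gsmap: GeneSetMap) -> nx.Graph:
    """The disease/pathway-gene bipartite incidence graph (exportable layer)."""
    g = nx.Graph()
    for sid in sorted(gsmap.sets):
        g.add_node(sid, bipartite=0, kind=gsmap.set_kind)
        for gene in sorted(gsmap.sets[sid]):
            g.add_node(gene, bipartite=1, kind="gene")
            g.add_edge(sid, gene)
    return g


def bipartite_projection(gsmap: GeneSetMap) -> nx.Graph:
    """Project the bipartite graph onto sets: edge iff >= 1 shared gene,
    weighted by the Jaccard index of the two gene neighbourhoods."""
    g = nx.Graph()
    ids = sorted(gsmap.sets)
    g.add_nodes_from(ids)
    for idx, id_a in enumerate(ids):
        for id_b in ids[idx + 1:]:
            k = len(gsmap.sets[id_a] & gsmap.sets[id_b])
            if k >= 1:
                g.add_edge(id_a, id_b,
                           weight=jaccard(gsmap.sets[id_a], gsmap.sets[id_b]),
                           shared=k)
    return g


_ASSOC_COLUMNS = ["id_a", "id_b", "shared_count", "jaccard", "p_raw", "p_adj", "shared_elements"]


def write_associations(records: list[AssociationRecord], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(_ASSOC_COLUMNS) + "\n")
        for r in sorted(records, key=lambda r: r.pair):
            fh.write("\t".join([
                r.pair[0], r.pair[1], str(r.shared_count),
                format(r.jaccard, ".12g"), format(r.p_raw, ".12g"),
                format(r.p_adj, ".12g"), ",".join(sorted(r.shared_elements)),
            ]) + "\n")


def read_associations(path) -> list[AssociationRecord]:
    import pandas as pd

    frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    return [
        AssociationRecord(
            pair=(str(row.id_a), str(row.id_b)),
            shared_count=int(row.shared_count),
            jaccard=float(row.jaccard),
            p_raw=float(row.p_raw),
            p_adj=float(row.p_adj),
            shared_elements=frozenset(e for e in str(row.shared_elements).split(",") if e),
        )
        for row in frame.itertuples(index=False)
    ]
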