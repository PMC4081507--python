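"""Assemble multi-evidence comorbidity networks and export them.

Evidence of four kinds — clinical co-occurrence edges, gene-set overlap,
pathway overlap and ontology semantic similarity — is merged per canonical
disease pair.  The evidence types stay side by side on each edge; no
composite score is formed, because the underlying statistics are not
commensurable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import networkx as nx
import pandas as pd

from .clinical import ComorbidityEdge, apply_ci_filter
from .errors import LookupError_, ValidationError
from .genesets import AssociationRecord
from .io import IdCrosswalk, pair_key
from .ontology import SimilarityResult

EVIDENCE_KINDS = ("clinical", "geneset", "pathway", "ontology")


@dataclass
class ComorbidityNetwork:
    """Disease nodes plus per-pair evidence bundles.

    Each edge maps a canonical pair to a dict with any of the keys
    ``clinical`` (:class:`ComorbidityEdge`), ``geneset`` / ``pathway``
    (:class:`AssociationRecord`), ``ontology`` (:class:`SimilarityResult`);
    every edge has at least one entry and there are no self-loops.
    """

    edges: dict[tuple[str, str], dict[str, object]]
    labels: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        for pair, bundle in self.edges.items():
            if pair != pair_key(*pair):
                raise ValidationError(f"edge key {pair} is not canonical")
            if not bundle:
                raise ValidationError(f"edge {pair} carries no evidence")
            unknown = set(bundle) - set(EVIDENCE_KINDS)
            if unknown:
                raise ValidationError(f"unknown evidence kinds {unknown} on edge {pair}")

    @property
    def nodes(self) -> frozenset[str]:
        return frozenset(n for pair in self.edges for n in pair)


def build_network(clinical: list[ComorbidityEdge] | None = None,
                  geneset: list[AssociationRecord] | None = None,
                  pathway: list[AssociationRecord] | None = None,
                  ontology: list[SimilarityResult] | None = None,
                  p_adj_max: float | None = None,
                  s_sim_min: float | None = None,
                  crosswalk: IdCrosswalk | None = None,
                  strict_crosswalk: bool = False) -> ComorbidityNetwork:
    """Merge evidence sources into one network, applying per-source filters.

    Clinical edges are passed through the Katz-interval filter; association
    records need >= 1 shared element and, when ``p_adj_max`` is given,
    p_adj <= p_adj_max; ontology pairs need s_sim > 0 and, when
    ``s_sim_min`` is given, s_sim >= s_sim_min.  With ``strict_crosswalk``
    every node id must resolve in the crosswalk (offenders are listed).
    """
    edges: dict[tuple[str, str], dict[str, object]] = {}

    def bundle(a: str, b: str) -> dict[str, object]:
        return edges.setdefault(pair_key(a, b), {})

    for e in apply_ci_filter(clinical or []):
        bundle(*e.pair)["clinical"] = e
    for kind, records in (("geneset", geneset), ("pathway", pathway)):
        for r in records or []:
            if r.shared_count < 1:
                continue
            if p_adj_max is not None and r.p_adj > p_adj_max:
                continue
            bundle(*r.pair)[kind] = r
    for s in ontology or []:
        if s.pair[0] == s.pair[1] or s.s_sim <= 0:
            continue
        if s_sim_min is not None and s.s_sim < s_sim_min:
            continue
        bundle(*s.pair)["ontology"] = s

    labels: dict[str, str] = {}
    if crosswalk is not None:
        missing = []
        for node in sorted({n for pair in edges for n in pair}):
            if node in crosswalk:
                row = crosswalk.lookup(node)
                if row.name:
                    labels[node] = row.name
            else:
                missing.append(node)
        if strict_crosswalk and missing:
            raise LookupError_(f"ids not resolvable in crosswalk: {', '.join(missing)}")
    return ComorbidityNetwork(edges, labels)


# ---------------------------------------------------------------------------
# flattening and export

def _edge_attributes(bundle: dict[str, object]) -> dict[str, object]:
    attrs: dict[str, object] = {"evidence_count": len(bundle), "evidence": ",".join(sorted(bundle))}
    e: ComorbidityEdge | None = bundle.get("clinical")  # type: ignore[assignment]
    if e is not None:
        attrs.update({
            "clinical_c": e.c, "clinical_n": e.n, "clinical_p_i": e.p_i,
            "clinical_p_j": e.p_j, "clinical_variant": e.variant,
            "clinical_rr": e.rr, "clinical_phi": e.phi, "clinical_sigma": e.sigma,
            "clinical_lb": e.lb, "clinical_ub": e.ub, "clinical_t": e.t_stat,
            "clinical_significant": e.significant,
        })
    for kind in ("geneset", "pathway"):
        r: AssociationRecord | None = bundle.get(kind)  # type: ignore[assignment]
        if r is not None:
            attrs.update({
                f"{kind}_shared": r.shared_count,
                f"{kind}_jaccard": r.jaccard,
                f"{kind}_p_raw": r.p_raw,
                f"{kind}_p_adj": r.p_adj,
            })
    s: SimilarityResult | None = bundle.get("ontology")  # type: ignore[assignment]
    if s is not None:
        attrs["ontology_s_sim"] = s.s_sim
    return attrs


_TSV_COLUMNS = [
    "disease_i", "disease_j", "evidence_count", "evidence",
    "clinical_c", "clinical_n", "clinical_p_i", "clinical_p_j", "clinical_variant",
    "clinical_rr", "clinical_phi", "clinical_sigma", "clinical_lb", "clinical_ub",
    "clinical_t", "clinical_significant",
    "geneset_shared", "geneset_jaccard", "geneset_p_raw", "geneset_p_adj",
    "pathway_shared", "pathway_jaccard", "pathway_p_raw", "pathway_p_adj",
    "ontology_s_sim",
]


def network_to_frame(net: ComorbidityNetwork) -> pd.DataFrame:
    rows = []
    for pair in sorted(net.edges):
        attrs = _edge_attributes(net.edges[pair])
        row = {"disease_i": pair[0], "disease_j": pair[1]}
        row.update({c: attrs.get(c) for c in _TSV_COLUMNS[2:]})
        rows.append(row)
    return pd.DataFrame(rows, columns=_TSV_COLUMNS)


def _fmt(v) -> str:
    if v is None or (isinstance(v, float) and math.isnan(v)):
        return ""
    if isinstance(v, bool):
        return str(v).lower()
    if isinstance(v, float):
        return format(v, ".12g")
    return str(v)


def export_graph(net: ComorbidityNetwork, path, fmt: str) -> None:
    """Write the network as ``tsv``, ``graphml`` or ``dot``.

    Output is deterministic: nodes and edges in lexicographic pair order,
    evidence statistics serialized as typed attributes.
    """
    if not net.edges:
        raise ValidationError("refusing to export an empty network")
    if fmt == "tsv":
        frame = network_to_frame(net)
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("\t".join(_TSV_COLUMNS) + "\n")
            for row in frame.itertuples(index=False):
                fh.write("\t".join(_fmt(v) for v in row) + "\n")
    elif fmt == "graphml":
        g = nx.Graph()
        for node in sorted(net.nodes):
            attrs = {"label": net.labels[node]} if node in net.labels else {}
            g.add_node(node, **attrs)
        for pair in sorted(net.edges):
            attrs = {k: v for k, v in _edge_attributes(net.edges[pair]).items()
                     if v is not None and not (isinstance(v, float) and math.isnan(v))}
            g.add_edge(*pair, **attrs)
        nx.write_graphml(g, path)
    elif fmt == "dot":
        lines = ["graph comorbidity {"]
        for node in sorted(net.nodes):
            label = net.labels.get(node, node)
            lines.append(f'  "{node}" [label="{label}"];')
        for pair in sorted(net.edges):
            attrs = _edge_attributes(net.edges[pair])
            parts = [f'evidence="{attrs["evidence"]}"']
            if "clinical_rr" in attrs:
                parts.append(f'rr="{_fmt(attrs["clinical_rr"])}"')
            if "geneset_jaccard" in attrs:
                parts.append(f'jaccard="{_fmt(attrs["geneset_jaccard"])}"')
            if "ontology_s_sim" in attrs:
                parts.append(f's_sim="{_fmt(attrs["ontology_s_sim"])}"')
            lines.append(f'  "{pair[0]}" -- "{pair[1]}" [{", ".join(parts)}];')
        lines.append("}")
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("\n".join(lines) + "\n")
    else:
        raise ValidationError(f"unknown export format {fmt!r} (use tsv, graphml or dot)")


def read_network_tsv(path) -> ComorbidityNetwork:
    """Rebuild a network from its exported TSV (lossless for the columns
    exported; rebuilding from an export yields an identical export)."""
    frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    edges: dict[tuple[str, str], dict[str, object]] = {}
    for row in frame.itertuples(index=False):
        r = row._asdict()

        def opt_f(col):
            v = r.get(col, "")
            return None if v == "" else float(v)

        def opt_i(col):
            v = r.get(col, "")
            return None if v == "" else int(v)

        bundle: dict[str, object] = {}
        kinds = str(r["evidence"]).split(",")
        if "clinical" in kinds:
            bundle["clinical"] = ComorbidityEdge(
                pair=(str(r["disease_i"]), str(r["disease_j"])),
                c=opt_i("clinical_c"), n=opt_i("clinical_n"),
                p_i=opt_i("clinical_p_i"), p_j=opt_i("clinical_p_j"),
                variant=str(r["clinical_variant"]),
                rr=opt_f("clinical_rr"), phi=opt_f("clinical_phi"),
                sigma=opt_f("clinical_sigma"), lb=opt_f("clinical_lb"),
                ub=opt_f("clinical_ub"), t_stat=opt_f("clinical_t"),
                significant=str(r["clinical_significant"]).lower() == "true",
            )
        for kind in ("geneset", "pathway"):
            if kind in kinds:
                bundle[kind] = AssociationRecord(
                    pair=(str(r["disease_i"]), str(r["disease_j"])),
                    shared_count=opt_i(f"{kind}_shared"),
                    jaccard=opt_f(f"{kind}_jaccard"),
                    p_raw=opt_f(f"{kind}_p_raw"),
                    p_adj=opt_f(f"{kind}_p_adj"),
                    shared_elements=frozenset(),
                )
        if "ontology" in kinds:
            bundle["ontology"] = SimilarityResult(
                pair=(str(r["disease_i"]), str(r["disease_j"])),
                dv_a=math.nan, dv_b=math.nan, shared_terms=frozenset(),
                s_sim=opt_f("ontology_s_sim"),
            )
        edges[pair_key(str(r["disease_i"]), str(r["disease_j"]))] = bundle
    return ComorbidityNetwork(edges)


# ---------------------------------------------------------------------------
# neighbourhood query

def query_disease(net: ComorbidityNetwork, identifier: str,
                  crosswalk: IdCrosswalk | None = None) -> pd.DataFrame:
    """Report every partner of a focal disease with all evidence statistics.

    ``identifier`` may be in any crosswalk vocabulary; rows are sorted by
    (evidence count desc, rr desc, p_adj asc).  An id present in the
    crosswalk but absent from all evidence yields an empty report.
    """
    candidates = [identifier]
    resolved_via_crosswalk = False
    if crosswalk is not None and identifier in crosswalk:
        candidates = list(crosswalk.lookup(identifier).ids().values())
        resolved_via_crosswalk = True
    focal = next((c for c in candidates if c in net.nodes), None)
    if focal is None:
        if resolved_via_crosswalk:
            return pd.DataFrame(columns=["partner"] + _TSV_COLUMNS[2:])
        import difflib

        pool = sorted(net.nodes) + (sorted(crosswalk._index) if crosswalk else [])
        raise LookupError_(f"unknown disease id {identifier!r}",
                           difflib.get_close_matches(identifier, pool, n=3))
    rows = []
    for pair, bundle in net.edges.items():
        if focal not in pair:
            continue
        partner = pair[0] if pair[1] == focal else pair[1]
        attrs = _edge_attributes(bundle)
        row = {"partner": partner}
        row.update({c: attrs.get(c) for c in _TSV_COLUMNS[2:]})
        rows.append(row)
    frame = pd.DataFrame(rows, columns=["partner"] + _TSV_COLUMNS[2:])
    if not frame.empty:
        p_adj = frame[["geneset_p_adj", "pathway_p_adj"]].astype(float).min(axis=1)
        frame = (frame.assign(_p=p_adj)
                 .sort_values(["evidence_count", "clinical_rr", "_p", "partner"],
                              ascending=[False, False, True, True],
                              na_position="last")
                 .drop(columns="_p")
                 .reset_index(drop=True))
    return frame
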