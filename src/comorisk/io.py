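"""Data model and file I/O: patient records, co-occurrence counts, gene sets
(GMT), disease-ontology DAGs (OBO subset or TSV) and identifier crosswalks.

No statistics live here.  All tab-separated files are UTF-8 with ``#``
comment lines; pair-indexed structures use the canonical (min_id, max_id)
key so lookups are order-insensitive.
"""

from __future__ import annotations

import itertools
import logging
import re
from collections import Counter
from dataclasses import dataclass, field

import networkx as nx
import obonet

from .errors import CycleError, DomainError, LookupError_, ParseError, ValidationError

logger = logging.getLogger(__name__)

#: Wang-style semantic contribution factors per edge relation.
DEFAULT_RELATION_WEIGHTS = {"is_a": 0.7, "part_of": 0.6, "other": 0.7}

_ICD9_RE = re.compile(r"^(V\d{2}|E\d{3}|\d{3})(\.\d{1,2})?$")


def pair_key(a: str, b: str) -> tuple[str, str]:
    """Canonical unordered pair key: lexicographically sorted (min_id, max_id)."""
    if a == b:
        raise ValidationError(f"self-pair {a!r} is not a valid disease pair")
    return (a, b) if a < b else (b, a)


# ---------------------------------------------------------------------------
# dialects and comment-aware TSV iteration

@dataclass(frozen=True)
class Dialect:
    """Parsing options for long-format patient records.

    ``sentinel`` names a pseudo-disease marking a patient with no recorded
    diagnosis; such rows keep the patient in the population denominator N
    without contributing a disease.  ``strict`` rejects rows whose column
    count differs from two.
    """

    header: bool = False
    sentinel: str | None = "none"
    strict: bool = True


def _iter_tsv(path):
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            yield lineno, line.split("\t")


# ---------------------------------------------------------------------------
# patient records and co-occurrence counts

@dataclass(frozen=True)
class PatientRecordSet:
    """De-duplicated (patient, disease) diagnosis pairs.

    ``patients`` includes patients carrying zero diseases (entered through a
    sentinel row) so that the population size N is preserved.
    """

    patients: frozenset[str]
    records: frozenset[tuple[str, str]]

    def __post_init__(self):
        for pid, did in self.records:
            if not pid or not did:
                raise ValidationError("patient and disease ids must be non-empty")
            if pid not in self.patients:
                raise ValidationError(f"record references unknown patient {pid!r}")

    @property
    def diseases(self) -> frozenset[str]:
        return frozenset(d for _, d in self.records)

    def by_patient(self) -> dict[str, set[str]]:
        out: dict[str, set[str]] = {p: set() for p in self.patients}
        for pid, did in self.records:
            out[pid].add(did)
        return out


def read_patient_records(path, dialect: Dialect = Dialect()) -> PatientRecordSet:
    """Read two-column (patient_id, disease_id) long-format TSV records.

    Duplicate rows are collapsed; the number dropped is logged.
    """
    patients: set[str] = set()
    records: set[tuple[str, str]] = set()
    dropped = 0
    rows = _iter_tsv(path)
    if dialect.header:
        next(rows, None)
    for lineno, fields in rows:
        if len(fields) != 2:
            if dialect.strict:
                raise ParseError(f"expected 2 columns, got {len(fields)}", path, lineno)
            fields = fields[:2]
        pid, did = (f.strip() for f in fields)
        if not pid or not did:
            raise ParseError("empty patient or disease id", path, lineno)
        patients.add(pid)
        if dialect.sentinel is not None and did == dialect.sentinel:
            continue
        if (pid, did) in records:
            dropped += 1
        else:
            records.add((pid, did))
    if dropped:
        logger.info("read_patient_records: dropped %d duplicate rows from %s", dropped, path)
    return PatientRecordSet(frozenset(patients), frozenset(records))


def write_patient_records(recs: PatientRecordSet, path, dialect: Dialect = Dialect()) -> None:
    """Write records in sorted order; zero-disease patients get a sentinel row."""
    by_patient = recs.by_patient()
    with open(path, "w", encoding="utf-8") as fh:
        if dialect.header:
            fh.write("patient_id\tdisease_id\n")
        for pid in sorted(by_patient):
            diseases = sorted(by_patient[pid])
            if not diseases:
                if dialect.sentinel is None:
                    continue
                fh.write(f"{pid}\t{dialect.sentinel}\n")
            for did in diseases:
                fh.write(f"{pid}\t{did}\n")


@dataclass(frozen=True)
class CooccurrenceTable:
    """Population size N, per-disease prevalence counts P_i, and unordered
    pair co-occurrence counts C_ij (pairs with C_ij = 0 omitted)."""

    n_patients: int
    prevalence: dict[str, int]
    pair_counts: dict[tuple[str, str], int]

    def __post_init__(self):
        if self.n_patients < 1:
            raise ValidationError("population size N must be >= 1")
        for d, p in self.prevalence.items():
            if not 0 <= p <= self.n_patients:
                raise ValidationError(f"prevalence of {d!r} ({p}) outside [0, N={self.n_patients}]")
        for (i, j), c in self.pair_counts.items():
            if (i, j) != pair_key(i, j):
                raise ValidationError(f"pair key {(i, j)} is not canonical")
            if i not in self.prevalence or j not in self.prevalence:
                raise ValidationError(f"pair {(i, j)} references disease without prevalence")
            if c < 0 or c > min(self.prevalence[i], self.prevalence[j]):
                raise ValidationError(
                    f"C_{i},{j}={c} exceeds min(P_i={self.prevalence[i]}, P_j={self.prevalence[j]})"
                )

    def pair_count(self, i: str, j: str) -> int:
        return self.pair_counts.get(pair_key(i, j), 0)


def aggregate_counts(recs: PatientRecordSet) -> CooccurrenceTable:
    """Aggregate patient-level diagnoses into N / P_i / C_ij counts.

    N counts distinct patients (including zero-disease patients); C_ij counts
    patients diagnosed with both i and j.  The result is independent of
    record order.
    """
    if not recs.patients:
        raise DomainError("cannot aggregate an empty record set")
    prevalence: Counter[str] = Counter()
    pair_counts: Counter[tuple[str, str]] = Counter()
    for diseases in recs.by_patient().values():
        prevalence.update(diseases)
        for i, j in itertools.combinations(sorted(diseases), 2):
            pair_counts[(i, j)] += 1
    return CooccurrenceTable(len(recs.patients), dict(prevalence), dict(pair_counts))


_COOC_PREVALENCE_MARK = "."


def write_cooccurrence(table: CooccurrenceTable, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"#n_patients\t{table.n_patients}\n")
        for d in sorted(table.prevalence):
            fh.write(f"{d}\t{_COOC_PREVALENCE_MARK}\t{table.prevalence[d]}\n")
        for (i, j) in sorted(table.pair_counts):
            fh.write(f"{i}\t{j}\t{table.pair_counts[(i, j)]}\n")


def read_cooccurrence(path) -> CooccurrenceTable:
    """Read a pre-aggregated count table written by :func:`write_cooccurrence`.

    Count invariants (C_ij <= min(P_i, P_j) <= N) are re-checked on load and
    violations raise, never warn.
    """
    n_patients = None
    prevalence: dict[str, int] = {}
    pair_counts: dict[tuple[str, str], int] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith("#"):
                fields = line[1:].split("\t")
                if len(fields) == 2 and fields[0] == "n_patients":
                    n_patients = int(fields[1])
                continue
            fields = line.split("\t")
            if len(fields) != 3:
                raise ParseError(f"expected 3 columns, got {len(fields)}", path, lineno)
            a, b, count = fields
            try:
                c = int(count)
            except ValueError:
                raise ParseError(f"non-integer count {count!r}", path, lineno) from None
            if b == _COOC_PREVALENCE_MARK:
                prevalence[a] = c
            else:
                pair_counts[pair_key(a, b)] = c
    if n_patients is None:
        raise ParseError("missing '#n_patients' directive", path)
    return CooccurrenceTable(n_patients, prevalence, pair_counts)


# ---------------------------------------------------------------------------
# gene sets (GMT)

@dataclass(frozen=True)
class GeneSetMap:
    """Named gene sets (disease- or pathway-keyed) over a stated universe."""

    universe: frozenset[str]
    sets: dict[str, frozenset[str]]
    set_kind: str = "disease"
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        if self.set_kind not in ("disease", "pathway"):
            raise ValidationError(f"set_kind must be 'disease' or 'pathway', got {self.set_kind!r}")
        for sid, members in self.sets.items():
            stray = members - self.universe
            if stray:
                raise ValidationError(
                    f"set {sid!r} contains genes outside the universe: {sorted(stray)[:5]}"
                )


def read_gene_sets(path, universe_path=None, set_kind: str = "disease") -> GeneSetMap:
    """Read GMT (set_id TAB description TAB gene1 TAB gene2 ...).

    Without an explicit universe file the universe is the union of all sets.
    """
    sets: dict[str, frozenset[str]] = {}
    descriptions: dict[str, str] = {}
    for lineno, fields in _iter_tsv(path):
        if len(fields) < 3:
            raise ParseError(f"GMT line needs >=3 fields, got {len(fields)}", path, lineno)
        sid, desc, *genes = (f.strip() for f in fields)
        if sid in sets:
            raise ParseError(f"duplicate set id {sid!r}", path, lineno)
        sets[sid] = frozenset(g for g in genes if g)
        descriptions[sid] = desc
    if universe_path is not None:
        universe = frozenset(
            f[0].strip() for _, f in _iter_tsv(universe_path)
        )
    else:
        universe = frozenset(itertools.chain.from_iterable(sets.values()))
    return GeneSetMap(universe, sets, set_kind, descriptions)


def write_gene_sets(gsmap: GeneSetMap, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for sid in sorted(gsmap.sets):
            desc = gsmap.descriptions.get(sid, "na") or "na"
            genes = "\t".join(sorted(gsmap.sets[sid]))
            fh.write(f"{sid}\t{desc}\t{genes}\n")


# ---------------------------------------------------------------------------
# ontology DAG

@dataclass(frozen=True)
class OntologyGraph:
    """A DAG of ontology terms with typed child->parent edges.

    ``graph`` is a :class:`networkx.DiGraph` whose edges run child -> parent
    carrying a ``relation`` attribute; ``weights`` maps each relation to its
    semantic contribution factor in (0, 1).
    """

    graph: nx.DiGraph
    weights: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_RELATION_WEIGHTS))

    def __post_init__(self):
        for rel, w in self.weights.items():
            if not 0.0 < w < 1.0:
                raise ValidationError(f"weight for relation {rel!r} must be in (0,1), got {w}")
        if not nx.is_directed_acyclic_graph(self.graph):
            raise CycleError([u for u, _ in nx.find_cycle(self.graph)])

    @property
    def terms(self) -> frozenset[str]:
        return frozenset(self.graph.nodes)

    def edge_weight(self, child: str, parent: str) -> float:
        rel = self.graph.edges[child, parent].get("relation", "other")
        return self.weights.get(rel, self.weights["other"])

    def edges(self) -> set[tuple[str, str, str]]:
        return {
            (c, p, d.get("relation", "other")) for c, p, d in self.graph.edges(data=True)
        }


_KNOWN_RELATIONS = ("is_a", "part_of")


def _build_ontology(term_names: dict[str, str | None],
                    edges: list[tuple[str, str, str]],
                    weights: dict[str, float] | None) -> OntologyGraph:
    g = nx.DiGraph()
    for t in sorted(term_names):
        g.add_node(t, name=term_names[t])
    for child, parent, rel in edges:
        if parent not in term_names:
            raise ValidationError(f"dangling parent id {parent!r} (referenced by {child!r})")
        if child not in term_names:
            raise ValidationError(f"dangling child id {child!r}")
        if rel not in _KNOWN_RELATIONS:
            rel = "other"
        g.add_edge(child, parent, relation=rel)
    w = dict(DEFAULT_RELATION_WEIGHTS)
    if weights:
        w.update(weights)
    return OntologyGraph(g, w)


def read_ontology(path, weights: dict[str, float] | None = None, fmt: str | None = None) -> OntologyGraph:
    """Read a DAG from an OBO file or a 3-column (child, parent, relation) TSV.

    Format is inferred from the ``.obo`` suffix unless ``fmt`` is given.
    Unknown relation types map to ``other``; acyclicity is verified.
    """
    if fmt is None:
        fmt = "obo" if str(path).endswith(".obo") else "tsv"
    if fmt == "obo":
        multi = obonet.read_obo(path)
        # obonet adds referenced-but-undeclared parents as attribute-less nodes
        term_names = {t: d.get("name") for t, d in multi.nodes(data=True) if d}
        edges = [(c, p, rel) for c, p, rel in multi.edges(keys=True)]
        return _build_ontology(term_names, edges, weights)
    if fmt != "tsv":
        raise ValidationError(f"unknown ontology format {fmt!r}")
    term_names: dict[str, str | None] = {}
    edges = []
    for lineno, fields in _iter_tsv(path):
        fields = [f.strip() for f in fields]
        if len(fields) == 1:  # isolated term declaration
            term_names.setdefault(fields[0], None)
            continue
        if len(fields) not in (2, 3):
            raise ParseError(f"expected child/parent[/relation], got {len(fields)} fields", path, lineno)
        child, parent = fields[0], fields[1]
        rel = fields[2] if len(fields) == 3 else "is_a"
        term_names.setdefault(child, None)
        term_names.setdefault(parent, None)
        edges.append((child, parent, rel))
    return _build_ontology(term_names, edges, weights)


def write_ontology_tsv(og: OntologyGraph, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("#child\tparent\trelation\n")
        isolated = set(og.terms) - {t for e in og.edges() for t in e[:2]}
        for t in sorted(isolated):
            fh.write(f"{t}\n")
        for child, parent, rel in sorted(og.edges()):
            fh.write(f"{child}\t{parent}\t{rel}\n")


def write_ontology_obo(og: OntologyGraph, path) -> None:
    """Write the minimal OBO subset (id / name / is_a / relationship)."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("format-version: 1.2\n")
        for t in sorted(og.terms):
            fh.write(f"\n[Term]\nid: {t}\n")
            name = og.graph.nodes[t].get("name")
            fh.write(f"name: {name if name else t}\n")
            for _, parent, data in sorted(og.graph.out_edges(t, data=True)):
                rel = data.get("relation", "other")
                if rel == "is_a":
                    fh.write(f"is_a: {parent}\n")
                else:
                    fh.write(f"relationship: {rel} {parent}\n")


# ---------------------------------------------------------------------------
# identifier crosswalk

_CROSSWALK_VOCABS = ("omim", "icd9", "doid", "name")


@dataclass(frozen=True)
class CrosswalkRow:
    omim: str | None = None
    icd9: str | None = None
    doid: str | None = None
    name: str | None = None

    def ids(self) -> dict[str, str]:
        return {v: getattr(self, v) for v in _CROSSWALK_VOCABS if getattr(self, v)}


@dataclass
class IdCrosswalk:
    """OMIM / ICD-9-CM / DOID / display-name equivalence table.

    Lookup by any identifier present in a row returns that row.
    """

    rows: list[CrosswalkRow]

    def __post_init__(self):
        self._index: dict[str, CrosswalkRow] = {}
        for row in self.rows:
            ids = row.ids()
            if not ids:
                raise ValidationError("crosswalk row with no identifiers")
            for value in ids.values():
                self._index[value] = row

    def lookup(self, identifier: str) -> CrosswalkRow:
        try:
            return self._index[identifier]
        except KeyError:
            import difflib

            close = difflib.get_close_matches(identifier, self._index, n=3)
            raise LookupError_(f"unknown identifier {identifier!r}", close) from None

    def __contains__(self, identifier: str) -> bool:
        return identifier in self._index


def read_crosswalk(path) -> IdCrosswalk:
    rows = []
    it = _iter_tsv(path)
    first = next(it, None)
    if first is None:
        return IdCrosswalk([])
    lineno, fields = first

    def parse(fields, lineno):
        fields = [f.strip() for f in fields]
        if len(fields) != 4:
            raise ParseError(f"expected 4 columns (omim, icd9, doid, name), got {len(fields)}", path, lineno)
        return CrosswalkRow(*(f or None for f in fields))

    if [f.strip().lower() for f in fields] != list(_CROSSWALK_VOCABS):
        rows.append(parse(fields, lineno))
    for lineno, fields in it:
        rows.append(parse(fields, lineno))
    return IdCrosswalk(rows)


def write_crosswalk(xw: IdCrosswalk, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(_CROSSWALK_VOCABS) + "\n")
        for row in xw.rows:
            fh.write("\t".join(getattr(row, v) or "" for v in _CROSSWALK_VOCABS) + "\n")


# ---------------------------------------------------------------------------
# ICD-9-CM normalization

def normalize_icd9(code: str, level: int = 5) -> str:
    """Normalize an ICD-9-CM code to the 3-digit category or full 5-digit form.

    Codes are treated lexically: 3 leading characters (digits, or V/E
    prefixed), an optional decimal with up to two digits.  Leading zeros are
    preserved ("042" stays "042").
    """
    if level not in (3, 5):
        raise ValidationError(f"level must be 3 or 5, got {level}")
    code = code.strip()
    if not _ICD9_RE.match(code):
        raise ValidationError(f"{code!r} is not a valid ICD-9-CM code")
    if level == 3:
        return code.split(".", 1)[0]
    return code
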