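"""Seeded synthetic-data generators with planted, recoverable structure.

Every generator is a pure function of its spec (including the seed), so the
same spec reproduces the same bytes on disk.  They exist so that each
statistic in the package can be exercised against a known ground truth:

* :func:`simulate_patients` draws a patient population where selected
  disease pairs have a chosen relative risk and all other diseases are
  independent;
* :func:`random_genesets` draws gene sets where selected pairs share an
  exact planted overlap against a low-overlap random background;
* :func:`random_dag` draws a random ontology DAG that is acyclic by
  construction.

Planting inverts the expected-count relation of the chosen relative-risk
variant.  With per-patient marginals p_i, p_j and joint probability p_ij,
expected counts are P_i = N p_i and C = N p_ij, so

* standard variant  RR = C N / (P_i P_j):  p_ij = RR p_i p_j;
* modified variant  RR = C N / (P_i P_j − C):
  N p_ij · N = RR (N² p_i p_j − N p_ij)  ⇒  p_ij = RR N p_i p_j / (N + RR).

Neither generator attempts realistic ICD code frequency spectra or real
ontology shapes; see the methods note.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .errors import ValidationError
from .io import GeneSetMap, OntologyGraph, PatientRecordSet, pair_key


@dataclass(frozen=True)
class PopulationSpec:
    """Population with independent diseases except for planted pairs.

    ``planted_pairs`` maps a disease pair to a target relative risk under
    ``variant``.  Marginal probabilities are per-patient Bernoulli rates.
    """

    n_patients: int
    prevalence: dict[str, float]
    planted_pairs: list[tuple[tuple[str, str], float]] = field(default_factory=list)
    variant: str = "standard"
    seed: int = 0

    def __post_init__(self):
        if self.n_patients < 1:
            raise ValidationError("n_patients must be >= 1")
        for d, p in self.prevalence.items():
            if not 0.0 < p < 1.0:
                raise ValidationError(f"marginal probability of {d!r} must be in (0,1), got {p}")
        seen: set[str] = set()
        for (a, b), rr in self.planted_pairs:
            if a not in self.prevalence or b not in self.prevalence:
                raise ValidationError(f"planted pair ({a},{b}) references unknown disease")
            if rr <= 0:
                raise ValidationError("planted target_rr must be > 0")
            if a in seen or b in seen:
                raise ValidationError("a disease may appear in at most one planted pair")
            seen.update((a, b))
            self._joint(a, b, rr)  # feasibility check

    def _joint(self, a: str, b: str, rr: float) -> float:
        p_a, p_b = self.prevalence[a], self.prevalence[b]
        if self.variant == "standard":
            p_ab = rr * p_a * p_b
        else:  # modified denominator: solve C N/(P_i P_j - C) = rr in expectation
            p_ab = rr * self.n_patients * p_a * p_b / (self.n_patients + rr)
        if p_ab > min(p_a, p_b) or p_ab < max(0.0, p_a + p_b - 1.0):
            raise ValidationError(
                f"infeasible joint probability {p_ab:.4g} for planted pair ({a},{b}) at rr={rr}"
            )
        return p_ab


def simulate_patients(spec: PopulationSpec) -> PatientRecordSet:
    """Draw a population; identical spec (incl. seed) -> identical output.

    Patients that draw zero diseases are kept in the population (they count
    in the denominator N); :func:`comorisk.io.write_patient_records` emits a
    sentinel row for them.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_patients
    width = len(str(n))
    patient_ids = [f"p{idx:0{width}d}" for idx in range(1, n + 1)]
    planted_diseases = {d for (pair, _) in spec.planted_pairs for d in pair}
    carriers: dict[str, np.ndarray] = {}
    # planted pairs first (spec order), then remaining diseases in sorted order
    for (a, b), rr in spec.planted_pairs:
        p_a, p_b = spec.prevalence[a], spec.prevalence[b]
        p_ab = spec._joint(a, b, rr)
        u = rng.random(n)
        cut_both = p_ab
        cut_a_only = p_ab + (p_a - p_ab)
        cut_b_only = cut_a_only + (p_b - p_ab)
        carriers[a] = (u < cut_a_only)
        carriers[b] = (u < cut_both) | ((u >= cut_a_only) & (u < cut_b_only))
    for d in sorted(set(spec.prevalence) - planted_diseases):
        carriers[d] = rng.random(n) < spec.prevalence[d]
    records = {
        (patient_ids[i], d)
        for d in carriers
        for i in np.flatnonzero(carriers[d])
    }
    return PatientRecordSet(frozenset(patient_ids), frozenset(records))


@dataclass(frozen=True)
class OverlapSpec:
    """Random gene sets with exact planted overlaps between chosen pairs."""

    n_sets: int
    universe_size: int
    set_size_range: tuple[int, int] = (10, 10)
    planted_overlaps: list[tuple[tuple[int, int], int]] = field(default_factory=list)
    seed: int = 0
    set_kind: str = "disease"

    def __post_init__(self):
        lo, hi = self.set_size_range
        if not 1 <= lo <= hi <= self.universe_size:
            raise ValidationError("need 1 <= min size <= max size <= universe size")
        if self.n_sets < 1:
            raise ValidationError("n_sets must be >= 1")
        seen: set[int] = set()
        for (i, j), k in self.planted_overlaps:
            if not (0 <= i < self.n_sets and 0 <= j < self.n_sets and i != j):
                raise ValidationError(f"planted pair ({i},{j}) out of range")
            if i in seen or j in seen:
                raise ValidationError("a set may appear in at most one planted overlap")
            seen.update((i, j))
            if k > lo:
                raise ValidationError(f"planted overlap {k} exceeds minimum set size {lo}")
            if 2 * hi - k > self.universe_size:
                raise ValidationError("universe too small to keep the planted pair overlap exact")


def random_genesets(spec: OverlapSpec) -> GeneSetMap:
    """Draw the gene-set map; planted pairs share *exactly* their overlap,
    all other sets are uniform draws without replacement."""
    rng = np.random.default_rng(spec.seed)
    gene_width = len(str(spec.universe_size))
    universe = [f"g{idx:0{gene_width}d}" for idx in range(1, spec.universe_size + 1)]
    set_width = len(str(spec.n_sets))
    ids = [f"D{idx:0{set_width}d}" for idx in range(1, spec.n_sets + 1)]
    lo, hi = spec.set_size_range
    sizes = rng.integers(lo, hi + 1, size=spec.n_sets)
    sets: dict[str, frozenset[str]] = {}
    planted_members = {idx for (pair, _) in spec.planted_overlaps for idx in pair}
    for (i, j), k in spec.planted_overlaps:
        need = sizes[i] + sizes[j] - k
        chosen = rng.choice(spec.universe_size, size=need, replace=False)
        shared = chosen[:k]
        own_i = chosen[k:sizes[i]]
        own_j = chosen[sizes[i]:]
        sets[ids[i]] = frozenset(universe[g] for g in np.concatenate([shared, own_i]))
        sets[ids[j]] = frozenset(universe[g] for g in np.concatenate([shared, own_j]))
    for idx in range(spec.n_sets):
        if idx in planted_members:
            continue
        chosen = rng.choice(spec.universe_size, size=sizes[idx], replace=False)
        sets[ids[idx]] = frozenset(universe[g] for g in chosen)
    return GeneSetMap(frozenset(universe), sets, spec.set_kind)


def random_dag(n_terms: int, max_parents: int = 3, seed: int = 0) -> OntologyGraph:
    """Random ontology DAG: terms labelled in topological order, each
    non-root term linked (is_a) to 1..max_parents earlier terms."""
    if n_terms < 1:
        raise ValidationError("n_terms must be >= 1")
    rng = np.random.default_rng(seed)
    width = len(str(n_terms))
    labels = [f"T{idx:0{width}d}" for idx in range(1, n_terms + 1)]
    g = nx.DiGraph()
    g.add_nodes_from(labels)
    for idx in range(1, n_terms):
        n_par = int(rng.integers(1, max_parents + 1))
        n_par = min(n_par, idx)
        parents = rng.choice(idx, size=n_par, replace=False)
        for p in sorted(parents):
            g.add_edge(labels[idx], labels[p], relation="is_a")
    return OntologyGraph(g)


def planted_pair_ids(spec: OverlapSpec) -> list[tuple[str, str]]:
    """Canonical set-id pairs corresponding to the spec's planted overlaps."""
    width = len(str(spec.n_sets))
    return [
        pair_key(f"D{i + 1:0{width}d}", f"D{j + 1:0{width}d}")
        for (i, j), _ in spec.planted_overlaps
    ]
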