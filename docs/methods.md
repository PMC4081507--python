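# Methods

## Clinical co-occurrence model

For a population of N patients, disease i has prevalence count P_i (number
of patients ever diagnosed with i) and a pair (i, j) has joint count C_ij.
Under independence the expected number of co-diagnosed patients is
P_i P_j / N, so the relative risk compares C_ij with that expectation and
the φ-correlation is the Pearson correlation of the two binary disease
indicators.

Two algebraic variants are implemented behind a `variant` switch:

* `modified` (default): `RR = C·N/(P_i P_j − C)` and
  `φ = (CN − P_i P_j)/sqrt((P_i P_j − C)(N−P_i)(N−P_j))`.  These forms carry
  a `−C_ij` term in the denominator.
* `standard`: the classical forms with denominator `P_i P_j`, as used in the
  phenotypic disease-network literature (Hidalgo et al.).  Only this variant
  satisfies |φ| ≤ 1 for every realizable contingency table; the default
  variant can exceed 1 and is deliberately *documented, not clamped*.

Both variants agree in sign and converge when C ≪ P_i P_j (the usual regime
for population data).  We take no position on which is "intended"; the
default preserves the published forms exactly, and cross-study comparisons
should use `standard`.  Degenerate configurations (denominator ≤ 0, possible
only at desk scale) raise a typed signal carried per edge as a flag plus a
sentinel (+inf for RR); a batch computation never aborts.

### Katz interval and significance

σ_ij = sqrt(1/C_ij + 1/(P_i P_j) − 1/N − 1/N²), LB = RR·exp(−z σ),
UB = RR·exp(z σ).  The multiplier defaults to z = 2.56 — kept exactly as
published for a 99% interval rather than the textbook 2.576 — and is
configurable (`--z`).  The edge filter keeps a pair iff (RR > 1 and LB > 1)
or (RR < 1 and UB < 1); pairs with C_ij = 0 have no interval and can never
pass (their RR is 0 with an undefined CI, so they are dropped by
construction).  For φ, t = φ√(n−2)/√(1−φ²) with n read as the number of
patients N (the number of observations entering the 2×2 table).  No default
significance threshold is applied to φ; an optional two-sided p-value from
Student's t with N−2 degrees of freedom can be requested, but edge inclusion
is governed solely by the Katz filter.

`min_count` (default 1) drops pairs with fewer co-occurrences before any
statistic is computed; rare-pair noise is the main practical failure mode of
count-based comorbidity scores.

## Set-overlap association

Disease→gene-set and pathway→gene-set maps are compared pairwise: overlap
count, Jaccard index, and an over-representation p-value
P(X ≥ k) for the hypergeometric distribution with universe N, annotated M,
query n, overlap k — computed through `scipy.stats.hypergeom.sf`, which
works in log space and is verified in the tests against exact
rational-arithmetic enumeration (max relative error ~5·10⁻¹⁶ over the full
N ≤ 15 sweep).  Only the upper tail is offered; the method detects
over-representation, not depletion.

For disease–disease pairs the hypergeometric "query" role is assigned to
the smaller set (ties broken toward the lexicographically first id).  The
tail probability is not exactly role-symmetric, so the convention is fixed
and documented rather than averaged.  BH adjustment
(`statsmodels.multipletests(..., method="fdr_bh")`) is applied within one
call's family — all emitted pairs, or all sets hit by one query — never
pooled across calls.  The FDR threshold (conventionally 0.05) is applied
only when explicitly requested; by default all scored pairs are reported.

Pathway mode shares every code path with gene mode (`set_kind` only labels
outputs).  The disease–gene incidence is also exposed as a bipartite graph
whose one-mode projection carries the Jaccard weights; projection weights
and `associate_sets` Jaccard values agree by construction and are
cross-checked in the tests.

## Ontology semantic similarity

The Wang construction over the ancestor DAG: D_A(A) = 1 and
D_A(t) = max over children t′ of t *within the ancestor closure of A* of
w_e · D_A(t′).  Restricting the max to the closure is the standard Wang
semantics (children outside T_A have no defined contribution); evaluation is
a single pass in topological order, so each value is final when read and is
independent of edge iteration order (max is order-free, no tie-breaking
needed).  Default contribution factors: is_a 0.7, part_of 0.6, unknown
relations 0.7 — the conventional Wang values; all configurable in (0, 1).

S(A,B) ∈ [0, 1]; S(A,A) = 1; S = 0 exactly when the ancestor DAGs are
disjoint (different roots).  DOLite-style simplified vocabularies are just
another ontology input file — the mathematics does not change.  Enrichment
against ontology-term gene sets (the other route to "comorbid in an
ontology sense") goes through the set-overlap module; the two scores are
reported side by side, never merged, as no principled combination rule
exists for them.

## Network assembly

Evidence bundles are merged on canonical (min_id, max_id) pair keys.
Clinical edges must have passed the Katz filter; set-overlap records need
≥ 1 shared element and optionally p_adj ≤ threshold; ontology pairs need
s_sim > 0 and optionally s_sim ≥ threshold.  Evidence types are kept
side-by-side per edge with no composite score.  Tightening any threshold
can only remove edges (monotone filters), and rebuilding a network from its
own TSV export is the identity — both properties are tested.

Identifier vocabularies (OMIM, ICD-9-CM, DOID, display names) are bridged
by a user-supplied crosswalk table; no annotation database is bundled or
fetched.  ICD-9-CM handling is purely lexical (3-digit category truncation,
V/E prefixes, leading zeros preserved); no code-range hierarchy is modelled
because codes function only as identifiers here.

## Synthetic data

The generators define the conditions under which every claim in the test
suite is made:

* **Populations** — diseases are independent per-patient Bernoulli draws at
  their marginal rates except for planted pairs, which are drawn from a 2×2
  joint solved from (marginals, target RR): p_ij = RR·p_i·p_j for the
  standard variant, p_ij = RR·N·p_i·p_j/(N + RR) for the modified
  denominator (solving E[C]·N/(E[P_i]E[P_j] − E[C]) = RR).  Infeasible
  joints (p_ij > min marginal) are rejected at spec construction.  Patients
  with zero diseases stay in N via a sentinel record row.
* **Gene sets** — uniform draws without replacement; planted pairs share
  *exactly* the requested overlap.  For 10-gene sets over a 500-gene
  universe the background overlap stays ≤ 4 with high probability, so a
  planted overlap of 8 is unambiguous.
* **DAGs** — terms labelled in topological order, each non-root term with
  1..max_parents uniformly chosen earlier parents; acyclic by construction.

All generators are pure functions of (spec, seed) and the standard defaults
used in tests are: N = 10⁴ patients, 5% marginal prevalence, planted RR = 5
(clinical); 40 sets of 10 genes over a universe of 500, planted overlap 8
(annotation); 30-term DAGs with ≤ 3 parents (ontology).  These sizes keep
the whole suite in the seconds-to-a-minute range while leaving the planted
effects far outside sampling noise (at C ≈ 125 the log-RR standard error is
≈ 0.09, so RR = 5 sits ≈ 18 standard errors from the null).

What the simulations do *not* emulate: realistic ICD code frequency
spectra (real prevalence is heavy-tailed), age/sex structure and coding
artefacts in claims data, correlated gene-set families, and the shape of
real disease ontologies.  Passing tests therefore demonstrate correctness
of the estimators and pipeline under the stated model, not robustness to
real-world confounding (the method applies no prevalence correction or
stratification by design).

## Numerical and design notes

* Pair keys are canonicalized lexicographically; all outputs report
  (min_id, max_id); self-pairs are rejected.
* TSV exports format floats with `%.12g` and emit rows in sorted pair
  order, making byte-identical reruns the expected behaviour (tested
  end-to-end through the CLI).
* The planted-RR recovery check compares the across-seed mean of the
  empirical RR (20 seeds) against the planted value; a single seed's
  estimate has ≈ ±9% log-scale standard error at these sizes, the mean
  ≈ ±2%.
* OBO parsing uses `obonet` and keeps only id/name/is_a/relationship;
  referenced-but-undeclared parents are an error, as are cycles (one
  witness cycle is reported).
* Degenerate inputs never crash batch operations: they are flagged per
  record and excluded from significance, so a single pathological pair
  cannot poison a population-scale run.

## Known limitations

* The modified-denominator default means published Hidalgo-style RR/φ values
  are only reproduced under `variant="standard"`.
* Hypergeometric enrichment assumes the universe is the correct reference;
  an inflated universe anti-conservatively shrinks p-values.  The universe
  is therefore user-controllable (explicit universe file) rather than
  silently inferred when it matters.
* Wang similarity depends on the chosen contribution factors; 0.7/0.6 are
  conventional, not fitted.
* No causal claims: the network records association evidence only.  The
  significant-pair adjacency can be exported as TSV for external causal
  discovery tools, but no such algorithm is included.
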