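"""Pairwise comorbidity statistics from disease co-occurrence counts.

For diseases i and j observed in a population of N patients with prevalence
counts P_i, P_j and joint count C_ij, two strengths of association are
computed:

* relative risk  RR_ij — observed co-occurrence over the random expectation
  from prevalence.  Two variants are provided: ``modified`` uses the
  denominator (P_i P_j − C_ij); ``standard`` uses the classical P_i P_j.
* φ-correlation — Pearson correlation of the two binary disease indicators.
  The ``modified`` variant mirrors the same modified denominator; the
  ``standard`` variant is the textbook φ and is bounded by |φ| ≤ 1.  The
  ``modified`` variant is *not* bounded by 1; callers comparing against the
  classical phenotypic-network literature should use ``standard``.

Significance of RR uses the Katz log-normal approximation: the interval
[RR·exp(−z σ), RR·exp(z σ)] with σ = sqrt(1/C + 1/(P_i P_j) − 1/N − 1/N²)
and z = 2.56 (a 99% interval).  A pair is retained when the interval
excludes 1 on the side of its point estimate: LB > 1 for RR > 1, UB < 1 for
RR < 1.  Significance of φ uses t = φ sqrt(n−2)/sqrt(1−φ²) with n the number
of observations (patients).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import pandas as pd
from scipy import stats

from .errors import (
    DegenerateStatisticError,
    DomainError,
    UndefinedConfidenceIntervalError,
    ValidationError,
)
from .io import CooccurrenceTable

DEFAULT_Z = 2.56  #: multiplier for the 99% Katz interval

_VARIANTS = ("modified", "standard")


def _validate_counts(c: int, n: int, p_i: int, p_j: int) -> None:
    if n < 1:
        raise ValidationError("population size n must be >= 1")
    if not (0 <= p_i <= n and 0 <= p_j <= n):
        raise ValidationError("prevalences must satisfy 0 <= p <= n")
    if not (0 <= c <= min(p_i, p_j)):
        raise ValidationError("co-occurrence count must satisfy 0 <= c <= min(p_i, p_j)")


def _check_variant(variant: str) -> None:
    if variant not in _VARIANTS:
        raise ValidationError(f"variant must be one of {_VARIANTS}, got {variant!r}")


def relative_risk(c: int, n: int, p_i: int, p_j: int, variant: str = "modified") -> float:
    """Relative risk of co-occurrence: C·N / (P_i P_j − C) or C·N / (P_i P_j).

    Returns 0 for C = 0.  The modified variant raises
    :class:`DegenerateStatisticError` (sentinel +inf) when its denominator is
    not positive.
    """
    _check_variant(variant)
    _validate_counts(c, n, p_i, p_j)
    if c == 0:
        return 0.0
    denom = p_i * p_j - c if variant == "modified" else p_i * p_j
    if denom <= 0:
        raise DegenerateStatisticError(
            f"relative-risk denominator P_i*P_j - C = {denom} is not positive",
            sentinel=math.inf,
        )
    return c * n / denom


def phi_correlation(c: int, n: int, p_i: int, p_j: int, variant: str = "modified") -> float:
    """φ-correlation (CN − P_i P_j) / sqrt(D (N−P_i)(N−P_j)).

    D is (P_i P_j − C) for the modified variant and P_i P_j for the standard
    (textbook binary-Pearson) variant.  Sign equals sign(CN − P_i P_j) in
    both.
    """
    _check_variant(variant)
    _validate_counts(c, n, p_i, p_j)
    d = p_i * p_j - c if variant == "modified" else p_i * p_j
    radicand = d * (n - p_i) * (n - p_j)
    if radicand <= 0:
        raise DegenerateStatisticError(f"phi radicand {radicand} is not positive", sentinel=math.nan)
    return (c * n - p_i * p_j) / math.sqrt(radicand)


def katz_interval(rr: float, c: int, n: int, p_i: int, p_j: int,
                  z: float = DEFAULT_Z) -> tuple[float, float, float]:
    """Katz log-normal interval (sigma, lb, ub) around a relative risk.

    sigma = sqrt(1/C + 1/(P_i P_j) − 1/N − 1/N²); lb = RR·exp(−z·sigma);
    ub = RR·exp(z·sigma).  Undefined at C = 0.
    """
    _validate_counts(c, n, p_i, p_j)
    if c == 0:
        raise UndefinedConfidenceIntervalError("sigma is undefined at C_ij = 0")
    if not (math.isfinite(rr) and rr > 0):
        raise DomainError(f"rr must be finite and positive, got {rr}")
    radicand = 1.0 / c + 1.0 / (p_i * p_j) - 1.0 / n - 1.0 / (n * n)
    if radicand < 0:
        raise DegenerateStatisticError(f"sigma radicand {radicand} is negative", sentinel=math.nan)
    sigma = math.sqrt(radicand)
    return sigma, rr * math.exp(-z * sigma), rr * math.exp(z * sigma)


def phi_t_statistic(phi: float, n_obs: int) -> float:
    """t = φ sqrt(n−2) / sqrt(1−φ²) for testing φ ≠ 0 (odd in φ)."""
    if n_obs < 3:
        raise DomainError(f"need n_obs >= 3 observations, got {n_obs}")
    if not abs(phi) < 1:
        raise DomainError(f"|phi| must be < 1, got {phi}")
    return phi * math.sqrt(n_obs - 2) / math.sqrt(1.0 - phi * phi)


@dataclass
class ComorbidityEdge:
    """One disease pair with its full comorbidity statistics.

    ``flags`` records degenerate conditions (e.g. ``undefined_ci``,
    ``degenerate_rr``) instead of aborting a batch; such edges always carry
    ``significant=False``.
    """

    pair: tuple[str, str]
    c: int
    n: int
    p_i: int
    p_j: int
    variant: str
    rr: float
    phi: float | None = None
    sigma: float | None = None
    lb: float | None = None
    ub: float | None = None
    t_stat: float | None = None
    p_phi: float | None = None
    significant: bool = False
    flags: tuple[str, ...] = field(default_factory=tuple)


def comorbidity_table(table: CooccurrenceTable, variant: str = "modified",
                      z: float = DEFAULT_Z, min_count: int = 1,
                      phi_p_values: bool = False) -> list[ComorbidityEdge]:
    """Compute a ComorbidityEdge for every pair with C_ij >= min_count.

    Degenerate statistics are recorded per-edge via ``flags`` and sentinel
    values; the batch never aborts.  ``phi_p_values`` adds a two-sided
    Student-t p-value for φ with df = N − 2.
    """
    _check_variant(variant)
    n = table.n_patients
    edges: list[ComorbidityEdge] = []
    for (i, j) in sorted(table.pair_counts):
        c = table.pair_counts[(i, j)]
        if c < min_count:
            continue
        p_i, p_j = table.prevalence[i], table.prevalence[j]
        flags: list[str] = []
        try:
            rr = relative_risk(c, n, p_i, p_j, variant)
        except DegenerateStatisticError as err:
            rr = err.sentinel
            flags.append("degenerate_rr")
        try:
            phi = phi_correlation(c, n, p_i, p_j, variant)
        except DegenerateStatisticError:
            phi = None
            flags.append("degenerate_phi")
        sigma = lb = ub = None
        if math.isfinite(rr) and rr > 0:
            try:
                sigma, lb, ub = katz_interval(rr, c, n, p_i, p_j, z)
            except (UndefinedConfidenceIntervalError, DegenerateStatisticError):
                flags.append("undefined_ci")
        else:
            flags.append("undefined_ci")
        t_stat = p_phi = None
        if phi is not None and abs(phi) < 1 and n >= 3:
            t_stat = phi_t_statistic(phi, n)
            if phi_p_values:
                p_phi = 2.0 * stats.t.sf(abs(t_stat), df=n - 2)
        significant = lb is not None and ((rr > 1 and lb > 1) or (rr < 1 and ub < 1))
        edges.append(ComorbidityEdge(
            pair=(i, j), c=c, n=n, p_i=p_i, p_j=p_j, variant=variant,
            rr=rr, phi=phi, sigma=sigma, lb=lb, ub=ub,
            t_stat=t_stat, p_phi=p_phi, significant=significant,
            flags=tuple(flags),
        ))
    return edges


def apply_ci_filter(edges: list[ComorbidityEdge]) -> list[ComorbidityEdge]:
    """Keep pairs whose 99% Katz interval excludes 1 on the side of RR:
    (RR > 1 and LB > 1) or (RR < 1 and UB < 1).  Edges with an undefined
    interval are dropped."""
    kept = []
    for e in edges:
        if e.lb is None or e.ub is None:
            continue
        if (e.rr > 1 and e.lb > 1) or (e.rr < 1 and e.ub < 1):
            kept.append(e)
    return kept


_EDGE_COLUMNS = ["disease_i", "disease_j", "c", "n", "p_i", "p_j", "variant",
                 "rr", "phi", "sigma", "lb", "ub", "t", "p_phi", "significant", "flags"]


def edges_to_frame(edges: list[ComorbidityEdge]) -> pd.DataFrame:
    rows = [{
        "disease_i": e.pair[0], "disease_j": e.pair[1], "c": e.c, "n": e.n,
        "p_i": e.p_i, "p_j": e.p_j, "variant": e.variant, "rr": e.rr,
        "phi": e.phi, "sigma": e.sigma, "lb": e.lb, "ub": e.ub,
        "t": e.t_stat, "p_phi": e.p_phi, "significant": e.significant,
        "flags": ";".join(e.flags),
    } for e in edges]
    return pd.DataFrame(rows, columns=_EDGE_COLUMNS)


def _fmt(x) -> str:
    if x is None or (isinstance(x, float) and math.isnan(x)):
        return ""
    if isinstance(x, bool):
        return str(x).lower()
    if isinstance(x, float):
        return format(x, ".12g")
    return str(x)


def write_edges(edges: list[ComorbidityEdge], path) -> None:
    """Write the TSV edge table (deterministic order and float format)."""
    frame = edges_to_frame(edges)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(_EDGE_COLUMNS) + "\n")
        for row in frame.itertuples(index=False):
            fh.write("\t".join(_fmt(v) for v in row) + "\n")


def read_edges(path) -> list[ComorbidityEdge]:
    frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    edges = []
    for row in frame.itertuples(index=False):
        def opt(v):
            return None if v == "" else float(v)
        edges.append(ComorbidityEdge(
            pair=(str(row.disease_i), str(row.disease_j)),
            c=int(row.c), n=int(row.n), p_i=int(row.p_i), p_j=int(row.p_j),
            variant=row.variant, rr=float(row.rr), phi=opt(row.phi),
            sigma=opt(row.sigma), lb=opt(row.lb), ub=opt(row.ub),
            t_stat=opt(row.t), p_phi=opt(row.p_phi),
            significant=(str(row.significant).lower() == "true"),
            flags=tuple(f for f in str(row.flags).split(";") if f),
        ))
    return edges
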