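"""Clinical comorbidity statistics: closed forms, variants, CI filter."""

import math
from fractions import Fraction

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from comorisk import (
    CooccurrenceTable,
    apply_ci_filter,
    comorbidity_table,
    katz_interval,
    phi_correlation,
    phi_t_statistic,
    relative_risk,
)
from comorisk.clinical import ComorbidityEdge, read_edges, write_edges
from comorisk.errors import (
    DegenerateStatisticError,
    DomainError,
    UndefinedConfidenceIntervalError,
    ValidationError,
)

from conftest import oracle_phi, oracle_rr

# a realizable contingency configuration: max(0, p_i+p_j-n) <= c <= min(p_i, p_j)
count_tuples = st.tuples(
    st.integers(min_value=4, max_value=5000),   # n
    st.integers(min_value=1, max_value=200),    # p_i
    st.integers(min_value=1, max_value=200),    # p_j
    st.integers(min_value=0, max_value=200),    # c (clamped below)
).map(lambda t: (max(min(t[3], t[1], t[2]), t[1] + t[2] - (t[0] + max(t[1], t[2]))),
                 t[0] + max(t[1], t[2]), t[1], t[2]))


class TestRelativeRisk:
    def test_exact_value_modified_variant(self):
        assert relative_risk(10, 1000, 20, 30, "modified") == pytest.approx(10000 / 590, rel=1e-15)

    def test_exact_value_standard_variant(self):
        assert relative_risk(10, 1000, 20, 30, "standard") == pytest.approx(10000 / 600, rel=1e-15)

    def test_zero_cooccurrence_gives_zero(self):
        assert relative_risk(0, 1000, 20, 30) == 0.0

    def test_degenerate_denominator_signals_infinity(self):
        with pytest.raises(DegenerateStatisticError) as err:
            relative_risk(1, 10, 1, 1, "modified")
        assert err.value.sentinel == math.inf

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValidationError):
            relative_risk(5, 100, 3, 10)  # c > p_i

    @given(count_tuples)
    @settings(max_examples=200, derandomize=True)
    def test_strictly_increasing_in_c(self, tup):
        c, n, p_i, p_j = tup
        for variant in ("modified", "standard"):
            if c + 1 > min(p_i, p_j):
                continue
            try:
                lo = relative_risk(c, n, p_i, p_j, variant)
                hi = relative_risk(c + 1, n, p_i, p_j, variant)
            except DegenerateStatisticError:
                continue
            assert hi > lo


class TestPhi:
    def test_zero_at_independence_point(self):
        assert phi_correlation(6, 100, 20, 30, "modified") == 0.0

    def test_exact_value_modified_variant(self):
        expected = 9400 / math.sqrt(590 * 980 * 970)
        assert phi_correlation(10, 1000, 20, 30, "modified") == pytest.approx(expected, rel=1e-15)

    def test_standard_variant_strictly_smaller(self):
        modified = phi_correlation(10, 1000, 20, 30, "modified")
        standard = phi_correlation(10, 1000, 20, 30, "standard")
        assert standard == pytest.approx(9400 / math.sqrt(600 * 980 * 970), rel=1e-15)
        assert standard < modified

    def test_degenerate_radicand_signals(self):
        with pytest.raises(DegenerateStatisticError):
            phi_correlation(2, 10, 2, 10, "modified")  # n == p_j

    @given(count_tuples)
    @settings(max_examples=300, derandomize=True)
    def test_sign_matches_independence_gap_and_standard_bounded(self, tup):
        c, n, p_i, p_j = tup
        gap = c * n - p_i * p_j
        for variant in ("modified", "standard"):
            try:
                phi = phi_correlation(c, n, p_i, p_j, variant)
            except DegenerateStatisticError:
                continue
            assert math.copysign(1, phi) == math.copysign(1, gap) or phi == gap == 0
            if variant == "standard":
                assert abs(phi) <= 1 + 1e-12


class TestKatzInterval:
    def test_example_values(self):
        rr = relative_risk(10, 1000, 20, 30)
        sigma, lb, ub = katz_interval(rr, 10, 1000, 20, 30)
        assert sigma == pytest.approx(math.sqrt(0.1 + 1 / 600 - 1e-3 - 1e-6), rel=1e-14)
        assert lb == pytest.approx(7.5231, rel=1e-4)
        assert ub == pytest.approx(38.1853, rel=1e-4)

    @given(count_tuples)
    @settings(max_examples=200, derandomize=True)
    def test_interval_brackets_rr(self, tup):
        c, n, p_i, p_j = tup
        if c == 0:
            return
        try:
            rr = relative_risk(c, n, p_i, p_j)
            sigma, lb, ub = katz_interval(rr, c, n, p_i, p_j)
        except DegenerateStatisticError:
            return
        assert lb < rr < ub
        assert sigma > 0

    def test_zero_multiplier_collapses_interval(self):
        rr = relative_risk(10, 1000, 20, 30)
        _, lb, ub = katz_interval(rr, 10, 1000, 20, 30, z=0.0)
        assert lb == rr == ub

    def test_undefined_at_zero_count(self):
        with pytest.raises(UndefinedConfidenceIntervalError):
            katz_interval(1.0, 0, 100, 10, 10)


class TestPhiT:
    @pytest.mark.parametrize("phi,n,expected", [
        (0.0, 100, 0.0),
        (0.5, 11, 1.5 / math.sqrt(0.75)),
        (-0.5, 11, -1.5 / math.sqrt(0.75)),
    ])
    def test_closed_form_and_odd_symmetry(self, phi, n, expected):
        assert phi_t_statistic(phi, n) == pytest.approx(expected, rel=1e-12)

    @pytest.mark.parametrize("phi,n", [(1.0, 10), (-1.2, 10), (0.5, 2)])
    def test_domain_errors(self, phi, n):
        with pytest.raises(DomainError):
            phi_t_statistic(phi, n)


class TestComorbidityTable:
    def test_single_pair_composition(self):
        table = CooccurrenceTable(1000, {"A": 20, "B": 30}, {("A", "B"): 10})
        (edge,) = comorbidity_table(table)
        assert edge.rr == pytest.approx(float(oracle_rr(10, 1000, 20, 30)), rel=1e-12)
        assert edge.phi == pytest.approx(float(oracle_phi(10, 1000, 20, 30)), rel=1e-12)
        assert edge.significant and edge.lb > 1
        assert edge.t_stat == pytest.approx(
            edge.phi * math.sqrt(998) / math.sqrt(1 - edge.phi**2), rel=1e-12)

    def test_no_cooccurrence_gives_empty_list(self):
        table = CooccurrenceTable(100, {"A": 5, "B": 5}, {})
        assert comorbidity_table(table) == []

    def test_min_count_drops_rare_pairs(self):
        table = CooccurrenceTable(100, {"A": 10, "B": 10, "C": 10},
                                  {("A", "B"): 1, ("A", "C"): 5})
        edges = comorbidity_table(table, min_count=2)
        assert [e.pair for e in edges] == [("A", "C")]

    def test_degenerate_edges_flagged_not_fatal(self):
        # modified denominator collapses: P_i*P_j == C
        table = CooccurrenceTable(10, {"A": 1, "B": 1, "C": 5, "D": 5},
                                  {("A", "B"): 1, ("C", "D"): 3})
        edges = comorbidity_table(table, variant="modified")
        by_pair = {e.pair: e for e in edges}
        bad = by_pair[("A", "B")]
        assert bad.rr == math.inf and "degenerate_rr" in bad.flags
        assert not bad.significant
        assert ("C", "D") in by_pair  # batch survived

    def test_edge_table_round_trip(self, tmp_path):
        table = CooccurrenceTable(1000, {"A": 20, "B": 30, "C": 15},
                                  {("A", "B"): 10, ("A", "C"): 1})
        edges = comorbidity_table(table, phi_p_values=True)
        path = tmp_path / "edges.tsv"
        write_edges(edges, path)
        back = read_edges(path)
        assert [e.pair for e in back] == [e.pair for e in edges]
        for a, b in zip(back, edges):
            assert a.rr == pytest.approx(b.rr, rel=1e-10)
            assert a.significant == b.significant


class TestCiFilter:
    @staticmethod
    def _edge(rr, lb, ub):
        return ComorbidityEdge(pair=("A", "B"), c=1, n=10, p_i=2, p_j=2,
                               variant="modified", rr=rr, lb=lb, ub=ub)

    @pytest.mark.parametrize("rr,lb,ub,kept", [
        (16.95, 7.52, 38.19, True),    # risk branch, LB > 1
        (1.2, 0.9, 1.6, False),        # interval straddles 1
        (0.5, 0.3, 0.8, True),         # protective branch, UB < 1
        (0.5, 0.3, 1.1, False),
        (1.0, 0.8, 1.3, False),        # RR exactly 1 satisfies neither branch
    ])
    def test_rule_branches(self, rr, lb, ub, kept):
        assert (apply_ci_filter([self._edge(rr, lb, ub)]) != []) is kept

    def test_undefined_ci_dropped(self):
        edge = self._edge(2.0, None, None)
        assert apply_ci_filter([edge]) == []
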