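"""Network assembly, export formats, idempotence, neighbourhood query, CLI."""

import networkx as nx
import pytest
from click.testing import CliRunner

from comorisk import (
    CooccurrenceTable,
    build_network,
    comorbidity_table,
    export_graph,
    query_disease,
    read_network_tsv,
)
from comorisk.cli import main as cli_main
from comorisk.errors import LookupError_, ValidationError
from comorisk.genesets import AssociationRecord
from comorisk.io import CrosswalkRow, IdCrosswalk
from comorisk.network import network_to_frame
from comorisk.ontology import SimilarityResult


def _assoc(a, b, p_adj=0.01, shared=2, jac=0.5):
    return AssociationRecord(pair=(a, b), shared_count=shared, jaccard=jac,
                             p_raw=p_adj / 2, p_adj=p_adj,
                             shared_elements=frozenset(f"g{i}" for i in range(shared)))


def _sim(a, b, s):
    return SimilarityResult(pair=(a, b), dv_a=2.0, dv_b=2.0,
                            shared_terms=frozenset({"R"}) if s else frozenset(), s_sim=s)


@pytest.fixture
def clinical_edges():
    table = CooccurrenceTable(1000, {"042": 20, "250": 30, "714.0": 15},
                              {("042", "250"): 10, ("250", "714.0"): 1})
    return comorbidity_table(table)


class TestBuildNetwork:
    def test_evidence_merged_on_same_pair(self, clinical_edges):
        net = build_network(clinical=clinical_edges, geneset=[_assoc("042", "250")])
        assert set(net.edges[("042", "250")]) == {"clinical", "geneset"}

    def test_disjoint_pairs_sum(self, clinical_edges):
        net = build_network(clinical=clinical_edges, geneset=[_assoc("X", "Y")],
                            ontology=[_sim("U", "V", 0.4)])
        # only (042,250) survives the CI filter among clinical pairs
        assert len(net.edges) == 3

    def test_clinical_edges_pass_ci_filter(self, clinical_edges):
        net = build_network(clinical=clinical_edges)
        assert list(net.edges) == [("042", "250")]

    def test_threshold_filters_are_monotone(self, clinical_edges):
        sources = dict(clinical=clinical_edges,
                       geneset=[_assoc("A", "B", 0.2), _assoc("C", "D", 0.01)],
                       ontology=[_sim("U", "V", 0.3), _sim("U", "W", 0.8)])
        loose = build_network(**sources)
        tight = build_network(**sources, p_adj_max=0.05, s_sim_min=0.5)
        assert set(tight.edges) <= set(loose.edges)
        assert ("A", "B") not in tight.edges and ("U", "V") not in tight.edges

    def test_zero_similarity_never_an_edge(self):
        net = build_network(clinical=[], geneset=[_assoc("A", "B")],
                            ontology=[_sim("A", "C", 0.0)])
        assert list(net.edges) == [("A", "B")]

    def test_strict_crosswalk_names_offenders(self, clinical_edges):
        xw = IdCrosswalk([CrosswalkRow(icd9="042", name="HIV")])
        with pytest.raises(LookupError_, match="250"):
            build_network(clinical=clinical_edges, crosswalk=xw, strict_crosswalk=True)


class TestExport:
    def test_graphml_round_trip(self, clinical_edges, tmp_path):
        net = build_network(clinical=clinical_edges, geneset=[_assoc("042", "250")])
        path = tmp_path / "n.graphml"
        export_graph(net, path, "graphml")
        g = nx.read_graphml(path)
        assert g.number_of_nodes() == 2 and g.number_of_edges() == 1
        attrs = g.edges["042", "250"]
        assert attrs["clinical_rr"] == pytest.approx(10000 / 590, rel=1e-10)
        assert attrs["geneset_jaccard"] == pytest.approx(0.5)

    def test_tsv_idempotent_rebuild(self, clinical_edges, tmp_path):
        net = build_network(clinical=clinical_edges, geneset=[_assoc("042", "250")],
                            ontology=[_sim("U", "V", 0.4)])
        p1, p2 = tmp_path / "a.tsv", tmp_path / "b.tsv"
        export_graph(net, p1, "tsv")
        rebuilt = read_network_tsv(p1)
        export_graph(rebuilt, p2, "tsv")
        assert p1.read_bytes() == p2.read_bytes()
        assert set(rebuilt.edges) == set(net.edges)

    def test_dot_deterministic(self, clinical_edges, tmp_path):
        net = build_network(clinical=clinical_edges, geneset=[_assoc("A", "B")])
        p1, p2 = tmp_path / "a.dot", tmp_path / "b.dot"
        export_graph(net, p1, "dot")
        export_graph(net, p2, "dot")
        assert p1.read_bytes() == p2.read_bytes()
        assert p1.read_text().startswith("graph comorbidity {")

    def test_unknown_format_rejected(self, clinical_edges, tmp_path):
        net = build_network(clinical=clinical_edges)
        with pytest.raises(ValidationError):
            export_graph(net, tmp_path / "x", "svg")


class TestQueryDisease:
    @pytest.fixture
    def net(self, clinical_edges):
        return build_network(clinical=clinical_edges,
                             geneset=[_assoc("042", "250"), _assoc("042", "V10")])

    def test_partner_report(self, net):
        report = query_disease(net, "042")
        assert list(report["partner"]) == ["250", "V10"]
        assert report.loc[0, "evidence_count"] == 2

    def test_crosswalk_resolution(self, net):
        xw = IdCrosswalk([CrosswalkRow(omim="999999", icd9="042", name="HIV")])
        report = query_disease(net, "999999", crosswalk=xw)
        assert len(report) == 2

    def test_known_id_absent_from_evidence_is_empty(self, net):
        xw = IdCrosswalk([CrosswalkRow(icd9="777", name="unrelated")])
        report = query_disease(net, "777", crosswalk=xw)
        assert report.empty

    def test_unknown_id_raises_with_suggestions(self, net):
        with pytest.raises(LookupError_):
            query_disease(net, "zzz")

    def test_sort_order_contract(self, net):
        report = query_disease(net, "042")
        key = list(zip(-report["evidence_count"],
                       [-x if x == x else float("inf") for x in report["clinical_rr"].astype(float)]))
        assert key == sorted(key)


class TestCli:
    def test_end_to_end_determinism(self, tmp_path):
        """Identical seeds and configs must produce byte-identical outputs."""
        runner = CliRunner()
        outputs = []
        for tag in ("run1", "run2"):
            d = tmp_path / tag
            d.mkdir()
            steps = [
                ["simulate", "patients", "--n-patients", "800", "--plant", "D1:D2:5",
                 "--seed", "7", "--out", str(d / "recs.tsv")],
                ["clinical", "--records", str(d / "recs.tsv"), "--out", str(d / "edges.tsv")],
                ["simulate", "genesets", "--n-sets", "10", "--universe-size", "120",
                 "--plant", "0:1:6", "--seed", "7", "--out", str(d / "sets.gmt")],
                ["geneset", "--gmt", str(d / "sets.gmt"), "--out", str(d / "assoc.tsv")],
                ["network", "--clinical", str(d / "edges.tsv"), "--geneset", str(d / "assoc.tsv"),
                 "--tsv", str(d / "net.tsv"), "--graphml", str(d / "net.graphml"),
                 "--dot", str(d / "net.dot")],
            ]
            for args in steps:
                result = runner.invoke(cli_main, args, catch_exceptions=False)
                assert result.exit_code == 0
            outputs.append({f.name: f.read_bytes() for f in sorted(d.iterdir())})
        assert outputs[0] == outputs[1]

    def test_query_subcommand(self, tmp_path, clinical_edges):
        net = build_network(clinical=clinical_edges)
        net_path = tmp_path / "net.tsv"
        export_graph(net, net_path, "tsv")
        out = tmp_path / "report.tsv"
        runner = CliRunner()
        result = runner.invoke(cli_main, ["query", "--network", str(net_path),
                                          "--id", "042", "--out", str(out)],
                               catch_exceptions=False)
        assert result.exit_code == 0
        assert "250" in out.read_text()


def test_network_frame_column_stability(clinical_edges):
    frame = network_to_frame(build_network(clinical=clinical_edges))
    assert frame.columns[0] == "disease_i" and "ontology_s_sim" in frame.columns
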