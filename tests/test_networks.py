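"""Network loading, pathogenic-gene filtering, and C-T / C-T-P assembly."""

import networkx as nx
import pandas as pd
import pytest

from fcig.networks import (
    PathogenicGeneSet,
    build_ct_network,
    build_ctp_network,
    build_disease_network,
    degree_table,
    filter_pathogenic,
    load_ppi,
    network_summary,
    write_sif,
)


def _pgs(genes):
    return PathogenicGeneSet(frozenset(genes), {}, 0.0)


class TestLoadPPI:
    def test_dedupe_and_self_loop_removal(self, tmp_path):
        path = tmp_path / "edges.tsv"
        path.write_text("A\tB\nB\tA\nB\tB\n")
        g = load_ppi(path)
        assert set(g.nodes) == {"A", "B"}
        assert g.number_of_edges() == 1

    def test_symbols_uppercased_and_stripped(self, tmp_path):
        path = tmp_path / "edges.tsv"
        path.write_text("tp53 \tmdm2\n")
        g = load_ppi(path)
        assert set(g.nodes) == {"TP53", "MDM2"}

    def test_empty_file_warns(self, tmp_path, caplog):
        path = tmp_path / "empty.tsv"
        path.write_text("")
        with caplog.at_level("WARNING"):
            g = load_ppi(path)
        assert g.number_of_nodes() == 0
        assert any("empty" in r.message for r in caplog.records)

    def test_single_column_raises_with_line_number(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("A\tB\nJUSTONE\n")
        with pytest.raises(ValueError, match="line 2"):
            load_ppi(path)

    def test_confidence_filter(self, tmp_path):
        path = tmp_path / "edges.tsv"
        path.write_text("A\tB\t0.9\nC\tD\t0.2\n")
        g = load_ppi(path, min_confidence=0.5)
        assert set(map(frozenset, g.edges)) == {frozenset({"A", "B"})}


class TestFilterPathogenic:
    def test_strict_above_mean(self):
        table = pd.DataFrame({"gene": ["A", "B", "C"], "score": [1, 2, 3]})
        result = filter_pathogenic(table)
        assert result.genes == frozenset({"C"})
        assert result.mean_score == pytest.approx(2.0)

    def test_all_equal_scores_give_empty_set(self):
        table = pd.DataFrame({"gene": ["A", "B"], "score": [2, 2]})
        assert filter_pathogenic(table).genes == frozenset()

    def test_non_numeric_rows_rejected_with_warning(self, caplog):
        table = pd.DataFrame({"gene": ["A", "B", "C"], "score": [1, "n/a", 4]})
        with caplog.at_level("WARNING"):
            result = filter_pathogenic(table)
        assert result.genes == frozenset({"C"})  # mean over A, C = 2.5
        assert any("non-numeric" in r.message for r in caplog.records)

    def test_empty_table_raises(self):
        with pytest.raises(ValueError):
            filter_pathogenic(pd.DataFrame({"gene": [], "score": []}))


class TestDiseaseNetwork:
    def test_induced_subgraph_with_isolates(self):
        ppi = nx.Graph([("A", "B"), ("B", "D")])
        net = build_disease_network(_pgs({"A", "B", "C"}), ppi)
        assert set(net.nodes) == {"A", "B", "C"}
        assert set(map(frozenset, net.edges)) == {frozenset({"A", "B"})}

    def test_disjoint_pathogenic_set_gives_isolates(self):
        ppi = nx.Graph([("X", "Y")])
        net = build_disease_network(_pgs({"A", "B", "C"}), ppi)
        assert net.number_of_nodes() == 3
        assert net.number_of_edges() == 0

    def test_counts_match_set_arithmetic(self, synthetic_run):
        scores = synthetic_run["scores"][["gene", "score"]]
        pathogenic = filter_pathogenic(scores)
        ppi = synthetic_run["ppi"]
        net = build_disease_network(pathogenic, ppi)
        assert net.number_of_nodes() == len(pathogenic.genes)
        assert set(net.edges) <= set(ppi.subgraph(pathogenic.genes).edges)


class TestCTNetwork:
    def test_complete_bipartite_counts(self):
        active = pd.DataFrame({"ingredient_id": ["I1", "I2"]})
        tm = pd.DataFrame(
            {"ingredient_id": ["I1"] * 3 + ["I2"] * 3, "gene": ["G1", "G2", "G3"] * 2}
        )
        ct = build_ct_network(active, tm)
        assert ct.number_of_nodes() == 5
        assert ct.number_of_edges() == 6
        ing_deg = degree_table(ct, kind="ingredient")
        assert ing_deg["degree"].mean() == pytest.approx(3.0)

    def test_isolated_ingredient_kept(self):
        active = pd.DataFrame({"ingredient_id": ["I1", "I2"]})
        tm = pd.DataFrame({"ingredient_id": ["I1"], "gene": ["G1"]})
        ct = build_ct_network(active, tm)
        assert ct.degree("I2") == 0

    def test_non_active_map_rows_dropped(self, caplog):
        active = pd.DataFrame({"ingredient_id": ["I1"]})
        tm = pd.DataFrame({"ingredient_id": ["I1", "IX"], "gene": ["G1", "G2"]})
        with caplog.at_level("WARNING"):
            ct = build_ct_network(active, tm)
        assert "IX" not in ct
        assert "G2" not in ct

    def test_mean_degree_tracks_generator_parameters(self, synthetic_run, default_config):
        active = synthetic_run["ingredients"]  # no screening: all 30
        ct = build_ct_network(active, synthetic_run["target_map"])
        n_core = default_config.planted_core_size
        n_fill = default_config.n_herbs * default_config.ingredients_per_herb - n_core
        expected = (
            n_core * default_config.targets_per_core_ingredient
            + n_fill * default_config.targets_per_filler_ingredient
        ) / (n_core + n_fill)
        mean_deg = degree_table(ct, kind="ingredient")["degree"].mean()
        assert mean_deg == pytest.approx(expected, rel=0.15)


class TestCTPNetwork:
    def test_union_rule_by_hand(self):
        active = pd.DataFrame({"ingredient_id": ["I1"]})
        ct = build_ct_network(active, pd.DataFrame({"ingredient_id": ["I1"], "gene": ["G1"]}))
        ppi = nx.Graph([("G1", "G2"), ("G3", "G4")])
        ctp = build_ctp_network(ct, ppi, _pgs({"G2"}))
        assert set(ctp.nodes) == {"I1", "G1", "G2"}
        assert set(map(frozenset, ctp.edges)) == {
            frozenset({"I1", "G1"}),
            frozenset({"G1", "G2"}),
        }

    def test_empty_ct_reduces_to_disease_context(self):
        ct = build_ct_network(pd.DataFrame({"ingredient_id": []}), pd.DataFrame({"ingredient_id": [], "gene": []}))
        ppi = nx.Graph([("A", "B"), ("B", "C"), ("C", "D")])
        ctp = build_ctp_network(ct, ppi, _pgs({"A", "B"}))
        assert set(ctp.nodes) == {"A", "B"}
        assert set(map(frozenset, ctp.edges)) == {frozenset({"A", "B"})}

    def test_provenance_counts_are_disjoint(self, synthetic_run):
        active = synthetic_run["ingredients"]
        ct = build_ct_network(active, synthetic_run["target_map"])
        pathogenic = filter_pathogenic(synthetic_run["scores"][["gene", "score"]])
        ctp = build_ctp_network(ct, synthetic_run["ppi"], pathogenic)
        summary = network_summary(ctp)
        by_source = summary["edges_by_source"]
        assert by_source.get("ct", 0) + by_source.get("ppi", 0) == summary["n_edges"]
        assert by_source.get("ct", 0) == ct.number_of_edges()


class TestExports:
    def test_sif_round_trip_edge_count(self, tmp_path):
        g = nx.Graph([("A", "B", {"source": "ppi"}), ("B", "C", {"source": "ct"})])
        g.add_node("D")
        path = tmp_path / "net.sif"
        write_sif(g, path)
        lines = path.read_text().strip().split("\n")
        assert len(lines) == 3  # 2 edges + 1 isolate
        assert "A\tppi\tB" in lines
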