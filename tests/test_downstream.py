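import numpy as np
import pandas as pd
import pytest

from netpharm.downstream import (
    DockingRatioMatrix,
    TripartiteNetwork,
    build_compound_key_target_network,
    build_ctp_network,
    docking_ratios,
    ratio_heatmap,
)
from netpharm.model import CompoundTargetMap, DockingTable, Role
from tests.conftest import make_network


class TestTripartiteNetwork:
    def test_allowed_edges(self):
        tri = TripartiteNetwork()
        tri.add_node("C1", "compound")
        tri.add_node("T1", "target")
        tri.add_node("T2", "target")
        tri.add_node("P1", "pathway")
        tri.add_edge("C1", "T1")
        tri.add_edge("T1", "T2")
        tri.add_edge("T1", "P1")
        tri.validate()
        assert tri.edges_of_type("compound-target") == [("C1", "T1")]

    @pytest.mark.parametrize(
        "u,v", [("C1", "P1"), ("C1", "C2"), ("P1", "P2")]
    )
    def test_forbidden_edges(self, u, v):
        tri = TripartiteNetwork()
        tri.add_node("C1", "compound")
        tri.add_node("C2", "compound")
        tri.add_node("P1", "pathway")
        tri.add_node("P2", "pathway")
        with pytest.raises(ValueError):
            tri.add_edge(u, v)


@pytest.fixture
def toy_hub():
    return make_network(
        [("G3", "G5", 0.8), ("G3", "G4", 0.6), ("G4", "G5", 0.5)],
        roles={"G3": Role.COMMON, "G4": Role.COMMON, "G5": Role.DISEASE_TARGET},
    )


class TestCompoundKeyTargetNetwork:
    def test_single_pair(self):
        hub = make_network([("G1", "G2", 0.9)], roles={"G1": Role.COMMON, "G2": Role.NEIGHBOR})
        ct = CompoundTargetMap()
        ct.add("C1", "G1")
        net = build_compound_key_target_network(ct, {"G1"}, hub)
        assert net.nodes == {"C1", "G1"}
        assert net.n_edges() == 1

    def test_toy_rule(self, toy_hub):
        ct = CompoundTargetMap()
        ct.add("C1", "G3")
        ct.add("C1", "G9")
        ct.add("C2", "G5")
        net = build_compound_key_target_network(ct, {"G3"}, toy_hub)
        # G5 is not key: C2 has no hit and is excluded
        assert net.nodes == {"C1", "G3"}
        assert "C2" not in net.nodes

    def test_keep_neighbors_retains_hub_targets(self, toy_hub):
        ct = CompoundTargetMap()
        ct.add("C1", "G3")
        ct.add("C2", "G5")
        net = build_compound_key_target_network(ct, {"G3"}, toy_hub, keep_neighbors=True)
        assert {"G3", "G4", "G5", "C1", "C2"} == net.nodes
        assert ("G3", "G5") in net.edge_set()

    def test_compound_without_hits_logged(self, toy_hub, caplog):
        ct = CompoundTargetMap()
        ct.add("C1", "G3")
        ct.add("C2", "G9")
        with caplog.at_level("INFO"):
            net = build_compound_key_target_network(ct, {"G3"}, toy_hub)
        assert "no key-target hits" in caplog.text
        assert "C2" not in net.nodes

    def test_degree_size_attribute(self, toy_hub):
        ct = CompoundTargetMap()
        ct.add("C1", "G3")
        ct.add("C1", "G4")
        net = build_compound_key_target_network(ct, {"G3", "G4"}, toy_hub)
        for node in net.nodes:
            assert net.graph.nodes[node]["size"] == net.graph.degree[node]

    def test_empty_key_errors(self, toy_hub):
        with pytest.raises(ValueError):
            build_compound_key_target_network(CompoundTargetMap(), set(), toy_hub)


class TestCtpNetwork:
    def test_membership_counts(self):
        ct = CompoundTargetMap()
        ct.add("C1", "T1")
        ct.add("C2", "T2")
        key = {"T1", "T2", "T3"}
        membership = {"P1": {"T1", "T2"}, "P2": {"T3", "T9"}}
        tri = build_ctp_network(ct, key, membership, ["P1", "P2"])
        assert tri.nodes_of_type("target") == {"T1", "T2", "T3"}
        assert tri.nodes_of_type("pathway") == {"P1", "P2"}
        assert tri.nodes_of_type("compound") == {"C1", "C2"}
        tri.validate()

    def test_published_pathway_membership_counts(self):
        # target membership lists as printed for the two disease pathways
        tnf = {
            "RELA", "EDN1", "IL6", "MAPK1", "MAPK3", "CCL2", "CCL5", "JUN",
            "CASP3", "IL1B", "MMP9", "PTGS2", "TNF",
        }
        hif1 = {
            "BCL2", "EGFR", "EGF", "HMOX1", "IFNG", "NOS2", "NOS3", "TLR4",
            "VEGFA", "RELA", "EDN1", "IL6", "MAPK1", "MAPK3",
        }
        key = tnf | hif1 | {"TP53", "ALB"}  # key set is a superset
        ct = CompoundTargetMap()
        for g in sorted(tnf | hif1):
            ct.add("C1", g)
        membership = {
            "TNF signaling pathway": tnf,
            "HIF-1 signaling pathway": hif1,
        }
        tri = build_ctp_network(
            ct, key, membership, ["TNF signaling pathway", "HIF-1 signaling pathway"]
        )
        assert len(tri.nodes_of_type("target")) == len(tnf | hif1)
        assert len([
            e for e in tri.edges_of_type("target-pathway")
            if "TNF signaling pathway" in e
        ]) == 13
        assert len([
            e for e in tri.edges_of_type("target-pathway")
            if "HIF-1 signaling pathway" in e
        ]) == 14

    def test_empty_selection_errors(self):
        with pytest.raises(ValueError):
            build_ctp_network(CompoundTargetMap(), {"T1"}, {"P1": {"T1"}}, [])

    def test_unknown_pathway_errors(self):
        with pytest.raises(ValueError, match="membership"):
            build_ctp_network(CompoundTargetMap(), {"T1"}, {"P1": {"T1"}}, ["P2"])

    def test_no_surviving_target_errors(self):
        ct = CompoundTargetMap()
        ct.add("C1", "T1")
        with pytest.raises(ValueError, match="no key target"):
            build_ctp_network(ct, {"T1"}, {"P1": {"T9"}}, ["P1"])

    def test_compound_without_edge_dropped(self):
        ct = CompoundTargetMap()
        ct.add("C1", "T1")
        ct.add("C2", "T9")
        tri = build_ctp_network(ct, {"T1"}, {"P1": {"T1"}}, ["P1"])
        assert tri.nodes_of_type("compound") == {"C1"}


def simple_table(**scores):
    records = {("LIG", "T1"): 100.0}
    records.update({(m, "T1"): s for m, s in scores.items()})
    return DockingTable(records, {"T1": "LIG"})


class TestDockingRatios:
    def test_basic_arithmetic(self):
        matrix = docking_ratios(simple_table(M1=110.0))
        assert matrix.ratios.loc["M1", "T1"] == pytest.approx(1.1)
        assert matrix.categories.loc["M1", "T1"] == "strong"

    def test_equal_scores_ratio_one(self):
        matrix = docking_ratios(simple_table(M1=100.0))
        assert matrix.ratios.loc["M1", "T1"] == pytest.approx(1.0)
        assert matrix.categories.loc["M1", "T1"] == "strong"  # strong >= 1.0

    def test_missing_cell(self):
        matrix = docking_ratios(simple_table(M1=None))
        assert np.isnan(matrix.ratios.loc["M1", "T1"])
        assert matrix.categories.loc["M1", "T1"] == "none"

    @pytest.mark.parametrize(
        "score,category",
        [(79.999, "weak"), (80.0, "moderate"), (99.999, "moderate"), (100.0, "strong")],
    )
    def test_category_boundaries_half_open(self, score, category):
        matrix = docking_ratios(simple_table(M1=score))
        assert matrix.categories.loc["M1", "T1"] == category

    def test_custom_cutoffs(self):
        matrix = docking_ratios(simple_table(M1=95.0), cutoffs=(0.5, 0.9))
        assert matrix.categories.loc["M1", "T1"] == "strong"

    def test_scaling_invariance(self):
        t1 = DockingTable(
            {("LIG", "T1"): 100.0, ("M1", "T1"): 73.0}, {"T1": "LIG"}
        )
        t2 = DockingTable(
            {("LIG", "T1"): 300.0, ("M1", "T1"): 219.0}, {"T1": "LIG"}
        )
        r1 = docking_ratios(t1).ratios
        r2 = docking_ratios(t2).ratios
        assert r1.loc["M1", "T1"] == pytest.approx(r2.loc["M1", "T1"])

    def test_nonpositive_ligand_errors(self):
        table = DockingTable(
            {("LIG", "T1"): 0.0, ("M1", "T1"): 50.0}, {"T1": "LIG"}
        )
        with pytest.raises(ValueError, match="ligand"):
            docking_ratios(table)


class TestRatioHeatmap:
    def test_single_cell_and_csv_twin(self, tmp_path):
        matrix = docking_ratios(simple_table(M1=110.0))
        img = tmp_path / "heat.png"
        csv = tmp_path / "heat.csv"
        ratio_heatmap(matrix, img, out_csv=csv)
        assert img.exists()
        back = pd.read_csv(csv, index_col="compound")
        assert back.loc["M1", "T1"] == pytest.approx(1.1)

    def test_all_missing_column_flagged(self, tmp_path, caplog):
        records = {
            ("LIG", "T1"): 100.0, ("LIG2", "T2"): 50.0,
            ("M1", "T1"): 90.0, ("M1", "T2"): None,
        }
        table = DockingTable(records, {"T1": "LIG", "T2": "LIG2"})
        matrix = docking_ratios(table)
        with caplog.at_level("INFO"):
            ratio_heatmap(matrix, tmp_path / "h.png")
        assert "no docking result" in caplog.text

    def test_csv_round_trip_matches_matrix(self, tmp_path):
        from netpharm.synthetic import SyntheticConfig, generate_dataset

        ds = generate_dataset(SyntheticConfig(seed=5))
        matrix = docking_ratios(ds.docking)
        csv = tmp_path / "m.csv"
        ratio_heatmap(matrix, tmp_path / "m.png", out_csv=csv)
        back = pd.read_csv(csv, index_col="compound")
        pd.testing.assert_frame_equal(back, matrix.ratios, check_names=False)
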