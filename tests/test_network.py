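"""Network assembly, scaling, ancestor insertion and graphml round trips."""

import itertools
import math

import networkx as nx
import numpy as np
import pytest
from lxml import etree

from pathnet.datasets import Dataset, GeneRecord
from pathnet.enrichment import (
    ContingencyCounts,
    EnrichmentResult,
    LevelCutoffs,
    rank_and_flag,
    standard_enrichment,
)
from pathnet.errors import ParameterError
from pathnet.network import (
    NetworkNode,
    NetworkOptions,
    PieSlice,
    SCPNetwork,
    SCPSelectionGroup,
    add_gene_children,
    apply_scp_selection,
    build_network,
    insert_ancestors,
    network_filename,
    read_graphml_summary,
    scale_labels,
    scale_nodes,
    write_graphml,
)
from pathnet.ontology import InteractionNetwork
from tests.conftest import make_ontology, random_dag_ontology

CHAIN = make_ontology([("A", "B"), ("B", "C")])


def sig_result(term, p, dataset="d1", overlap=(), level=None):
    return EnrichmentResult(
        dataset_name=dataset, term_id=term,
        counts=ContingencyCounts(1, 10, 10, 100), p_value=p,
        minus_log10_p=-math.log10(p), significant=True, level=level,
        overlap_genes=set(overlap),
    )


def simple_datasets(names=("d1", "d2")):
    return [
        Dataset(name=n, color=c, order_index=i,
                records=[GeneRecord(symbol="G1")])
        for i, (n, c) in enumerate(zip(names, ["#ff0000", "#00ff00"]))
    ]


class TestInsertAncestors:
    def test_intermediate_fills_chain_gap(self):
        added, edges = insert_ancestors({"A", "C"}, CHAIN, "intermediate_only")
        assert added == {"B"}
        assert set(edges) == {("A", "B"), ("B", "C")}

    def test_disjoint_branches_root_not_intermediate(self):
        ont = make_ontology([("R", "A"), ("R", "B"), ("A", "X"), ("B", "Y")])
        added, edges = insert_ancestors({"X", "Y"}, ont, "intermediate_only")
        # R is ancestor of both but on no predicted-to-predicted path
        assert added == set()
        assert edges == []

    def test_all_ancestors_closure(self):
        added, _ = insert_ancestors({"C"}, CHAIN, "all_ancestors")
        assert added == {"A", "B"}

    def test_matches_bruteforce_path_oracle(self):
        rng = np.random.default_rng(17)
        for _ in range(20):
            ont = random_dag_ontology(rng, 25, edge_prob=0.12)
            g = ont.to_networkx()
            terms = sorted(ont.terms)
            predicted = {
                t for t in terms if rng.random() < 0.25
            } or {terms[0]}
            added, _ = insert_ancestors(predicted, ont, "intermediate_only")
            expected = set()
            for a, b in itertools.permutations(predicted, 2):
                for path in nx.all_simple_paths(g, a, b):
                    expected |= set(path[1:-1])
            assert added == expected - predicted


class TestBuildNetwork:
    def test_parent_child_pair_one_edge(self):
        results = {"d1": [sig_result("A", 1e-3), sig_result("B", 1e-4)]}
        net = build_network(results, simple_datasets(("d1",)),
                            make_ontology([("A", "B")]))
        assert set(net.nodes) == {"A", "B"}
        assert [(e.source_id, e.target_id, e.kind) for e in net.edges] == [
            ("A", "B", "hierarchical")
        ]

    def test_shared_prediction_gets_two_slices(self):
        results = {
            "d1": [sig_result("X", 1e-3, dataset="d1")],
            "d2": [sig_result("X", 1e-5, dataset="d2")],
        }
        ont = make_ontology([("X", "Y")])
        net = build_network(results, simple_datasets(), ont)
        assert len(net.nodes["X"].slices) == 2
        # slice order follows dataset order_index
        assert [s.dataset_name for s in net.nodes["X"].slices] == ["d1", "d2"]

    def test_non_significant_results_excluded(self):
        r = sig_result("A", 1e-3)
        r.significant = False
        net = build_network({"d1": [r]}, simple_datasets(("d1",)), CHAIN)
        assert net.nodes == {}

    def test_ancestor_modes_differ_on_fixture_dag(self):
        # A -> B -> D and root R above A; C a sibling branch
        ont = make_ontology([("R", "A"), ("A", "B"), ("B", "D"), ("R", "C")])
        results = {"d1": [sig_result("A", 1e-3), sig_result("D", 1e-3)]}
        inter = build_network(
            results, simple_datasets(("d1",)), ont,
            options=NetworkOptions(ancestor_mode="intermediate_only"),
        )
        assert set(inter.nodes) == {"A", "B", "D"}
        assert inter.nodes["B"].is_filler
        full = build_network(
            results, simple_datasets(("d1",)), ont,
            options=NetworkOptions(ancestor_mode="all_ancestors"),
        )
        assert set(full.nodes) == {"R", "A", "B", "D"}

    def test_functional_edges_from_top_interactions(self):
        ont = make_ontology([("R", "A"), ("R", "B"), ("R", "C")])
        results = {"d1": [sig_result("A", 1e-3), sig_result("B", 1e-3),
                          sig_result("C", 1e-3)]}
        interactions = InteractionNetwork(
            [("A", "B", 0.9), ("A", "C", 0.1), ("B", "C", 0.2)]
        )
        net = build_network(
            results, simple_datasets(("d1",)), ont, interactions,
            NetworkOptions(hierarchical_edges=False, functional_edges=True,
                           top_interaction_percent=33.0),
        )
        kinds = [(e.source_id, e.target_id) for e in net.edges
                 if e.kind == "functional"]
        assert kinds == [("A", "B")]

    def test_empty_results_give_empty_network(self):
        net = build_network({}, [], CHAIN)
        assert net.nodes == {} and net.edges == []


class TestScaling:
    def pie(self, values, colors=None):
        node = NetworkNode(node_id="X", kind="scp")
        for i, v in enumerate(values):
            node.slices.append(PieSlice(
                dataset_name=f"d{i}",
                color=(colors or ["#111111"] * len(values))[i], value=v,
            ))
        net = SCPNetwork()
        net.add_node(node)
        return net, node

    def test_significance_angle_fractions(self):
        net, node = self.pie([3.0, 1.0])
        scale_nodes(net, NetworkOptions())
        assert [s.angle_fraction for s in node.slices] == [0.75, 0.25]
        assert sum(s.angle_fraction for s in node.slices) == pytest.approx(1.0)

    def test_area_proportional_to_total_value(self):
        net = SCPNetwork()
        for tid, vals in [("X", [3.0, 1.0]), ("Y", [1.0])]:
            node = NetworkNode(node_id=tid, kind="scp")
            node.slices = [PieSlice(f"d{i}", "#222222", v)
                           for i, v in enumerate(vals)]
            net.add_node(node)
        scale_nodes(net, NetworkOptions())
        assert net.nodes["X"].area / net.nodes["Y"].area == pytest.approx(
            4.0, abs=1e-9
        )
        ref = NetworkOptions().reference_diameter
        assert net.nodes["X"].diameter == pytest.approx(ref)

    def test_uniform_mode_equal_areas_and_angles(self):
        net = SCPNetwork()
        for tid, vals in [("X", [3.0, 1.0, 2.0]), ("Y", [9.0])]:
            node = NetworkNode(node_id=tid, kind="scp")
            node.slices = [PieSlice(f"d{i}", "#222222", v)
                           for i, v in enumerate(vals)]
            net.add_node(node)
        scale_nodes(net, NetworkOptions(scaling_mode="uniform"))
        assert net.nodes["X"].area == net.nodes["Y"].area
        assert [s.angle_fraction for s in net.nodes["X"].slices] == (
            pytest.approx([1 / 3] * 3)
        )

    def test_dataset_and_color_count_modes(self):
        net, node = self.pie([5.0, 1.0, 1.0],
                             colors=["#a", "#a", "#b"])
        scale_nodes(net, NetworkOptions(scaling_mode="dataset_count"))
        a3 = node.area
        scale_nodes(net, NetworkOptions(scaling_mode="color_count"))
        a2 = node.area
        ref_area = math.pi * 40 ** 2
        assert a3 == pytest.approx(ref_area)  # 3 datasets, max in context
        assert a2 == pytest.approx(ref_area)  # 2 colors, max in context

    def test_shared_context_equal_values_equal_areas(self):
        nets = []
        for _ in range(2):
            net, _ = self.pie([2.0])
            nets.append(net)
        for net in nets:
            scale_nodes(net, NetworkOptions(scaling_context="shared"),
                        context_max=10.0)
        assert nets[0].nodes["X"].area == nets[1].nodes["X"].area

    def test_label_interpolation_endpoints_and_midpoint(self):
        net = SCPNetwork()
        for tid, area in [("A", 10.0), ("B", 30.0), ("C", 20.0)]:
            node = NetworkNode(node_id=tid, kind="scp", area=area)
            net.add_node(node)
        scale_labels(net, 8, 16)
        sizes = {n.node_id: n.label_size for n in net.nodes.values()}
        assert sizes == {"A": 8.0, "B": 16.0, "C": 12.0}

    def test_equal_areas_all_min_label(self):
        net = SCPNetwork()
        for tid in "AB":
            net.add_node(NetworkNode(node_id=tid, kind="scp", area=5.0))
        scale_labels(net, 8, 16)
        assert {n.label_size for n in net.nodes.values()} == {8.0}

    def test_inverted_label_range_rejected(self):
        with pytest.raises(ParameterError):
            scale_labels(SCPNetwork(), 16, 8)
        with pytest.raises(ParameterError):
            NetworkOptions(min_label=16, max_label=8)


class TestGeneChildren:
    def test_shared_gene_one_node_two_edges(self):
        net = SCPNetwork()
        for tid in ("X", "Y"):
            net.add_node(NetworkNode(node_id=tid, kind="scp"))
        results = {"d1": [
            sig_result("X", 1e-3, overlap={"G1"}),
            sig_result("Y", 1e-3, overlap={"G1", "G2"}),
        ]}
        add_gene_children(net, results, simple_datasets(("d1",)))
        gene_nodes = [n for n in net.nodes.values() if n.kind == "gene"]
        assert {n.label for n in gene_nodes} == {"G1", "G2"}
        g1_edges = [e for e in net.edges if e.target_id == "gene::G1"]
        assert len(g1_edges) == 2
        assert all(e.kind == "gene_membership" for e in net.edges)

    def test_no_overlap_no_gene_nodes(self):
        net = SCPNetwork()
        net.add_node(NetworkNode(node_id="X", kind="scp"))
        add_gene_children(net, {"d1": [sig_result("X", 1e-3)]},
                          simple_datasets(("d1",)))
        assert all(n.kind == "scp" for n in net.nodes.values())

    def test_membership_edge_count_matches_oracle(self):
        rng = np.random.default_rng(23)
        net = SCPNetwork()
        results = {"d1": []}
        n_memberships = 0
        seen = set()
        genes = [f"G{i}" for i in range(10)]
        for tid in ("X", "Y", "Z"):
            net.add_node(NetworkNode(node_id=tid, kind="scp"))
            overlap = {g for g in genes if rng.random() < 0.5}
            n_memberships += len(overlap)
            seen |= overlap
            results["d1"].append(sig_result(tid, 1e-3, overlap=overlap))
        add_gene_children(net, results, simple_datasets(("d1",)))
        gene_nodes = [n for n in net.nodes.values() if n.kind == "gene"]
        assert len(gene_nodes) == len(seen)
        assert len(net.edges) == n_memberships


class TestScpSelection:
    def test_override_includes_non_significant(self):
        r = sig_result("X", 0.9)
        r.significant = False
        out = apply_scp_selection(
            {"d1": [r]}, [SCPSelectionGroup("g", ["X"])],
            make_ontology([("X", "Y")]),
        )
        assert out["g"]["d1"][0].significant is True

    def test_branch_selection_includes_descendants(self):
        ont = make_ontology([("P", "A"), ("P", "B"), ("A", "C"), ("A", "D")])
        results = {"d1": [sig_result(t, 1e-3) for t in "PABCD"]}
        out = apply_scp_selection(
            results,
            [SCPSelectionGroup("g", ["A"], include_descendants=True)], ont,
        )
        assert {r.term_id for r in out["g"]["d1"]} == {"A", "C", "D"}

    def test_unknown_term_rejected(self):
        with pytest.raises(ParameterError, match="NOPE"):
            apply_scp_selection(
                {}, [SCPSelectionGroup("g", ["NOPE"])], CHAIN
            )


class TestGraphml:
    def test_empty_network_is_wellformed_xml(self, tmp_path):
        path = write_graphml(SCPNetwork(name="empty"), tmp_path / "e.graphml")
        root = etree.parse(str(path)).getroot()
        assert root.tag.endswith("graphml")
        assert read_graphml_summary(path).nodes == {}

    def test_round_trip_counts_areas_slices(self, tmp_path, fixture_ontology,
                                            fixture_datasets, fixture_network):
        ont, _ = fixture_ontology
        results = {
            ds.name: rank_and_flag(standard_enrichment(ds, ont),
                                   LevelCutoffs())
            for ds in fixture_datasets
        }
        net = build_network(results, fixture_datasets, ont, fixture_network,
                            NetworkOptions(box_levels=True))
        path = write_graphml(net, tmp_path / "n.graphml")
        back = read_graphml_summary(path)
        assert set(back.nodes) == set(net.nodes)
        assert len(back.edges) == len(net.edges)
        for nid, node in net.nodes.items():
            assert back.nodes[nid].area == pytest.approx(node.area, abs=1e-9)
            got = [s.angle_fraction for s in back.nodes[nid].slices]
            want = [s.angle_fraction for s in node.slices]
            assert got == pytest.approx(want, abs=1e-9)

    def test_multislice_nodes_are_svg_pies(self, tmp_path):
        results = {
            "d1": [sig_result("X", 1e-3, dataset="d1")],
            "d2": [sig_result("X", 1e-5, dataset="d2")],
        }
        net = build_network(results, simple_datasets(),
                            make_ontology([("X", "Y")]))
        path = write_graphml(net, tmp_path / "p.graphml")
        text = path.read_text()
        assert "SVGNode" in text and "<svg" in text
        assert text.count("<path") == 2  # two pie slices

    def test_filename_pattern(self):
        assert network_filename("Go_bp_human", "prednisolone - Down",
                                "standard") == (
            "Go_bp_human_prednisolone - Down_standard.graphml"
        )
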