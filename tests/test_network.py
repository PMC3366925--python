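"""Median-joining networks: construction, medians, MST properties, dating."""

import networkx as nx
import numpy as np
import pytest

import mtphylo as m
from mtphylo.network import (
    _distance_matrix,
    build_character_matrix,
    median_joining,
    network_node_ages,
)

from conftest import random_binary_matrix


def hap(tokens, sid="s", region=""):
    return m.Haplotype(sid, m.parse_variants(tokens) if tokens else frozenset(),
                       region=region)


class TestCharacterMatrix:
    def test_identical_rows_merge_with_multiplicity(self):
        haps = [hap("16360", "a"), hap("16360", "b"), hap("16360 89", "c")]
        mat = build_character_matrix(haps)
        assert sorted(mat.multiplicity.tolist()) == [1, 2]
        assert len(mat.taxa) == 2

    def test_insertions_excluded(self):
        haps = [hap("16360 309.1C", "a"), hap("", "b")]
        mat = build_character_matrix(haps)
        assert "309.1C" not in mat.characters
        assert "16360" in mat.characters

    def test_invariant_columns_dropped_unless_reference(self):
        haps = [hap("16360", "a"), hap("16360 89", "b"), hap("16360 89 146", "c")]
        mat = build_character_matrix(haps)
        assert mat.characters == ["146", "89"]
        mat_ref = build_character_matrix(haps, include_reference=True)
        assert "16360" in mat_ref.characters

    def test_empty_input_error(self):
        with pytest.raises(ValueError):
            build_character_matrix([])

    def test_region_composition_recorded(self):
        haps = [hap("16360", "a", "X"), hap("16360", "b", "Y"),
                hap("16360", "c", "Y")]
        mat = build_character_matrix(haps)
        assert mat.regions[0] == {"X": 1, "Y": 2}


class TestMedianJoining:
    def test_chain_has_no_medians(self):
        haps = [hap("", "A"), hap("100", "B"), hap("100 200", "C")]
        net = median_joining(build_character_matrix(haps))
        assert sorted(net.graph.edges) == [("A", "B"), ("B", "C")]
        assert net.medians == []

    def test_triplet_produces_single_median(self):
        haps = [hap("", "A"), hap("100 200", "B"), hap("100 300", "C")]
        net = median_joining(build_character_matrix(haps))
        assert len(net.medians) == 1
        mv = net.medians[0]
        assert sorted(net.graph.edges) == sorted(
            [("A", mv), ("B", mv), ("C", mv)])
        # the median is the majority profile {m1}
        chars = net.characters
        prof = dict(zip(chars, net.graph.nodes[mv]["profile"]))
        assert prof == {"100": 1, "200": 0, "300": 0}

    def test_single_taxon(self):
        net = median_joining(build_character_matrix([hap("", "A")]))
        assert list(net.graph.nodes) == ["A"]
        assert net.graph.number_of_edges() == 0

    def test_network_contains_observed_msts(self, rng):
        for _ in range(40):
            mat = random_binary_matrix(rng)
            net = median_joining(mat)
            D = _distance_matrix(mat.matrix.astype(float),
                                 mat.weights.astype(float))
            n = len(mat.taxa)
            sp = dict(nx.all_pairs_dijkstra_path_length(net.graph, weight="weight"))
            for i in range(n):
                for j in range(i + 1, n):
                    d = D[i, j]
                    below = nx.Graph(
                        [(a, b) for a in range(n) for b in range(a + 1, n)
                         if D[a, b] < d])
                    below.add_nodes_from(range(n))
                    if not nx.has_path(below, i, j):
                        # an edge of some MST: realized at exact length
                        assert sp[mat.taxa[i]][mat.taxa[j]] == d

    def test_epsilon_networks_nested(self, rng):
        for _ in range(20):
            mat = random_binary_matrix(rng)
            n0 = median_joining(mat, epsilon=0)
            n2 = median_joining(mat, epsilon=2)
            assert set(n0.graph.nodes) <= set(n2.graph.nodes)

    def test_medians_do_not_lengthen_mst(self, rng):
        for _ in range(20):
            mat = random_binary_matrix(rng)
            net = median_joining(mat)
            D = _distance_matrix(mat.matrix.astype(float),
                                 mat.weights.astype(float))
            sp = dict(nx.all_pairs_dijkstra_path_length(net.graph, weight="weight"))
            n = len(mat.taxa)
            gH, gN = nx.Graph(), nx.Graph()
            for i in range(n):
                for j in range(i + 1, n):
                    gH.add_edge(i, j, weight=D[i, j])
                    gN.add_edge(i, j, weight=sp[mat.taxa[i]][mat.taxa[j]])
            wH = sum(d["weight"] for *_, d in
                     nx.minimum_spanning_tree(gH).edges(data=True))
            wN = sum(d["weight"] for *_, d in
                     nx.minimum_spanning_tree(gN).edges(data=True))
            assert wN <= wH

    def test_non_binary_matrix_rejected(self):
        from mtphylo.network import CharacterMatrix

        with pytest.raises(ValueError, match="binary"):
            CharacterMatrix(
                taxa=["a"], matrix=np.array([[2]]), characters=["c"],
                weights=np.ones(1, dtype=int), multiplicity=np.ones(1, dtype=int),
                members=[["a"]], regions=[{}])


class TestNetworkAges:
    def _star(self, dists):
        haps = [hap("", "root-sample")]
        pool = iter(range(1000, 9000, 10))
        for i, d in enumerate(dists):
            toks = " ".join(str(next(pool)) for _ in range(d))
            haps.append(m.Haplotype(
                f"t{i}", m.parse_variants(toks),
                covered_range=m.CircularInterval(1, 16569)))
        haps[0] = m.Haplotype("t-root", frozenset(),
                              covered_range=m.CircularInterval(1, 16569))
        return haps

    def test_identical_taxa_age_zero(self):
        haps = [m.Haplotype(f"s{i}", m.parse_variants("16360")) for i in range(4)]
        mat = build_character_matrix(haps, ancestor=haps[0])
        net = median_joining(mat)
        est = network_node_ages(net, mat.taxa[0], m.ClockConfig(),
                                scale="whole_molecule")
        assert est.rho == 0.0 and est.age_years == 0.0

    def test_star_mean_distance(self):
        haps = self._star([1, 2, 3, 2])
        anc = haps[0]
        mat = build_character_matrix(haps[1:], ancestor=anc)
        net = median_joining(mat)
        root = next(n for n, d in net.graph.nodes(data=True)
                    if sum(d["profile"]) == 0)
        est = network_node_ages(net, root, m.ClockConfig(),
                                scale="whole_molecule")
        assert est.rho == pytest.approx(2.0)
        assert est.age_years == pytest.approx(2.0 * 3624)

    def test_rho_one_whole_molecule_clock(self):
        haps = [m.Haplotype("a", m.parse_variants("5000"),
                            m.CircularInterval(1, 16569))]
        mat = build_character_matrix(
            haps, ancestor=m.Haplotype("anc", frozenset(),
                                       m.CircularInterval(1, 16569)))
        net = median_joining(mat)
        root = next(n for n, d in net.graph.nodes(data=True)
                    if sum(d["profile"]) == 0)
        est = network_node_ages(net, root, m.ClockConfig(), "whole_molecule")
        assert est.rho == 1.0
        assert est.age_years == pytest.approx(3624.0)

    def test_missing_root_error(self):
        net = median_joining(build_character_matrix([hap("", "A"), hap("100", "B")]))
        with pytest.raises(ValueError, match="root"):
            network_node_ages(net, "nope", m.ClockConfig(), "whole_molecule")

    def test_rho_matches_tree_route(self, rng):
        # cross-module consistency: network rho on a star equals tree rho
        dists = [int(rng.integers(0, 4)) for _ in range(6)]
        haps = self._star(dists)
        mat = build_character_matrix(haps[1:], ancestor=haps[0])
        net = median_joining(mat)
        root = next(n for n, d in net.graph.nodes(data=True)
                    if sum(d["profile"]) == 0)
        est_net = network_node_ages(net, root, m.ClockConfig(), "whole_molecule")
        children = [m.TreeNode(label=f"t{i}", length=d)
                    for i, d in enumerate(dists)]
        est_tree = m.rho_sigma(m.GenealogyTree(m.TreeNode(children=children)))
        assert est_net.rho == pytest.approx(est_tree.rho)


def test_exports_round_trip(tmp_path):
    haps = [hap("", "A"), hap("100 200", "B"), hap("100 300", "C")]
    net = median_joining(build_character_matrix(haps))
    gml = tmp_path / "n.gml"
    dot = tmp_path / "n.dot"
    net.write_gml(gml)
    net.write_dot(dot)
    back = nx.read_gml(str(gml))
    assert set(back.nodes) == set(net.graph.nodes)
    assert "graph hapnetwork" in dot.read_text()
    table = net.node_table()
    assert set(table.columns) == {"id", "is_median", "multiplicity", "regions"}
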