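"""rho/sigma estimation, clock conversion, HKY85+Gamma likelihood fit."""

import itertools
import math

import numpy as np
import pytest

import mtphylo as m
from mtphylo.dating import (
    GenealogyTree,
    HKYGammaModel,
    MLModelConfig,
    TreeNode,
    discrete_gamma_rates,
    hky_eigensystem,
    ml_age,
)
from mtphylo.variants import SiteFilter

from conftest import enumerate_rooted_binary_topologies

NO_FILTER = SiteFilter(excluded_positions=frozenset(), cstretch_ranges=())


def brute_rho_sigma(tree):
    """Independent oracle: explicit enumeration of leaves and edges."""
    leaves = []

    def collect(node, depth, path):
        if node.is_leaf:
            leaves.append((node, depth, list(path)))
        for c in node.children:
            collect(c, depth + c.length, path + [c])

    collect(tree.root, 0.0, [])
    N = sum(l.multiplicity for l, _, _ in leaves)
    rho = sum(l.multiplicity * d for l, d, _ in leaves) / N
    var = 0.0
    edges = set()
    for l, _, path in leaves:
        edges.update(id(e) for e in path)
    for node in tree.edges():
        n_below = sum(l.multiplicity for l, _, p in leaves
                      if id(node) in {id(x) for x in p})
        var += node.length * (n_below / N) ** 2
    return rho, math.sqrt(var)


def tuples_to_tree(shape, lengths):
    """Build a GenealogyTree from a nested-tuple topology with an edge
    length iterator."""

    def build(node):
        if isinstance(node, str):
            return TreeNode(label=node, length=next(lengths))
        left, right = node
        return TreeNode(length=next(lengths),
                        children=[build(left), build(right)])

    root = build(shape)
    root.length = 0.0
    return GenealogyTree(root)


class TestRhoSigma:
    def test_star_all_zero(self):
        t = GenealogyTree(TreeNode(children=[
            TreeNode(label=f"l{i}", length=0) for i in range(4)]))
        est = m.rho_sigma(t)
        assert est.rho == 0.0 and est.sigma == 0.0

    def test_star_1232(self):
        t = GenealogyTree.from_newick("(a:1,b:2,c:3,d:2)r;")
        est = m.rho_sigma(t)
        assert est.rho == pytest.approx(2.0)
        assert est.sigma ** 2 == pytest.approx(0.5)

    def test_caterpillar(self):
        t = GenealogyTree.from_newick("((a:1,b:1):1,c:2)r;")
        est = m.rho_sigma(t)
        assert est.rho == pytest.approx(2.0)
        assert est.sigma ** 2 == pytest.approx(8.0 / 9.0)

    def test_multiplicities_weight_leaves(self):
        t = GenealogyTree.from_newick("(a:1,b:3)r;")
        t3 = GenealogyTree.from_newick("(a:1,b:3)r;",
                                       multiplicities={"a": 3})
        assert m.rho_sigma(t).rho == 2.0
        assert m.rho_sigma(t3).rho == pytest.approx((3 * 1 + 3) / 4)

    def test_exhaustive_oracle_small_trees(self, rng):
        labels = ["a", "b", "c", "d", "e"]
        for n in range(2, 6):
            for shape in enumerate_rooted_binary_topologies(labels[:n]):
                lengths = iter(int(x) for x in rng.integers(0, 5, size=2 * n))
                tree = tuples_to_tree(shape, lengths)
                est = m.rho_sigma(tree)
                rho_b, sigma_b = brute_rho_sigma(tree)
                assert est.rho == pytest.approx(rho_b)
                assert est.sigma == pytest.approx(sigma_b)


class TestClock:
    def test_rho_one_is_3624_years(self):
        est = m.to_years(m.AgeEstimate(rho=1.0, sigma=0.5, method="rho"),
                         m.ClockConfig(), scale="whole_molecule")
        assert est.age_years == pytest.approx(3624.0)
        assert est.age_se_years == pytest.approx(1812.0)

    def test_zero_rho_zero_years(self):
        est = m.to_years(m.AgeEstimate(rho=0.0, sigma=0.0, method="rho"),
                         m.ClockConfig(), scale="whole_molecule")
        assert est.age_years == 0.0

    def test_missing_control_region_rate_errors(self):
        with pytest.raises(ValueError, match="control-region"):
            m.ClockConfig().rate_for("control_region")
        clock = m.ClockConfig(control_region_rate=9058.0)
        assert clock.rate_for("control_region") == 9058.0

    def test_newick_round_trip(self):
        t = GenealogyTree.from_newick("((a:1,b:2):1,c:3)r;")
        t2 = GenealogyTree.from_newick(t.to_newick())
        assert m.rho_sigma(t2).rho == m.rho_sigma(t).rho


class TestHKYMachinery:
    def test_transition_matrix_is_stochastic(self):
        for kappa in (0.5, 1.0, 20.0):
            V, lam, Vinv = hky_eigensystem(
                np.array([0.31, 0.31, 0.13, 0.25]), kappa)
            for t in (0.0, 0.01, 0.5, 3.0):
                P = V @ (np.exp(lam * t)[:, None] * Vinv)
                assert np.allclose(P.sum(axis=1), 1.0)
                assert (P >= -1e-12).all()

    def test_gamma_categories_mean_one(self):
        for alpha in (0.2, 0.5, 1.0, 5.0):
            r = discrete_gamma_rates(alpha, 32)
            assert r.shape == (32,)
            assert np.isclose(r.mean(), 1.0)
            assert (np.diff(r) > 0).all()


class TestMLFit:
    def test_identical_sequences_zero_lengths(self):
        seqs = {"a": "ACGT" * 50, "b": "ACGT" * 50}
        topo = GenealogyTree.from_newick("(a:0.1,b:0.1)r;")
        cfg = MLModelConfig(n_rate_categories=1, partitions=(),
                            excluded=NO_FILTER, fix_kappa=2.0, fix_alpha=1.0)
        fit = HKYGammaModel(seqs, topo, cfg).fit()
        assert sum(e.length for e in fit.tree.edges()) < 1e-6

    def test_jukes_cantor_closed_form(self, rng):
        n = 2000
        s1 = "".join(rng.choice(list("ACGT"), n))
        s2 = list(s1)
        for i in rng.choice(n, size=200, replace=False):
            s2[i] = rng.choice([b for b in "ACGT" if b != s1[i]])
        s2 = "".join(s2)
        p = sum(a != b for a, b in zip(s1, s2)) / n
        jc = -0.75 * math.log(1 - 4 * p / 3)
        cfg = MLModelConfig(n_rate_categories=1, partitions=(),
                            excluded=NO_FILTER, equal_base_frequencies=True,
                            fix_kappa=1.0, fix_alpha=1.0)
        topo = GenealogyTree.from_newick("(a:0.01,b:0.01)r;")
        fit = HKYGammaModel({"a": s1, "b": s2}, topo, cfg).fit()
        assert sum(e.length for e in fit.tree.edges()) == pytest.approx(
            jc, abs=1e-6)

    def test_pruning_matches_exhaustive_summation(self, rng):
        newick = "((a:0.1,b:0.05):0.07,(c:0.2,d:0.02):0.03)r;"
        topo = GenealogyTree.from_newick(newick)
        seqs = {l: "".join(rng.choice(list("ACGT"), 30)) for l in "abcd"}
        cfg = MLModelConfig(n_rate_categories=4, partitions=(),
                            excluded=NO_FILTER)
        model = HKYGammaModel(seqs, topo, cfg)
        bl = [e.length for e in model.tree.edges()]
        kappa, alpha = 3.0, 0.7
        ll = model.log_likelihood(bl, kappa, alpha)
        assert ll == pytest.approx(
            exhaustive_loglik(model, bl, kappa, alpha), abs=1e-10)

    def test_parameter_recovery_on_simulated_alignment(self):
        rng = np.random.default_rng(5)
        topo = GenealogyTree.from_newick(
            "((a:0.01,b:0.02):0.01,(c:0.015,d:0.005):0.02,"
            "(e:0.01,f:0.03):0.005)r;")
        aln = m.simulate_alignment(topo, rng, n_sites=8000, kappa=10.0,
                                   alpha=0.5, n_rate_categories=8)
        cfg = MLModelConfig(n_rate_categories=8, partitions=(),
                            excluded=NO_FILTER)
        fit = HKYGammaModel(aln, topo, cfg).fit()
        assert fit.converged
        assert fit.kappa == pytest.approx(10.0, rel=0.25)
        assert fit.alpha == pytest.approx(0.5, rel=0.35)
        total = sum(e.length for e in fit.tree.edges())
        assert total == pytest.approx(0.125, rel=0.15)

    def test_missing_leaf_sequence_error(self):
        topo = GenealogyTree.from_newick("(a:0.1,b:0.1)r;")
        with pytest.raises(ValueError, match="missing"):
            HKYGammaModel({"a": "ACGT"}, topo, MLModelConfig())


class TestMLAge:
    def test_zero_tree_zero_years(self):
        t = GenealogyTree.from_newick("(a:0,b:0)r;")
        assert ml_age(t, m.ClockConfig()).age_years == 0.0

    def test_age_arithmetic(self):
        # mean root-to-leaf 2.709e-4 subs/site over 16,569 sites
        t = GenealogyTree.from_newick("(a:0.0002709,b:0.0002709)r;")
        est = ml_age(t, m.ClockConfig())
        assert est.rho == pytest.approx(2.709e-4 * 16569, rel=1e-6)
        assert est.age_years == pytest.approx(2.709e-4 * 16569 * 3624, rel=1e-6)

    def test_linearity_in_branch_lengths(self):
        t = GenealogyTree.from_newick("((a:0.001,b:0.002):0.001,c:0.003)r;")
        a1 = ml_age(t, m.ClockConfig()).age_years
        a2 = ml_age(t.scaled(2.0), m.ClockConfig()).age_years
        assert a2 == pytest.approx(2 * a1)


def exhaustive_loglik(model, bl, kappa, alpha):
    """Oracle: sum the likelihood over every internal-state assignment."""
    part = model.partitions[0]
    k = model.config.n_rate_categories
    g = discrete_gamma_rates(alpha, k)
    V, lam, Vinv = hky_eigensystem(part["freqs"], kappa)

    edges = model._edges
    internal = [n for n in [model.tree.root] + edges if not n.is_leaf]
    leaf_row = {lab: i for i, lab in enumerate(model.leaf_order)}
    edge_len = {id(n): t for n, t in zip(edges, bl)}

    def P(t):
        return V @ (np.exp(lam * t)[:, None] * Vinv)

    total = 0.0
    for s in range(part["patterns"].shape[1]):
        col = part["patterns"][:, s]
        site = 0.0
        for gc in g:
            Pmat = {id(n): P(edge_len[id(n)] * gc) for n in edges}
            for assign in itertools.product(range(4), repeat=len(internal)):
                state = {id(n): a for n, a in zip(internal, assign)}
                prob = part["freqs"][state[id(model.tree.root)]]
                stack = [model.tree.root]
                while stack:
                    node = stack.pop()
                    for child in node.children:
                        cs = (col[leaf_row[child.label]] if child.is_leaf
                              else state[id(child)])
                        prob *= Pmat[id(child)][state[id(node)], cs]
                        if not child.is_leaf:
                            stack.append(child)
                site += prob / k
        total += part["counts"][s] * math.log(site)
    return total
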