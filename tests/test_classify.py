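"""Haplogroup classification, frequency tables, chi-square test."""

import numpy as np
import pandas as pd
import pytest

import mtphylo as m
from mtphylo.classify import (
    chisq_independence,
    collapse_label,
    frequency_table,
    load_collapse_map,
)
from mtphylo.variants import CircularInterval, DEFAULT_RANGE

WG = CircularInterval(1, 16569)


def hap(tokens, rng=DEFAULT_RANGE, sid="s"):
    return m.Haplotype(sid, m.parse_variants(tokens) if tokens else frozenset(),
                       covered_range=rng)


class TestClassify:
    @pytest.mark.parametrize(
        "tokens, window, expected",
        [
            # control-region A2af motif; coding 5460 unobservable
            ("73@ 106-111d 16360", DEFAULT_RANGE, "A2af"),
            # whole genomes: basal + A2af1 + 89 / + 11482
            ("106-111d 5460 16360 6794 7960 89", WG, "A2af1a"),
            ("106-111d 5460 16360 6794 7960 11482", WG, "A2af1b"),
            # basal motif without the A2af1 markers stays A2af
            ("64 106-111d 5460 16360", WG, "A2af"),
            ("106-111d 5460 16360", WG, "A2af"),
        ],
    )
    def test_motif_examples(self, a2_tree, tokens, window, expected):
        assert m.classify(hap(tokens, window), a2_tree).best_node == expected

    def test_empty_variant_set_is_root(self, a2_tree):
        r = m.classify(hap("", DEFAULT_RANGE), a2_tree)
        assert r.best_node == "A2"
        assert r.score == 1.0 and r.private_mutations == 0

    def test_deterministic(self, default_tree):
        h = hap("73@ 106-111d 16360 146 153")
        calls = {m.classify(h, default_tree).best_node for _ in range(5)}
        assert len(calls) == 1

    def test_adding_child_mutation_never_shallower(self, a2_tree):
        base = "106-111d 5460 16360 6794 7960"
        before = m.classify(hap(base, WG), a2_tree)
        after = m.classify(hap(base + " 89", WG), a2_tree)
        depth = {n: a2_tree.nodes[n].depth for n in a2_tree.nodes}
        assert depth[after.best_node] >= depth[before.best_node]

    def test_private_mutations_counted(self, a2_tree):
        r = m.classify(hap("73@ 106-111d 16360 16111 16223"), a2_tree)
        assert r.best_node == "A2af"
        assert r.private_mutations == 2

    def test_empty_tree_error(self):
        with pytest.raises(ValueError):
            m.HaplogroupTree.from_text("")


class TestFoundingVariants:
    def test_reversion_removes_upstream(self, default_tree):
        f = default_tree.founding_variants("A2af1")
        toks = {m.serialize_variant(v) for v in f}
        assert "106-111d" in toks and "6794" in toks
        assert "73" not in toks and "64" not in toks  # both reverted

    def test_tree_loader_rejects_duplicates(self):
        text = "root:\n  A: 100\n  A: 200\n"
        with pytest.raises(ValueError, match="duplicate"):
            m.HaplogroupTree.from_text(text)


class TestFrequencyTable:
    def _meta(self, rows):
        return pd.DataFrame(rows, columns=["sample_id", "region", "region_kind"])

    def test_single_region_all_a2(self):
        results = [
            m.ClassificationResult(f"s{i}", "A2af1a", 1, 1, 0, 1.0)
            for i in range(5)
        ]
        meta = self._meta([(f"s{i}", "Coclé", "province") for i in range(5)])
        tab = frequency_table(results, meta)
        assert tab.loc["Coclé", "A2"] == 100.0
        assert tab.loc["Coclé", "Native"] == 100.0

    def test_comarca_native_total(self):
        # 44 + 48 (one L2) + 27 native samples across the three comarcas
        rows, results = [], []
        spec = [("Emberá-Wounaan", 44, 0), ("Kuna Yala", 48, 1),
                ("Ngäbe-Buglé", 27, 0)]
        i = 0
        for region, n, n_l2 in spec:
            for j in range(n):
                label = "L2" if j < n_l2 else "A2"
                results.append(m.ClassificationResult(f"s{i}", label, 1, 1, 0, 1.0))
                rows.append((f"s{i}", region, "comarca"))
                i += 1
        tab = frequency_table(results, self._meta(rows))
        assert tab.loc["Total Comarcas", "Native"] == pytest.approx(99.16, abs=0.005)

    def test_row_percentages_sum_to_100(self):
        rng = np.random.default_rng(0)
        labels = ["A2", "B2", "L2", "HV", "G"]
        results, rows = [], []
        for i in range(200):
            results.append(m.ClassificationResult(
                f"s{i}", str(rng.choice(labels)), 1, 1, 0, 1.0))
            rows.append((f"s{i}", f"R{int(rng.integers(3))}", "province"))
        tab = frequency_table(results, self._meta(rows))
        from mtphylo.classify import TABLE_BINS
        assert np.allclose(tab[TABLE_BINS].sum(axis=1), 100.0)

    def test_unmapped_label_error(self):
        results = [m.ClassificationResult("s0", "Z9", 1, 1, 0, 1.0)]
        with pytest.raises(ValueError, match="Z9"):
            frequency_table(results, self._meta([("s0", "X", "province")]))

    def test_collapse_longest_prefix(self):
        cm = load_collapse_map()
        assert collapse_label("A2af1a", cm) == "A2"
        assert collapse_label("L3e2b", cm) == "L3"
        assert collapse_label("Q1", cm) is None


class TestChiSquare:
    def test_uniform_table(self):
        stat, dof, p = chisq_independence([[10, 10], [10, 10]])
        assert stat == pytest.approx(0.0)
        assert dof == 1 and p == pytest.approx(1.0)

    def test_diagonal_table(self):
        stat, dof, p = chisq_independence([[20, 0], [0, 20]])
        assert stat == pytest.approx(40.0)
        assert dof == 1

    def test_matches_pearson_term_summation(self, rng):
        obs = rng.integers(1, 40, size=(3, 4)).astype(float)
        stat, dof, _ = chisq_independence(obs)
        total = obs.sum()
        exp = obs.sum(1, keepdims=True) @ obs.sum(0, keepdims=True) / total
        brute = ((obs - exp) ** 2 / exp).sum()
        assert stat == pytest.approx(brute, rel=1e-12)
        assert dof == 6

    def test_zero_margin_error(self):
        with pytest.raises(ValueError, match="margin"):
            chisq_independence([[0, 0], [5, 5]])
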