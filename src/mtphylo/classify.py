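"""Motif-based haplogroup classification and regional frequency tables.

Haplogroups are defined on a rooted tree whose edges carry mutational
motifs — the diagnostic variants acquired on that branch. A haplotype is
assigned to the deepest node whose *net founder motif* (positives
accumulated from the root, minus entries cancelled by a downstream back
mutation) it satisfies in full, with two safeguards:

* motif entries lying outside the sample's sequenced window are
  *unobservable* and are skipped entirely (control-region data cannot be
  penalized for coding-region diagnostics);
* a node needs evidence on its own defining branch: an observable
  surviving positive the sample carries, or — when the branch's only
  observable evidence is a back mutation (``@``, which matches when the
  sample *lacks* the upstream variant) — that back mutation satisfied
  while the parent node is contradicted by those very reverted sites.
  Absence of a mutation alone never promotes past a consistent parent,
  and fully unobservable branches never promote at all.

The second rule keeps a control-region-only haplotype carrying a clade's
basal motif from being pushed into a sub-clade on negative evidence,
while still allowing sub-clades defined by reversions to claim the
samples that contradict their parent's motif.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .haplotypes import Haplotype
from .variants import (
    NETWORK_FILTER,
    SiteFilter,
    Variant,
    parse_variants,
)


@dataclass
class HgNode:
    name: str
    parent: "HgNode | None"
    motif: frozenset[Variant]
    children: list["HgNode"]

    @property
    def depth(self) -> int:
        d, node = 0, self
        while node.parent is not None:
            d += 1
            node = node.parent
        return d


class HaplogroupTree:
    """Rooted haplogroup tree with per-edge defining motifs.

    The text format is one node per line, ``name: mutation tokens``, with
    two-space indentation giving the parent/child structure::

        root:
          A2: 64 73 146 153 235 263 16111 16223 16290 16319 16362
            A2af: 73@ 106-111d 5460 16360
    """

    def __init__(self, root: HgNode):
        self.root = root
        self.nodes: dict[str, HgNode] = {}
        stack = [root]
        while stack:
            n = stack.pop()
            if n.name in self.nodes:
                raise ValueError(f"duplicate haplogroup label {n.name!r}")
            self.nodes[n.name] = n
            stack.extend(n.children)

    @classmethod
    def from_text(cls, text: str) -> "HaplogroupTree":
        root: HgNode | None = None
        stack: list[tuple[int, HgNode]] = []  # (indent, node)
        for lineno, raw in enumerate(text.splitlines(), start=1):
            if not raw.strip() or raw.lstrip().startswith("#"):
                continue
            indent = len(raw) - len(raw.lstrip(" "))
            if indent % 2:
                raise ValueError(f"line {lineno}: odd indentation")
            name, _, tokens = raw.strip().partition(":")
            name = name.strip()
            motif = parse_variants(tokens) if tokens.strip() else frozenset()
            while stack and stack[-1][0] >= indent:
                stack.pop()
            parent = stack[-1][1] if stack else None
            if parent is not None and not motif:
                raise ValueError(f"line {lineno}: non-root node {name!r} has empty motif")
            node = HgNode(name, parent, motif, [])
            if parent is None:
                if root is not None:
                    raise ValueError(f"line {lineno}: second root {name!r}")
                root = node
            else:
                parent.children.append(node)
            stack.append((indent, node))
        if root is None:
            raise ValueError("empty haplogroup tree")
        return cls(root)

    @classmethod
    def from_file(cls, path) -> "HaplogroupTree":
        with open(path) as fh:
            return cls.from_text(fh.read())

    @classmethod
    def bundled(cls, name: str = "default") -> "HaplogroupTree":
        """Load a bundled tree: ``default`` (cohort-wide) or ``a2`` (the
        A2ad/A2af sub-tree only, rooted at A2)."""
        text = resources.files("mtphylo").joinpath("data", f"{name}_tree.txt").read_text()
        return cls.from_text(text)

    def path(self, name: str) -> list[HgNode]:
        node = self.nodes[name]
        out = []
        while node is not None:
            out.append(node)
            node = node.parent
        return out[::-1]

    def founding_variants(self, name: str) -> frozenset[Variant]:
        """Variant set (relative to the tree's reference root) carried by
        the founder haplotype of a haplogroup: positives accumulate along
        the path, reversions remove the corresponding upstream variant."""
        acc: set[Variant] = set()
        for node in self.path(name):
            for v in node.motif:
                if v.reversion:
                    acc.discard(v.without_reversion())
                else:
                    acc.add(v)
        return frozenset(acc)

    def diagnostic_positions(self) -> set[int]:
        out: set[int] = set()
        for node in self.nodes.values():
            for v in node.motif:
                out.update(range(v.position, v.span_end + 1))
        return out


@dataclass(frozen=True)
class ClassificationResult:
    sample_id: str
    best_node: str
    matched: int
    expected: int
    private_mutations: int
    score: float


def classify(
    h: Haplotype,
    tree: HaplogroupTree,
    site_filter: SiteFilter = NETWORK_FILTER,
) -> ClassificationResult:
    """Assign a haplotype to its best-matching haplogroup.

    A node is evaluated against its *net founder motif*: the positive
    entries accumulated from the root, minus those cancelled by a
    downstream reversion (so a sub-clade that reverts an upstream
    diagnostic is judged on the net expectation, not edge by edge). A node
    matches when every observable founder variant is present, every
    observable reverted variant is absent, and each edge on the path
    contributes at least one observable surviving positive that the sample
    carries — the positive-evidence gate that keeps unobservable or
    reversion-only edges from promoting a call.
    """
    if not tree.nodes:
        raise ValueError("empty haplogroup tree")
    present = {v.without_reversion() for v in h.variants if not v.reversion}
    observable = h.covered_range.contains_variant

    info: dict[str, dict] = {}

    def evaluate(node: HgNode) -> dict:
        """Net founder motif and match bookkeeping for one node."""
        if node.name in info:
            return info[node.name]
        founder: set[Variant] = set()
        reverted: set[Variant] = set()
        for anc in tree.path(node.name):
            for e in anc.motif:
                if e.reversion:
                    base = e.without_reversion()
                    founder.discard(base)
                    reverted.add(base)
                else:
                    founder.add(e)
                    reverted.discard(e)
        founder_obs = {e for e in founder if observable(e)}
        reverted_obs = {e for e in reverted if observable(e)}
        matched = sum(1 for e in founder_obs if e in present) + sum(
            1 for e in reverted_obs if e not in present)
        expected = len(founder_obs) + len(reverted_obs)
        consistent = matched == expected
        # terminal-edge evidence: does the defining branch of this node
        # carry an observable *surviving* positive the sample has, or an
        # observable reversion the sample satisfies?
        pos_evidence = any(
            not e.reversion and observable(e) and e in founder and e in present
            for e in node.motif
        )
        rev_evidence = any(
            e.reversion and observable(e.without_reversion())
            and e.without_reversion() not in present
            for e in node.motif
        )
        out = {
            "founder": founder, "matched": matched, "expected": expected,
            "consistent": consistent, "pos": pos_evidence, "rev": rev_evidence,
        }
        info[node.name] = out
        return out

    passes: dict[str, bool] = {tree.root.name: True}

    def node_passes(node: HgNode) -> bool:
        if node.name in passes:
            return passes[node.name]
        ev = evaluate(node)
        parent_ok = node_passes(node.parent)
        # Positive mutations on the defining branch promote outright; a
        # branch whose only observable evidence is a back mutation promotes
        # only when the parent itself is contradicted (by those very
        # reverted sites) — otherwise absence of a mutation is not treated
        # as evidence for a deeper clade.
        ok = ev["consistent"] and (
            ev["pos"] or (ev["rev"] and not parent_ok)
        )
        passes[node.name] = ok
        return ok

    counted = site_filter.apply(h.variants, profile="network")
    candidates = []
    for node in tree.nodes.values():
        if node_passes(node):
            ev = evaluate(node)
            private = sum(1 for v in counted if v not in ev["founder"])
            candidates.append((node, ev["matched"], ev["expected"], private))
    best, matched, expected, private = min(
        candidates, key=lambda c: (-c[0].depth, c[3], c[0].name))
    return ClassificationResult(
        sample_id=h.sample_id,
        best_node=best.name,
        matched=matched,
        expected=expected,
        private_mutations=private,
        score=matched / expected if expected else 1.0,
    )


# ---------------------------------------------------------------------------
# regional frequency tables

#: column layout of the regional frequency table; aggregate columns are
#: derived from the individual haplogroup bins.
TABLE_BINS = ["A2", "B2", "C1", "D1", "L0", "L1", "L2", "L3",
              "HV", "JT", "N1'2", "U", "G"]
AGGREGATES: dict[str, list[str]] = {
    "Native": ["A2", "B2", "C1", "D1"],
    "Africa": ["L0", "L1", "L2", "L3"],
    "West Eurasia": ["HV", "JT", "N1'2", "U"],
    "East Asia": ["G"],
}
TABLE_COLUMNS = ["A2", "B2", "C1", "D1", "Native", "L0", "L1", "L2", "L3",
                 "Africa", "HV", "JT", "N1'2", "U", "West Eurasia", "G",
                 "East Asia"]


def load_collapse_map(path=None) -> dict[str, str]:
    """Haplogroup → major-clade bin map (tab-separated, two columns).

    Without a path, the bundled map mirroring the standard table layout is
    loaded. Lookup is by longest label prefix, so sub-haplogroup calls
    (``A2af1a``) collapse into their major clade (``A2``).
    """
    if path is None:
        text = resources.files("mtphylo").joinpath("data", "collapse_map.tsv").read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    out: dict[str, str] = {}
    for line in text.splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        label, _, bin_ = line.partition("\t")
        out[label.strip()] = bin_.strip()
    return out


def collapse_label(label: str, collapse: Mapping[str, str]) -> str | None:
    if label in collapse:
        return collapse[label]
    hits = [k for k in collapse if label.startswith(k)]
    if not hits:
        return None
    return collapse[max(hits, key=len)]


def frequency_table(
    results: Sequence[ClassificationResult],
    metadata: pd.DataFrame,
    collapse: Mapping[str, str] | None = None,
    grouping: str = "region",
    region_kind: str = "region_kind",
) -> pd.DataFrame:
    """Counts and row percentages of major haplogroups per region.

    ``metadata`` must carry ``sample_id``, the grouping column and (for
    the province/comarca subtotal rows) a ``region_kind`` column with
    values ``province``/``comarca``. Returns a table in percent with an
    ``n`` column, one row per region plus ``Total Provinces``,
    ``Total Comarcas`` and ``Grand Total`` rows; aggregation into totals
    is count-weighted.
    """
    if collapse is None:
        collapse = load_collapse_map()
    meta = metadata.set_index("sample_id")
    rows = []
    offenders = []
    for r in results:
        bin_ = collapse_label(r.best_node, collapse)
        if bin_ is None:
            offenders.append(r.best_node)
            continue
        info = meta.loc[r.sample_id]
        rows.append((info[grouping], info.get(region_kind, "province"), bin_))
    if offenders:
        raise ValueError(f"unmapped haplogroup labels: {sorted(set(offenders))}")
    df = pd.DataFrame(rows, columns=["region", "kind", "bin"])
    counts = (
        df.pivot_table(index="region", columns="bin", aggfunc="size", fill_value=0)
        .reindex(columns=TABLE_BINS, fill_value=0)
    )
    kind_of = df.drop_duplicates("region").set_index("region")["kind"]

    def pct_row(c: pd.Series) -> pd.Series:
        n = int(c.sum())
        row = {"n": n}
        for b in TABLE_BINS:
            row[b] = 100.0 * c[b] / n
        for agg, members in AGGREGATES.items():
            row[agg] = 100.0 * sum(c[b] for b in members) / n
        return pd.Series(row)

    out_rows: dict[str, pd.Series] = {}
    for region in counts.index:
        out_rows[region] = pct_row(counts.loc[region])
    prov = counts.loc[[r for r in counts.index if kind_of[r] == "province"]].sum()
    com = counts.loc[[r for r in counts.index if kind_of[r] == "comarca"]].sum()
    if prov.sum():
        out_rows["Total Provinces"] = pct_row(prov)
    if com.sum():
        out_rows["Total Comarcas"] = pct_row(com)
    out_rows["Grand Total"] = pct_row(counts.sum())
    table = pd.DataFrame(out_rows).T
    table["n"] = table["n"].astype(int)
    return table[["n"] + TABLE_COLUMNS]


def chisq_independence(table) -> tuple[float, int, float]:
    """Pearson chi-square test of independence on a contingency table."""
    arr = np.asarray(table, dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 2 or arr.shape[1] < 2:
        raise ValueError("contingency table must be at least 2x2")
    if (arr < 0).any():
        raise ValueError("negative counts in contingency table")
    if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
        raise ValueError("zero-margin row/column; collapse categories first")
    stat, p, dof, _ = sps.chi2_contingency(arr, correction=False)
    return float(stat), int(dof), float(p)
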