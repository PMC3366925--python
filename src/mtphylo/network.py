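"""Median-joining networks of control-region haplotypes.

Observed haplotypes are binary-coded over their filtered variants
(presence/absence of each retained mutation). The network iterates
between a minimum-spanning network (the union of all minimum spanning
trees, with an optional tolerance ``epsilon``) and the addition of
quasi-median vectors — majority-consensus profiles of connected triplets
— until no new vector arises. Inferred medians stand for unsampled
intermediate haplotypes.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .dating import AgeEstimate, ClockConfig
from .haplotypes import Haplotype
from .variants import NETWORK_FILTER, SiteFilter, serialize_variant


@dataclass
class CharacterMatrix:
    """Binary haplotype-by-variant matrix with taxon multiplicities."""

    taxa: list[str]                  # representative id per distinct haplotype
    matrix: np.ndarray               # shape (n_taxa, n_characters), 0/1
    characters: list[str]            # variant token per column
    weights: np.ndarray              # positive int per column
    multiplicity: np.ndarray         # samples per taxon
    members: list[list[str]]         # sample ids collapsed into each taxon
    regions: list[dict[str, int]]    # geographic composition per taxon

    def __post_init__(self) -> None:
        if self.matrix.size and not np.isin(self.matrix, (0, 1)).all():
            raise ValueError("character matrix must be binary")
        if (self.multiplicity < 1).any():
            raise ValueError("multiplicities must be >= 1")


def build_character_matrix(
    haps: Sequence[Haplotype],
    site_filter: SiteFilter = NETWORK_FILTER,
    include_reference: bool = False,
    ancestor: Haplotype | None = None,
    weights: Mapping[str, int] | None = None,
) -> CharacterMatrix:
    """Binary-code haplotypes over their filtered variants.

    Identical rows are merged with multiplicity (the published circle
    sizes); constant columns are removed. ``include_reference`` adds a
    variant-free root profile (so that mutations shared by all samples
    relative to the reference stay informative); ``ancestor`` instead
    roots the matrix at an explicit haplotype (e.g. a clade's founding
    motif). The added root row carries no samples (empty member list)
    unless its profile coincides with an observed haplotype.
    """
    if not haps:
        raise ValueError("no haplotypes supplied")
    if include_reference and ancestor is not None:
        raise ValueError("pass either include_reference or ancestor, not both")
    filtered = [site_filter.apply(h.variants, profile="network") for h in haps]
    anc_tokens: set[str] = set()
    if ancestor is not None:
        anc_tokens = {
            serialize_variant(v)
            for v in site_filter.apply(ancestor.variants, profile="network")
        }
    universe = sorted(
        {serialize_variant(v) for fs in filtered for v in fs} | anc_tokens)
    profiles: dict[tuple[int, ...], list[int]] = {}
    order: list[tuple[int, ...]] = []
    for i, fs in enumerate(filtered):
        toks = {serialize_variant(v) for v in fs}
        prof = tuple(1 if t in toks else 0 for t in universe)
        if prof not in profiles:
            profiles[prof] = []
            order.append(prof)
        profiles[prof].append(i)
    if include_reference or ancestor is not None:
        root_prof = tuple(1 if t in anc_tokens else 0 for t in universe)
        if root_prof not in profiles:
            profiles[root_prof] = []
            order.append(root_prof)

    taxa, mult, members, regions, rows = [], [], [], [], []
    for prof in order:
        idx = profiles[prof]
        if idx:
            ids = [haps[i].sample_id for i in idx]
            reg: dict[str, int] = {}
            for i in idx:
                if haps[i].region:
                    reg[haps[i].region] = reg.get(haps[i].region, 0) + 1
        else:  # synthetic root taxon (reference or supplied ancestor)
            ids, reg = [], {}
        taxa.append(ids[0] if idx else "reference")
        members.append(ids)
        mult.append(max(len(idx), 1))
        regions.append(reg)
        rows.append(prof)
    mat = np.array(rows, dtype=np.int8).reshape(len(rows), len(universe))
    keep = [j for j in range(mat.shape[1])
            if 0 < mat[:, j].sum() < mat.shape[0]]
    mat = mat[:, keep]
    chars = [universe[j] for j in keep]
    w = np.array([1 if weights is None else int(weights.get(c, 1)) for c in chars],
                 dtype=int)
    if (w < 1).any():
        raise ValueError("character weights must be positive integers")
    return CharacterMatrix(
        taxa=taxa, matrix=mat, characters=chars, weights=w,
        multiplicity=np.array(mult, dtype=int), members=members, regions=regions,
    )


@dataclass
class HapNetwork:
    """Median-joining network: observed + inferred median haplotypes."""

    graph: nx.Graph
    characters: list[str]

    @property
    def observed(self) -> list[str]:
        return [n for n, d in self.graph.nodes(data=True) if not d["is_median"]]

    @property
    def medians(self) -> list[str]:
        return [n for n, d in self.graph.nodes(data=True) if d["is_median"]]

    def node_table(self) -> pd.DataFrame:
        rows = []
        for n, d in self.graph.nodes(data=True):
            rows.append(
                {
                    "id": n,
                    "is_median": d["is_median"],
                    "multiplicity": d["multiplicity"],
                    "regions": ";".join(f"{k}:{v}" for k, v in sorted(d["regions"].items())),
                }
            )
        return pd.DataFrame(rows)

    def write_gml(self, path) -> None:
        g = nx.Graph()
        for n, d in self.graph.nodes(data=True):
            g.add_node(n, is_median=int(d["is_median"]),
                       multiplicity=int(d["multiplicity"]),
                       regions=";".join(f"{k}:{v}" for k, v in sorted(d["regions"].items())))
        for u, v, d in self.graph.edges(data=True):
            g.add_edge(u, v, weight=int(d["weight"]), label="|".join(d["labels"]))
        nx.write_gml(g, str(path))

    def write_dot(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("graph hapnetwork {\n")
            for n, d in self.graph.nodes(data=True):
                shape = "point" if d["is_median"] else "circle"
                fh.write(f'  "{n}" [shape={shape}, width={0.2 + 0.1 * d["multiplicity"]:.2f}];\n')
            for u, v, d in self.graph.edges(data=True):
                fh.write(f'  "{u}" -- "{v}" [label="{"|".join(d["labels"])}"];\n')
            fh.write("}\n")


def _distance_matrix(X: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Weighted Hamming distances between binary profile rows."""
    Xf = X.astype(np.float64)
    s = Xf @ w
    cross = Xf @ (Xf * w).T
    D = s[:, None] + s[None, :] - 2 * cross
    return np.rint(D).astype(np.int64)


def _msn_edges(
    names: list[str], X: np.ndarray, w: np.ndarray, epsilon: int
) -> list[tuple[int, int, int]]:
    """Minimum-spanning network: an edge of weight d is kept iff its
    endpoints are not already connected using edges of weight < d - eps."""
    n = len(names)
    D = _distance_matrix(X, w)
    iu, ju = np.triu_indices(n, k=1)
    order = np.argsort(D[iu, ju], kind="stable")
    edges = [(int(D[iu[k], ju[k]]), int(iu[k]), int(ju[k])) for k in order]

    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    kept: list[tuple[int, int, int]] = []
    merge_ptr = 0
    for idx, (d, a, b) in enumerate(edges):
        # merge every edge of weight < d - epsilon before testing this class
        while merge_ptr < len(edges) and edges[merge_ptr][0] < d - epsilon:
            _, x, y = edges[merge_ptr]
            parent[find(x)] = find(y)
            merge_ptr += 1
        if find(a) != find(b):
            kept.append((a, b, d))
    return kept


def median_joining(matrix: CharacterMatrix, epsilon: int = 0,
                   max_rounds: int = 100) -> HapNetwork:
    """Construct the median-joining network of a binary character matrix."""
    if epsilon < 0:
        raise ValueError("epsilon must be non-negative")
    w = matrix.weights.astype(np.float64)
    names: list[str] = list(matrix.taxa)
    X = matrix.matrix.astype(np.int8).copy()
    n_sampled = len(names)
    median_count = 0
    seen_profiles = {tuple(int(x) for x in row) for row in X}

    for _ in range(max_rounds):
        edges = _msn_edges(names, X, w, epsilon)
        adj: dict[int, set[int]] = {i: set() for i in range(len(names))}
        for a, b, _d in edges:
            adj[a].add(b)
            adj[b].add(a)
        # connected triples = paths of length two (>= 2 of 3 pairs linked)
        triples = {
            tuple(sorted((u, v, x)))
            for u in range(len(names))
            for v, x in itertools.combinations(sorted(adj[u]), 2)
        }
        new_profiles = []
        for u, v, x in sorted(triples):
            med = (X[u].astype(int) + X[v] + X[x] >= 2).astype(np.int8)
            key = tuple(int(b) for b in med)
            if key not in seen_profiles:
                seen_profiles.add(key)
                new_profiles.append(med)
        if not new_profiles:
            break
        for med in new_profiles:
            median_count += 1
            names.append(f"mv{median_count}")
        X = np.vstack([X, np.array(new_profiles, dtype=np.int8)])

    edges = _msn_edges(names, X, w, epsilon)
    g = nx.Graph()
    diff_chars = lambda a, b: [
        matrix.characters[j] for j in np.nonzero(X[a] != X[b])[0]
    ]
    for i, name in enumerate(names):
        if i < n_sampled:
            g.add_node(name, is_median=False,
                       profile=tuple(int(x) for x in X[i]),
                       multiplicity=int(matrix.multiplicity[i]),
                       members=list(matrix.members[i]),
                       regions=dict(matrix.regions[i]))
        else:
            g.add_node(name, is_median=True,
                       profile=tuple(int(x) for x in X[i]),
                       multiplicity=0, members=[], regions={})
    for a, b, d in edges:
        g.add_edge(names[a], names[b], weight=d, labels=diff_chars(a, b))
    # guarantee that every minimum spanning tree of the sampled haplotypes
    # embeds in the network: re-add a direct minimum-spanning link wherever
    # median chains fail to realize it at its exact mutational length
    for a, b, d in _msn_edges(names[:n_sampled], X[:n_sampled], w, epsilon):
        u, v = names[a], names[b]
        try:
            sp = nx.dijkstra_path_length(g, u, v, weight="weight")
        except nx.NetworkXNoPath:
            sp = math.inf
        if sp > d:
            g.add_edge(u, v, weight=d, labels=diff_chars(a, b))
    # prune unsampled nodes that ended up as dangling leaves
    for n in list(g.nodes):
        if g.nodes[n]["is_median"] and g.degree(n) <= 1:
            g.remove_node(n)
    return HapNetwork(graph=g, characters=list(matrix.characters))


def network_node_ages(
    net: HapNetwork,
    root: str,
    clock: ClockConfig,
    scale: str = "control_region",
) -> AgeEstimate:
    """Age of an ancestral node: multiplicity-weighted mean mutational
    distance (shortest network path) from the root to every sampled
    haplotype, converted to years by the chosen clock."""
    if root not in net.graph:
        raise ValueError(f"root {root!r} not in network")
    lengths = nx.single_source_dijkstra_path_length(net.graph, root, weight="weight")
    total = 0.0
    n = 0
    for t in net.observed:
        if not net.graph.nodes[t]["members"]:
            continue  # synthetic root row, not a sampled haplotype
        m = net.graph.nodes[t]["multiplicity"]
        total += m * lengths[t]
        n += m
    if n == 0:
        raise ValueError("network has no sampled haplotypes")
    rho = total / n
    rate = clock.rate_for(scale)
    return AgeEstimate(rho=rho, sigma=float("nan"), method="rho",
                       age_years=rho * rate, age_se_years=float("nan"),
                       clock_label=clock.label, scale=scale)
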