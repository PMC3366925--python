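"""Synthetic cohorts with the statistical structure the pipeline assumes.

The generator emulates a region-stratified mtDNA survey: samples are drawn
per region with a fixed haplogroup composition (the default composition
encodes the published regional frequency table of the Panamanian cohort),
each haplotype starts from its haplogroup's founding motif and accumulates
Poisson-distributed private control-region mutations at hotspot-weighted
positions, and the metadata layer adds foreign-TMA samples and maternally
related clusters (which share a haplotype). A truth record keeps every
latent variable, so downstream stages can be scored without external data.

``composition="exact"`` places haplogroup counts by quota instead of
sampling, making frequency-table reconstruction deterministic.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .classify import HaplogroupTree
from .dating import ClockConfig, GenealogyTree, TreeNode, discrete_gamma_rates, hky_eigensystem
from .haplotypes import Haplotype
from .variants import (
    DEFAULT_CSTRETCH,
    DEFAULT_EXCLUDED,
    DEFAULT_RANGE,
    CircularInterval,
    Variant,
    parse_variant,
)

# ---------------------------------------------------------------------------
# default cohort composition: counts per region per major haplogroup,
# provinces first, then the three indigenous comarcas (n = 1350 in total)

HAPLOGROUP_BINS = ["A2", "B2", "C1", "D1", "L0", "L1", "L2", "L3",
                   "HV", "JT", "N1'2", "U", "G"]

REGION_COMPOSITION: dict[str, tuple[str, dict[str, int]]] = {
    "Bocas del Toro": ("province", {"A2": 28, "B2": 11, "L1": 2, "L2": 11, "L3": 8}),
    "Chiriquí": ("province", {"A2": 227, "B2": 91, "C1": 4, "D1": 5, "L0": 6,
                               "L1": 18, "L2": 16, "L3": 6, "HV": 3, "JT": 2}),
    "Coclé": ("province", {"A2": 50, "B2": 39, "C1": 7, "D1": 1, "L1": 1,
                            "L2": 3, "L3": 4, "HV": 2, "JT": 1, "N1'2": 1}),
    "Colón": ("province", {"A2": 19, "B2": 11, "C1": 1, "L1": 3, "L2": 15,
                            "L3": 7, "U": 1}),
    "Darién": ("province", {"A2": 13, "B2": 8, "C1": 3, "D1": 1, "L1": 5,
                             "L2": 9, "L3": 4, "HV": 1, "U": 1}),
    "Herrera": ("province", {"A2": 71, "B2": 28, "C1": 4, "L2": 5, "L3": 7, "U": 1}),
    "Los Santos": ("province", {"A2": 69, "B2": 30, "C1": 3, "D1": 1, "L0": 1,
                                 "L2": 3, "L3": 9, "HV": 4, "U": 1, "G": 1}),
    "Panamá": ("province", {"A2": 78, "B2": 46, "C1": 5, "D1": 3, "L1": 9,
                             "L2": 11, "L3": 17, "HV": 8, "U": 1}),
    "Veraguas": ("province", {"A2": 77, "B2": 65, "C1": 10, "L0": 1, "L1": 1,
                               "L2": 4, "L3": 4, "HV": 4}),
    "Emberá-Wounaan": ("comarca", {"A2": 7, "B2": 16, "C1": 18, "D1": 3}),
    "Kuna Yala": ("comarca", {"A2": 37, "B2": 6, "C1": 4, "L2": 1}),
    "Ngäbe-Buglé": ("comarca", {"A2": 13, "B2": 13, "C1": 1}),
}

#: A2 sub-clade quotas within the cohort's 689 A2 samples: 326 carry the
#: 6-bp deletion clade (A2af and descendants), ~42 the 16175/16300 clade.
A2_SUBCLADE_QUOTAS = {"A2af": 80, "A2af1a": 200, "A2af1b": 46, "A2ad": 42}

#: founder ages (years) used to draw private-mutation counts
DEFAULT_CLADE_AGES: dict[str, float] = {
    "A2": 18000.0, "A2ad": 16000.0,
    "A2af": 23240.0, "A2af1a": 17000.0, "A2af1b": 17000.0,
    "B2": 18000.0, "C1": 18000.0, "D1": 18000.0,
    "L0": 40000.0, "L1": 40000.0, "L2": 35000.0, "L3": 30000.0,
    "HV": 20000.0, "JT": 25000.0, "N1'2": 25000.0, "U": 30000.0, "G": 25000.0,
}

#: classic fast control-region sites get an elevated mutation rate
DEFAULT_HOTSPOTS: dict[int, float] = {
    16093: 5.0, 16129: 5.0, 16189: 5.0, 16311: 5.0,
    150: 5.0, 152: 5.0, 195: 5.0,
}

FOREIGN_TMA_ORIGINS: dict[str, float] = {
    "South America": 0.483, "Central America": 0.215, "Europe": 0.128,
    "North America": 0.074, "Caribbean": 0.060, "Asia": 0.040,
}
_FOREIGN_HAPLOGROUPS = {
    "South America": ["A2", "B2", "C1", "D1"],
    "Central America": ["A2", "B2"],
    "Europe": ["HV", "JT", "U"],
    "North America": ["A2", "HV"],
    "Caribbean": ["L2", "L3"],
    "Asia": ["G"],
}


@dataclass
class SimConfig:
    """All knobs of the cohort generator (defaults = study conditions)."""

    seed: int = 0
    regions: Mapping[str, tuple[str, dict[str, int]]] = field(
        default_factory=lambda: dict(REGION_COMPOSITION))
    clade_ages: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CLADE_AGES))
    clock: ClockConfig = field(default_factory=ClockConfig)
    hotspot_multipliers: Mapping[int, float] = field(
        default_factory=lambda: dict(DEFAULT_HOTSPOTS))
    n_foreign: int = 149
    n_related_pairs: int = 42
    n_related_triplets: int = 13
    composition: str = "exact"  # or "sampled"
    a2_subclades: Mapping[str, int] = field(
        default_factory=lambda: dict(A2_SUBCLADE_QUOTAS))
    covered_range: CircularInterval = DEFAULT_RANGE
    generations_mean: float = 3.13
    generations_sd: float = 0.87

    def __post_init__(self) -> None:
        for region, (_kind, comp) in self.regions.items():
            if any(c < 0 for c in comp.values()) or sum(comp.values()) == 0:
                raise ValueError(f"invalid composition for region {region!r}")
        if any(a < 0 for a in self.clade_ages.values()):
            raise ValueError("clade ages must be non-negative")
        if self.composition not in ("exact", "sampled"):
            raise ValueError("composition must be 'exact' or 'sampled'")


@dataclass
class SimulatedCohort:
    haplotypes: list[Haplotype]
    metadata: pd.DataFrame
    truth: dict

    def write(self, hap_path, meta_path, truth_path) -> None:
        from .haplotypes import write_haplotype_table

        write_haplotype_table(self.haplotypes, hap_path)
        self.metadata.to_csv(meta_path, sep="\t", index=False)
        with open(truth_path, "w") as fh:
            json.dump(self.truth, fh, indent=1, sort_keys=True)


def _private_site_pool(tree: HaplogroupTree, window: CircularInterval,
                       hotspots: Mapping[int, float]):
    """Candidate positions (and weights) for private transitions: the
    sequenced window minus diagnostic, excluded and C-stretch positions."""
    banned = set(tree.diagnostic_positions())
    for tok in DEFAULT_EXCLUDED:
        banned.add(parse_variant(tok).position)
    for rng in DEFAULT_CSTRETCH:
        banned.update(rng.positions())
    pool = np.array([p for p in window.positions() if p not in banned])
    weights = np.array([hotspots.get(int(p), 1.0) for p in pool], dtype=float)
    return pool, weights / weights.sum()


def simulate_cohort(config: SimConfig | None = None,
                    tree: HaplogroupTree | None = None) -> SimulatedCohort:
    """Generate a cohort: haplotype table, metadata table, truth record."""
    config = config or SimConfig()
    tree = tree or HaplogroupTree.bundled("default")
    rng = np.random.default_rng(config.seed)
    pool, pool_w = _private_site_pool(tree, config.covered_range,
                                      config.hotspot_multipliers)
    founders = {
        name: frozenset(
            v for v in tree.founding_variants(name)
            if config.covered_range.contains_variant(v)
        )
        for name in tree.nodes
    }
    rate = config.clock.years_per_mutation

    def evolve(haplogroup: str) -> tuple[frozenset[Variant], int]:
        age = config.clade_ages.get(haplogroup)
        if age is None:
            age = config.clade_ages.get(haplogroup[:2], 20000.0)
        lam = age / rate
        n_priv = int(rng.poisson(lam))
        base = set(founders[haplogroup])
        taken = {v.position for v in base}
        added = 0
        while added < n_priv:
            p = int(rng.choice(pool, p=pool_w))
            if p in taken:
                continue
            base.add(Variant(p))
            taken.add(p)
            added += 1
        return frozenset(base), n_priv

    # --- regional draws ----------------------------------------------------
    assignments: list[tuple[str, str, str]] = []  # (region, kind, haplogroup)
    for region, (kind, comp) in config.regions.items():
        labels = sorted(comp)
        counts = np.array([comp[l] for l in labels])
        if config.composition == "exact":
            for lab, c in zip(labels, counts):
                assignments.extend((region, kind, lab) for _ in range(c))
        else:
            draw = rng.multinomial(counts.sum(), counts / counts.sum())
            for lab, c in zip(labels, draw):
                assignments.extend((region, kind, lab) for _ in range(int(c)))

    # refine A2 draws into sub-clades by global quota (exact) or by the
    # quota proportions (sampled)
    a2_idx = [i for i, (_r, _k, lab) in enumerate(assignments) if lab == "A2"]
    order = rng.permutation(len(a2_idx))
    quotas = [(sub, q) for sub, q in sorted(config.a2_subclades.items())]
    quota_base = 689  # quotas are stated for the default cohort's A2 count
    cursor = 0
    for sub, q in quotas:
        frac = q / quota_base
        if config.composition == "exact":
            take = int(round(frac * len(a2_idx)))
        else:
            take = int(rng.binomial(len(a2_idx), min(frac, 1.0)))
        for j in range(cursor, min(cursor + take, len(a2_idx))):
            i = a2_idx[order[j]]
            assignments[i] = (assignments[i][0], assignments[i][1], sub)
        cursor = min(cursor + take, len(a2_idx))

    haps: list[Haplotype] = []
    meta_rows: list[dict] = []
    truth_samples: dict[str, dict] = {}

    def add_sample(sid: str, region: str, kind: str, hg: str, tma: str,
                   variants: frozenset[Variant] | None = None,
                   n_priv: int | None = None, cluster: str = "") -> Haplotype:
        if variants is None:
            variants, n_priv = evolve(hg)
        gen = max(1, int(round(rng.normal(config.generations_mean,
                                          config.generations_sd))))
        h = Haplotype(sample_id=sid, variants=variants,
                      covered_range=config.covered_range,
                      region=region, tma_origin=tma)
        haps.append(h)
        meta_rows.append(
            {"sample_id": sid, "region": region, "region_kind": kind,
             "tma_origin": tma, "generations": gen, "cluster_id": cluster}
        )
        truth_samples[sid] = {"haplogroup": hg, "region": region,
                              "n_private": int(n_priv or 0), "tma_origin": tma,
                              "cluster_id": cluster}
        return h

    for i, (region, kind, hg) in enumerate(assignments):
        add_sample(f"PA{i + 1:05d}", region, kind, hg, "Panama")

    # --- foreign-TMA samples ----------------------------------------------
    origins = list(FOREIGN_TMA_ORIGINS)
    origin_p = np.array([FOREIGN_TMA_ORIGINS[o] for o in origins])
    origin_p = origin_p / origin_p.sum()
    province_names = [r for r, (k, _c) in config.regions.items() if k == "province"]
    for j in range(config.n_foreign):
        origin = origins[int(rng.choice(len(origins), p=origin_p))]
        hg = str(rng.choice(_FOREIGN_HAPLOGROUPS[origin]))
        region = province_names[int(rng.integers(len(province_names)))]
        add_sample(f"FX{j + 1:04d}", region, "province", hg, origin)

    # --- relatedness clusters: members share the seed's haplotype ----------
    core_ids = [h.sample_id for h in haps if h.tma_origin == "Panama"]
    seeds = rng.choice(len(core_ids), size=config.n_related_pairs
                       + config.n_related_triplets, replace=False)
    dup_counter = 0
    for ci, seed_idx in enumerate(seeds):
        size = 2 if ci < config.n_related_pairs else 3
        cluster = f"F{ci + 1:03d}"
        src = haps[[h.sample_id for h in haps].index(core_ids[seed_idx])]
        truth_samples[src.sample_id]["cluster_id"] = cluster
        for row in meta_rows:
            if row["sample_id"] == src.sample_id:
                row["cluster_id"] = cluster
        for _ in range(size - 1):
            dup_counter += 1
            add_sample(f"RD{dup_counter:04d}", src.region, "province",
                       truth_samples[src.sample_id]["haplogroup"], "Panama",
                       variants=src.variants,
                       n_priv=truth_samples[src.sample_id]["n_private"],
                       cluster=cluster)

    metadata = pd.DataFrame(meta_rows)
    truth = {
        "seed": config.seed,
        "composition": config.composition,
        "n_core": len(assignments),
        "n_foreign": config.n_foreign,
        "n_related_extra": dup_counter,
        "clock_years_per_mutation": rate,
        "samples": truth_samples,
    }
    return SimulatedCohort(haplotypes=haps, metadata=metadata, truth=truth)


# ---------------------------------------------------------------------------
# genealogy / alignment simulation (oracles for the dating stack)


def star_clade(n_leaves: int, age_years: float, clock: ClockConfig,
               rng: np.random.Generator) -> GenealogyTree:
    """Star genealogy of known age: each lineage accumulates a Poisson
    number of mutations with mean age / years_per_mutation."""
    lam = age_years / clock.years_per_mutation
    children = [
        TreeNode(label=f"t{i}", length=float(rng.poisson(lam)))
        for i in range(n_leaves)
    ]
    return GenealogyTree(TreeNode(label="root", children=children))


def rho_age_calibration(
    root_seed: int,
    n_replicates: int = 500,
    n_leaves: int = 200,
    age_years: float = 23240.0,
    clock: ClockConfig | None = None,
) -> dict:
    """Monte-Carlo calibration of the rho clade-age pipeline.

    Simulates replicate star clades of known age (one RNG stream per
    replicate, all spawned from ``root_seed``), estimates each age via
    rho, and summarizes bias: the estimator is analytically unbiased, so
    the mean estimate should sit within Monte-Carlo error of the truth.
    """
    from . import dating

    clock = clock or ClockConfig()
    streams = np.random.SeedSequence(root_seed).spawn(n_replicates)
    ages = np.empty(n_replicates)
    for i, ss in enumerate(streams):
        tree = star_clade(n_leaves, age_years, clock, np.random.default_rng(ss))
        est = dating.to_years(dating.rho_sigma(tree), clock, "whole_molecule")
        ages[i] = est.age_years
    se = float(ages.std(ddof=1) / math.sqrt(n_replicates))
    return {
        "true_age": age_years,
        "mean_estimate": float(ages.mean()),
        "se": se,
        "bias": float(ages.mean() - age_years),
        "z": float((ages.mean() - age_years) / se),
        "n_replicates": n_replicates,
        "n_leaves": n_leaves,
    }


def simulate_alignment(
    tree: GenealogyTree,
    rng: np.random.Generator,
    n_sites: int = 16569,
    freqs: Sequence[float] = (0.31, 0.31, 0.13, 0.25),
    kappa: float = 10.0,
    alpha: float | None = 0.5,
    n_rate_categories: int = 32,
    partitions: Sequence[tuple[CircularInterval, float]] = (),
) -> dict[str, str]:
    """Evolve an alignment down a fixed tree under HKY85 (+ discrete Γ).

    ``partitions`` optionally lists (window, rate multiplier) pairs; sites
    outside every window evolve at the residual rate so that the overall
    site-weighted mean multiplier is one. Branch lengths are expected
    substitutions per site. Returns label -> sequence.
    """
    freqs = np.asarray(freqs, dtype=float)
    freqs = freqs / freqs.sum()
    bases = np.array(list("ACGT"))

    site_mult = np.ones(n_sites)
    if partitions:
        covered = np.zeros(n_sites, dtype=bool)
        for window, mult in partitions:
            idx = [p - 1 for p in window.positions() if p <= n_sites]
            site_mult[idx] = mult
            covered[idx] = True
        inside = site_mult[covered]
        if (~covered).any():
            residual = (n_sites - inside.sum()) / (~covered).sum()
            if residual <= 0:
                raise ValueError("partition multipliers exceed the total rate")
            site_mult[~covered] = residual

    if alpha is not None and n_rate_categories > 1:
        cats = discrete_gamma_rates(alpha, n_rate_categories)
        site_mult = site_mult * cats[rng.integers(n_rate_categories, size=n_sites)]

    V, lam, Vinv = hky_eigensystem(freqs, kappa)

    def transition_rows(t: float, rates: np.ndarray) -> np.ndarray:
        # P for each distinct site rate; rates shape (m,) -> (m, 4, 4)
        el = np.exp(lam[None, :] * (t * rates[:, None]))
        return np.einsum("ik,mk,kj->mij", V, el, Vinv)

    root_states = rng.choice(4, size=n_sites, p=freqs)
    out: dict[str, str] = {}

    def walk(node: TreeNode, states: np.ndarray) -> None:
        for child in node.children:
            uniq, inv = np.unique(site_mult, return_inverse=True)
            P = transition_rows(child.length, uniq)
            probs = P[inv, states, :]  # (n_sites, 4)
            probs = np.clip(probs, 0.0, None)
            probs /= probs.sum(axis=1, keepdims=True)
            u = rng.random(n_sites)
            child_states = (probs.cumsum(axis=1) < u[:, None]).sum(axis=1)
            if child.is_leaf:
                out[child.label] = "".join(bases[child_states])
            walk(child, child_states)

    walk(tree.root, root_states)
    if tree.root.is_leaf:
        out[tree.root.label] = "".join(bases[root_states])
    return out
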