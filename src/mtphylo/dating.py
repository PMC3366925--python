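"""Coalescence-age estimation for mtDNA clades.

Two routes, mirroring standard practice in mtDNA phylogeography:

* the ρ statistic — the (multiplicity-weighted) mean mutational distance
  of a clade's sampled haplotypes to the clade root — with the heuristic
  standard error σ computed over the genealogy's edges,
  σ² = Σ_e l_e (n_e / N)², where l_e is the edge length in mutations and
  n_e the number of sampled leaves below edge e;
* maximum-likelihood branch lengths on a fixed topology under HKY85 with
  discrete-gamma rate variation and partitioned rates (hypervariable
  segments vs. the remainder), the mean root-to-leaf path then being
  converted to expected mutations over the genome.

Mutational distances convert to years through a molecular clock; the
whole-molecule calibration of one mutation every 3,624 years is the
built-in default. A control-region rate (e.g. a purifying-selection
corrected published calibration) must be supplied explicitly.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import dendropy
import numpy as np
from scipy import optimize
from scipy.special import gammainc
from scipy.stats import gamma as gamma_dist

from .variants import (
    MT_LENGTH,
    CircularInterval,
    SiteFilter,
    parse_variant,
)

YEARS_PER_MUTATION_WHOLE_MOLECULE = 3624.0


@dataclass(frozen=True)
class ClockConfig:
    """Mutation-rate calibrations, in years per mutation."""

    years_per_mutation: float = YEARS_PER_MUTATION_WHOLE_MOLECULE
    control_region_rate: float | None = None
    label: str = "whole-molecule"

    def __post_init__(self) -> None:
        if self.years_per_mutation <= 0:
            raise ValueError("years_per_mutation must be positive")
        if self.control_region_rate is not None and self.control_region_rate <= 0:
            raise ValueError("control_region_rate must be positive")

    def rate_for(self, scale: str) -> float:
        if scale == "whole_molecule":
            return self.years_per_mutation
        if scale == "control_region":
            if self.control_region_rate is None:
                raise ValueError(
                    "no control-region rate configured; set "
                    "ClockConfig.control_region_rate explicitly"
                )
            return self.control_region_rate
        raise ValueError(f"unknown clock scale {scale!r}")


@dataclass(frozen=True)
class AgeEstimate:
    rho: float
    sigma: float
    method: str  # "rho" or "ML"
    age_years: float = float("nan")
    age_se_years: float = float("nan")
    clock_label: str = ""
    scale: str = ""

    def __post_init__(self) -> None:
        if self.rho < 0:
            raise ValueError("rho must be non-negative")
        if self.sigma < 0:
            raise ValueError("sigma must be non-negative")


# ---------------------------------------------------------------------------
# genealogy trees


class TreeNode:
    __slots__ = ("label", "length", "children", "multiplicity")

    def __init__(self, label: str = "", length: float = 0.0,
                 children: "list[TreeNode] | None" = None, multiplicity: int = 1):
        self.label = label
        self.length = float(length)
        self.children: list[TreeNode] = children or []
        self.multiplicity = int(multiplicity)
        if self.length < 0:
            raise ValueError("negative edge length")

    @property
    def is_leaf(self) -> bool:
        return not self.children


class GenealogyTree:
    """Rooted genealogy whose edges carry mutation counts (ρ mode) or
    expected substitutions per site (ML mode); leaves may carry a sampled
    multiplicity (identical sequences collapsed into one tip)."""

    def __init__(self, root: TreeNode):
        self.root = root
        if not self.leaves():
            raise ValueError("tree must have at least one leaf")

    def leaves(self) -> list[TreeNode]:
        out = []
        stack = [self.root]
        while stack:
            n = stack.pop()
            if n.is_leaf:
                out.append(n)
            stack.extend(n.children)
        return out

    def edges(self) -> list[TreeNode]:
        """Every non-root node stands for the edge above it."""
        out = []
        stack = list(self.root.children)
        while stack:
            n = stack.pop()
            out.append(n)
            stack.extend(n.children)
        return out

    @property
    def n_samples(self) -> int:
        return sum(l.multiplicity for l in self.leaves())

    @classmethod
    def from_newick(cls, newick: str,
                    multiplicities: Mapping[str, int] | None = None) -> "GenealogyTree":
        dt = dendropy.Tree.get(data=newick, schema="newick")

        def convert(dn) -> TreeNode:
            label = (dn.taxon.label if dn.taxon is not None else dn.label) or ""
            mult = 1
            if multiplicities and label in multiplicities:
                mult = multiplicities[label]
            return TreeNode(
                label=label,
                length=dn.edge.length or 0.0,
                children=[convert(c) for c in dn.child_nodes()],
                multiplicity=mult,
            )

        return cls(convert(dt.seed_node))

    def to_newick(self) -> str:
        def fmt(n: TreeNode) -> str:
            if n.is_leaf:
                return f"{n.label}:{n.length:g}"
            inner = ",".join(fmt(c) for c in n.children)
            lab = n.label or ""
            return f"({inner}){lab}:{n.length:g}"

        inner = ",".join(fmt(c) for c in self.root.children)
        return f"({inner}){self.root.label or ''};"

    def scaled(self, factor: float) -> "GenealogyTree":
        def copy(n: TreeNode) -> TreeNode:
            return TreeNode(n.label, n.length * factor,
                            [copy(c) for c in n.children], n.multiplicity)

        return GenealogyTree(copy(self.root))


def rho_sigma(tree: GenealogyTree) -> AgeEstimate:
    """ρ and its heuristic standard error σ from a rooted genealogy."""
    total_n = tree.n_samples
    rho_sum = 0.0
    var_sum = 0.0

    def walk(node: TreeNode, depth: float) -> int:
        nonlocal rho_sum, var_sum
        if node.is_leaf:
            below = node.multiplicity
        else:
            below = sum(walk(c, depth + c.length) for c in node.children)
        if node is not tree.root:
            var_sum += node.length * (below / total_n) ** 2
        if node.is_leaf:
            rho_sum += node.multiplicity * depth
        return below

    walk(tree.root, 0.0)
    rho = rho_sum / total_n
    return AgeEstimate(rho=rho, sigma=math.sqrt(var_sum), method="rho")


def to_years(est: AgeEstimate, clock: ClockConfig,
             scale: str = "whole_molecule") -> AgeEstimate:
    """Convert a mutational-distance estimate into years."""
    rate = clock.rate_for(scale)
    return replace(
        est,
        age_years=est.rho * rate,
        age_se_years=est.sigma * rate,
        clock_label=clock.label,
        scale=scale,
    )


# ---------------------------------------------------------------------------
# HKY85 + discrete gamma, partitioned, on a fixed topology

DEFAULT_PARTITIONS: tuple[tuple[str, CircularInterval], ...] = (
    ("HVS-I", CircularInterval(16051, 16400)),
    ("HVS-II", CircularInterval(68, 263)),
)  # every other position falls into the "remainder" partition


@dataclass(frozen=True)
class MLModelConfig:
    """Configuration of the partitioned HKY85+Γ fit.

    ``partitions`` lists named position windows; all positions not in any
    window form the implicit remainder partition. Rate multipliers are
    per-partition, normalized to a site-weighted mean of one; ``kappa``
    (transition/transversion) and the gamma shape ``alpha`` are shared.
    """

    n_rate_categories: int = 32
    partitions: tuple[tuple[str, CircularInterval], ...] = DEFAULT_PARTITIONS
    excluded: SiteFilter = field(default_factory=SiteFilter)
    equal_base_frequencies: bool = False
    fix_kappa: float | None = None
    fix_alpha: float | None = None
    kappa_init: float = 10.0
    alpha_init: float = 0.5

    def __post_init__(self) -> None:
        if self.n_rate_categories < 1:
            raise ValueError("need at least one rate category")


def discrete_gamma_rates(alpha: float, k: int) -> np.ndarray:
    """Equal-probability discrete gamma categories, each represented by
    its category mean (the classic discretization)."""
    if k == 1:
        return np.ones(1)
    bounds = gamma_dist.ppf(np.arange(1, k) / k, a=alpha, scale=1.0 / alpha)
    upper = np.concatenate([bounds, [np.inf]])
    lower = np.concatenate([[0.0], bounds])
    # E[X; X in (l,u)] for Gamma(alpha, rate alpha) is the regularized
    # incomplete gamma of shape alpha+1 at alpha*x; mean of category i is
    # k times the restricted expectation.
    cdf_hi = gammainc(alpha + 1, alpha * np.where(np.isinf(upper), 1e12, upper))
    cdf_hi[np.isinf(upper)] = 1.0
    cdf_lo = gammainc(alpha + 1, alpha * lower)
    rates = k * (cdf_hi - cdf_lo)
    return rates / rates.mean()


def hky_eigensystem(freqs: np.ndarray, kappa: float):
    """Eigendecomposition of the rate-1-normalized HKY85 generator.

    Returns (V, lam, Vinv) with P(t) = V @ diag(exp(lam t)) @ Vinv.
    Base order is A, C, G, T.
    """
    pi = np.asarray(freqs, dtype=float)
    if pi.shape != (4,) or (pi <= 0).any():
        raise ValueError("base frequencies must be four positive numbers")
    pi = pi / pi.sum()
    A, C, G, T = range(4)
    Q = np.zeros((4, 4))
    for i, j in itertools.permutations(range(4), 2):
        transition = (i, j) in ((A, G), (G, A), (C, T), (T, C))
        Q[i, j] = (kappa if transition else 1.0) * pi[j]
    np.fill_diagonal(Q, -Q.sum(axis=1))
    mu = -(pi * np.diag(Q)).sum()
    Q /= mu
    # reversible: symmetrize with sqrt(pi) and use a symmetric eigensolver
    s = np.sqrt(pi)
    B = (Q * s[:, None]) / s[None, :]
    lam, U = np.linalg.eigh((B + B.T) / 2)
    V = U / s[:, None]
    Vinv = U.T * s[None, :]
    return V, lam, Vinv


_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}


@dataclass
class MLFitResult:
    """Outcome of :meth:`HKYGammaModel.fit`."""

    tree: GenealogyTree              # branch lengths in substitutions/site
    kappa: float
    alpha: float
    rate_multipliers: dict[str, float]
    log_likelihood: float
    converged: bool
    n_sites: dict[str, int]

    def summary(self) -> str:
        lines = [
            "HKY85+Gamma ML fit",
            f"  log-likelihood: {self.log_likelihood:.4f}",
            f"  kappa: {self.kappa:.3f}",
            f"  gamma shape alpha: {self.alpha:.3f}",
            f"  converged: {self.converged}",
        ]
        for name, r in self.rate_multipliers.items():
            lines.append(f"  rate[{name}]: {r:.3f} ({self.n_sites[name]} sites)")
        return "\n".join(lines)


class HKYGammaModel:
    """Maximum-likelihood branch lengths on a fixed topology.

    ``alignment`` maps leaf labels to equal-length sequences in reference
    coordinates (column i = position i+1). Columns containing gaps, N, or
    an excluded position are dropped (indels ignored, as usual).
    """

    def __init__(self, alignment: Mapping[str, str], topology: GenealogyTree,
                 config: MLModelConfig | None = None):
        self.config = config or MLModelConfig()
        self.tree = topology
        self.leaves = [l for l in topology.leaves()]
        labels = [l.label for l in self.leaves]
        if set(labels) - set(alignment):
            missing = sorted(set(labels) - set(alignment))
            raise ValueError(f"alignment missing sequences for leaves: {missing}")
        lengths = {len(alignment[l]) for l in labels}
        if len(lengths) != 1:
            raise ValueError("sequences must be aligned to equal length")
        (self.L,) = lengths
        self._prepare_partitions({l: alignment[l].upper() for l in labels})
        self._edges = self.tree.edges()

    # -- data preparation ---------------------------------------------------

    def _excluded_positions(self) -> set[int]:
        excl = set()
        for tok in self.config.excluded.excluded_positions:
            excl.add(parse_variant(tok).position)
        return excl

    def _prepare_partitions(self, seqs: dict[str, str]) -> None:
        excl = self._excluded_positions()
        part_names = [name for name, _ in self.config.partitions] + ["remainder"]
        cols_by_part: dict[str, list[int]] = {n: [] for n in part_names}
        for col in range(self.L):
            pos = col + 1
            if pos in excl:
                continue
            states = [seqs[l][col] for l in seqs]
            if any(b not in _BASE_INDEX for b in states):
                continue  # gap or ambiguous column: ignored
            for name, window in self.config.partitions:
                if pos in window:
                    cols_by_part[name].append(col)
                    break
            else:
                cols_by_part["remainder"].append(col)

        self.partitions: list[dict] = []
        order = list(seqs)
        self.leaf_order = order
        for name in part_names:
            cols = cols_by_part[name]
            if not cols:
                continue
            data = np.array(
                [[_BASE_INDEX[seqs[l][c]] for c in cols] for l in order],
                dtype=np.int8,
            )
            patterns, counts = np.unique(data, axis=1, return_counts=True)
            if self.config.equal_base_frequencies:
                freqs = np.full(4, 0.25)
            else:
                freqs = np.bincount(data.ravel(), minlength=4).astype(float)
                if (freqs == 0).any():
                    freqs = freqs + 1.0  # guard against absent bases
                freqs /= freqs.sum()
            self.partitions.append(
                {"name": name, "patterns": patterns, "counts": counts,
                 "freqs": freqs, "n_sites": len(cols)}
            )
        if not self.partitions:
            raise ValueError("no usable alignment columns after filtering")

    # -- likelihood ---------------------------------------------------------

    def log_likelihood(self, branch_lengths: Mapping[int, float] | np.ndarray,
                       kappa: float, alpha: float,
                       multipliers: Sequence[float] | None = None) -> float:
        """Pruning-algorithm log-likelihood at the given parameters.

        ``branch_lengths`` follows the order of ``tree.edges()``;
        ``multipliers`` the order of the used partitions (defaults to 1).
        """
        bl = np.asarray(branch_lengths, dtype=float)
        if multipliers is None:
            multipliers = np.ones(len(self.partitions))
        k = self.config.n_rate_categories
        g = discrete_gamma_rates(alpha, k)
        total = 0.0
        for part, r in zip(self.partitions, multipliers):
            V, lam, Vinv = hky_eigensystem(part["freqs"], kappa)
            npat = part["patterns"].shape[1]
            site_lik = np.zeros(npat)
            for gc in g:
                P = [
                    V @ (np.exp(lam * t * r * gc)[:, None] * Vinv)
                    for t in bl
                ]
                lik = self._prune(part["patterns"], P)
                site_lik += (part["freqs"] @ lik) / k
            if (site_lik <= 0).any() or not np.isfinite(site_lik).all():
                return -np.inf
            total += float(part["counts"] @ np.log(site_lik))
        return total

    def _prune(self, patterns: np.ndarray, P: list[np.ndarray]) -> np.ndarray:
        """Conditional likelihoods at the root, shape (4, n_patterns)."""
        leaf_row = {lab: i for i, lab in enumerate(self.leaf_order)}
        edge_index = {id(n): i for i, n in enumerate(self._edges)}
        npat = patterns.shape[1]
        eye = np.eye(4)

        def rec(node: TreeNode) -> np.ndarray:
            if node.is_leaf:
                states = patterns[leaf_row[node.label]]
                return eye[:, states]  # (4, npat) indicator columns
            out = np.ones((4, npat))
            for child in node.children:
                out *= P[edge_index[id(child)]] @ rec(child)
            return out

        return rec(self.tree.root)

    # -- fitting ------------------------------------------------------------

    def fit(self, maxiter: int = 500) -> MLFitResult:
        cfg = self.config
        n_edges = len(self._edges)
        npart = len(self.partitions)
        weights = np.array([p["n_sites"] for p in self.partitions], dtype=float)
        weights /= weights.sum()

        free_kappa = cfg.fix_kappa is None
        free_alpha = cfg.fix_alpha is None and cfg.n_rate_categories > 1

        def unpack(theta: np.ndarray):
            i = 0
            bl = np.exp(theta[i:i + n_edges]); i += n_edges
            kappa = np.exp(theta[i]) if free_kappa else cfg.fix_kappa
            i += free_kappa
            alpha = np.exp(theta[i]) if free_alpha else (cfg.fix_alpha or 1.0)
            i += free_alpha
            if npart > 1:
                s = np.concatenate([[1.0], np.exp(theta[i:i + npart - 1])])
                mult = s / (weights @ s)
                scale = 1.0  # gauge: multipliers normalized, lengths absolute
            else:
                mult = np.ones(1)
            return bl, float(kappa), float(alpha), mult

        def objective(theta: np.ndarray) -> float:
            bl, kappa, alpha, mult = unpack(theta)
            ll = self.log_likelihood(bl, kappa, alpha, mult)
            return -ll if np.isfinite(ll) else 1e12

        theta0 = np.concatenate([
            np.full(n_edges, math.log(1e-4)),
            [math.log(cfg.kappa_init)] if free_kappa else [],
            [math.log(cfg.alpha_init)] if free_alpha else [],
            np.zeros(max(npart - 1, 0)),
        ])
        bounds = (
            [(math.log(1e-9), math.log(1.0))] * n_edges
            + ([(math.log(0.05), math.log(500.0))] if free_kappa else [])
            + ([(math.log(0.02), math.log(50.0))] if free_alpha else [])
            + [(-6.0, 6.0)] * max(npart - 1, 0)
        )
        res = optimize.minimize(
            objective, theta0, method="L-BFGS-B", bounds=bounds,
            options={"maxiter": maxiter, "ftol": 1e-12, "gtol": 1e-7},
        )
        bl, kappa, alpha, mult = unpack(res.x)

        fitted = self.tree.scaled(1.0)
        for node, t in zip(fitted.edges(), bl):
            node.length = float(t)
        return MLFitResult(
            tree=fitted,
            kappa=kappa,
            alpha=alpha if free_alpha or cfg.fix_alpha else float("nan"),
            rate_multipliers={p["name"]: float(m)
                              for p, m in zip(self.partitions, mult)},
            log_likelihood=float(-res.fun),
            converged=bool(res.success),
            n_sites={p["name"]: int(p["n_sites"]) for p in self.partitions},
        )


def ml_branch_lengths(alignment: Mapping[str, str], topology: GenealogyTree,
                      config: MLModelConfig | None = None) -> MLFitResult:
    """Functional wrapper over :class:`HKYGammaModel`."""
    return HKYGammaModel(alignment, topology, config).fit()


def ml_age(tree: GenealogyTree, clock: ClockConfig,
           genome_length: int = MT_LENGTH) -> AgeEstimate:
    """Age from ML branch lengths: mean root-to-leaf distance (subs/site)
    times the genome length gives expected mutations; the clock converts
    mutations to years."""
    total = 0.0
    n = 0

    def walk(node: TreeNode, depth: float) -> None:
        nonlocal total, n
        if node.is_leaf:
            total += node.multiplicity * depth
            n += node.multiplicity
        for c in node.children:
            walk(c, depth + c.length)

    walk(tree.root, 0.0)
    mean_subs = total / n
    mutations = mean_subs * genome_length
    return AgeEstimate(
        rho=mutations, sigma=0.0, method="ML",
        age_years=mutations * clock.years_per_mutation,
        clock_label=clock.label, scale="whole_molecule",
    )
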