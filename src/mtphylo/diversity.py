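"""Sequence-diversity summaries over control-region haplotypes.

Statistics follow the standard population-genetic definitions computed on
rCRS-relative variant sets rather than raw alignments: the compared site
count L is the sequenced window minus gap-bearing (deleted), ambiguous
(heteroplasmic) and explicitly excluded positions; substitutions at the
remaining sites drive S, k and π.

* k  — mean number of pairwise differences,
* π  — nucleotide diversity per site, k / L,
* Hd — haplotype (gene) diversity, n(1 − Σ pᵢ²)/(n − 1).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from .haplotypes import Haplotype
from .variants import (
    DELETION,
    HETEROPLASMY,
    SiteFilter,
    parse_variant,
    serialize_variant,
)


@dataclass(frozen=True)
class DiversityStats:
    n: int
    L: int
    S: int
    invariable: int
    pi: float
    k: float
    Hd: float
    n_haplotypes: int


def diversity_stats(
    haps: Sequence[Haplotype],
    site_filter: SiteFilter | None = None,
    profile: str = "stats",
) -> DiversityStats:
    """Cohort diversity statistics.

    k is the mean pairwise mutational difference under the stats filter
    (substitutions only); π divides k by the number of compared sites.
    """
    n = len(haps)
    if n < 2:
        raise ValueError("diversity statistics require at least two samples")
    site_filter = site_filter or SiteFilter()
    window = haps[0].covered_range
    for h in haps:
        if h.covered_range != window:
            raise ValueError("all haplotypes must share a covered range")

    filtered = [site_filter.apply(h.variants, profile=profile) for h in haps]

    # compared sites: window minus deleted / heteroplasmic / excluded positions
    dropped: set[int] = set()
    for h in haps:
        for v in h.variants:
            if v.kind == DELETION:
                dropped.update(range(v.position, v.span_end + 1))
            elif v.kind == HETEROPLASMY:
                dropped.add(v.position)
    for tok in site_filter.excluded_positions:
        dropped.add(parse_variant(tok).position)
    L = sum(1 for p in window.positions() if p not in dropped)

    # k via per-variant sample counts: sum over variants of c(n-c) pairs
    counts = Counter()
    for fs in filtered:
        for v in fs:
            counts[serialize_variant(v)] += 1
    pairs = n * (n - 1) / 2
    k = sum(c * (n - c) for c in counts.values()) / pairs

    seg_sites = {parse_variant(t).position for t in counts}
    S = len(seg_sites)

    profiles = Counter(frozenset(fs) for fs in filtered)
    sum_p2 = sum((c / n) ** 2 for c in profiles.values())
    Hd = n * (1.0 - sum_p2) / (n - 1)

    return DiversityStats(
        n=n, L=L, S=S, invariable=L - S, pi=k / L, k=k,
        Hd=Hd, n_haplotypes=len(profiles),
    )


def haplotype_census(
    haps: Sequence[Haplotype],
    site_filter: SiteFilter | None = None,
    profile: str = "stats",
) -> tuple[int, dict[int, int]]:
    """Distinct haplotype count and multiplicity spectrum.

    The spectrum maps multiplicity -> number of haplotypes observed that
    many times, e.g. ``{3: 1, 2: 1, 1: 1}`` for 3+2+1 samples.
    """
    if not haps:
        return 0, {}
    site_filter = site_filter or SiteFilter()
    profiles = Counter(
        frozenset(site_filter.apply(h.variants, profile=profile)) for h in haps
    )
    spectrum = Counter(profiles.values())
    return len(profiles), dict(spectrum)


def diversity_report(
    haps: Sequence[Haplotype],
    site_filter: SiteFilter | None = None,
    by_region: bool = True,
) -> pd.DataFrame:
    """Cohort-wide (and optionally per-region) diversity table."""
    rows = {"all": diversity_stats(haps, site_filter)}
    if by_region:
        regions = sorted({h.region for h in haps if h.region})
        for r in regions:
            sub = [h for h in haps if h.region == r]
            if len(sub) >= 2:
                rows[r] = diversity_stats(sub, site_filter)
    return pd.DataFrame({k: vars(v) for k, v in rows.items()}).T
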