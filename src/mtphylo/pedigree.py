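"""Genealogical metadata: TMA filtering and kin deduplication.

Each sample carries the origin of its terminal maternal ancestor (TMA) —
the last known forebear on the strictly maternal line — and, where an
external genealogy search identified maternally related samples, a
relatedness cluster. Cohort-level analyses keep autochthonous samples
and exactly one member per extended family.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd


@dataclass(frozen=True)
class PedigreeRecord:
    sample_id: str
    maternal_generations: int = 0
    tma_origin: str = ""
    relatedness_cluster: str | None = None

    def __post_init__(self) -> None:
        if self.maternal_generations < 0:
            raise ValueError("maternal_generations must be >= 0")


def clusters_from_records(records: Sequence[PedigreeRecord]) -> list[set[str]]:
    """Group sample ids by their relatedness_cluster labels."""
    by_label: dict[str, set[str]] = {}
    for r in records:
        if r.relatedness_cluster:
            by_label.setdefault(r.relatedness_cluster, set()).add(r.sample_id)
    return [members for _, members in sorted(by_label.items()) if len(members) > 1]


def dedup_related(
    records: Sequence[PedigreeRecord],
    clusters: Iterable[set[str]],
) -> tuple[list[PedigreeRecord], pd.DataFrame]:
    """Retain one member per relatedness cluster.

    The retained member is the lexicographically smallest sample id — a
    deterministic stand-in for the study's unstated choice. Returns the
    retained records and a removal log (sample_id, cluster).
    """
    clusters = [set(c) for c in clusters]
    seen: set[str] = set()
    for c in clusters:
        if seen & c:
            raise ValueError(f"overlapping relatedness clusters: {sorted(seen & c)}")
        seen |= c
    drop: dict[str, int] = {}
    for i, c in enumerate(clusters):
        keep = min(c)
        for s in c:
            if s != keep:
                drop[s] = i
    retained = [r for r in records if r.sample_id not in drop]
    log = pd.DataFrame(
        sorted(drop.items()), columns=["sample_id", "cluster"]
    )
    return retained, log


def filter_by_tma(
    records: Sequence[PedigreeRecord],
    keep_origin: str = "Panama",
) -> tuple[list[PedigreeRecord], dict[str, int]]:
    """Keep samples whose TMA origin matches; report exclusions by origin."""
    kept = [r for r in records if r.tma_origin == keep_origin]
    excluded: dict[str, int] = {}
    for r in records:
        if r.tma_origin != keep_origin:
            excluded[r.tma_origin] = excluded.get(r.tma_origin, 0) + 1
    return kept, excluded


def records_from_metadata(metadata: pd.DataFrame) -> list[PedigreeRecord]:
    """Build pedigree records from a metadata table (sample_id, tma_origin,
    generations, cluster_id columns; missing columns default)."""
    out = []
    for row in metadata.itertuples(index=False):
        out.append(
            PedigreeRecord(
                sample_id=row.sample_id,
                maternal_generations=int(getattr(row, "generations", 0) or 0),
                tma_origin=getattr(row, "tma_origin", "") or "",
                relatedness_cluster=(getattr(row, "cluster_id", "") or None),
            )
        )
    return out
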