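"""Haplotypes: per-sample variant sets, mutation distances, variant calling.

A haplotype is the set of rCRS-relative variants observed for one sample
over a declared sequenced window (default np 16000–580, the 1150-bp
control-region read wrapping the origin), plus collection metadata.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import edlib
import pandas as pd
from Bio import SeqIO

from .reference import RefSequence
from .variants import (
    DEFAULT_RANGE,
    DELETION,
    HETEROPLASMY,
    INSERTION,
    NETWORK_FILTER,
    TRANSITION,
    TRANSVERSION,
    CircularInterval,
    SiteFilter,
    Variant,
    parse_variants,
    serialize_variants,
)

_TRANSITION_PARTNER = {"A": "G", "G": "A", "C": "T", "T": "C"}
_AMBIGUITY = set("RYSWKMBDHV")


@dataclass(frozen=True)
class Haplotype:
    """One sample's variant set over its sequenced window."""

    sample_id: str
    variants: frozenset[Variant]
    covered_range: CircularInterval = DEFAULT_RANGE
    region: str = ""
    tma_origin: str = ""
    haplogroup_call: str | None = None

    def __post_init__(self) -> None:
        slots = set()
        for v in self.variants:
            if not self.covered_range.contains_variant(v):
                raise ValueError(
                    f"{self.sample_id}: variant {v} outside covered range "
                    f"{self.covered_range.start}-{self.covered_range.end}"
                )
            if v.slot in slots:
                raise ValueError(f"{self.sample_id}: duplicate variant slot {v.slot}")
            slots.add(v.slot)

    def restricted(self, window: CircularInterval) -> frozenset[Variant]:
        return frozenset(v for v in self.variants if window.contains_variant(v))


def haplotype_distance(
    a: Haplotype,
    b: Haplotype,
    site_filter: SiteFilter = NETWORK_FILTER,
    profile: str = "network",
) -> int:
    """Number of mutational differences between two haplotypes.

    The symmetric difference of the two filtered variant sets, restricted
    to the shared covered range. Multi-base deletions count as one
    character. See :meth:`SiteFilter.apply` for the profiles.
    """
    if a.covered_range == b.covered_range:
        shared = a.covered_range
    else:
        if not a.covered_range.overlaps(b.covered_range):
            raise ValueError(
                f"disjoint covered ranges for {a.sample_id} and {b.sample_id}"
            )
        shared = _shared_interval(a.covered_range, b.covered_range)
    fa = site_filter.apply(
        (v for v in a.variants if shared.contains_variant(v)), profile)
    fb = site_filter.apply(
        (v for v in b.variants if shared.contains_variant(v)), profile)
    return len(fa ^ fb)


def _shared_interval(x: CircularInterval, y: CircularInterval) -> CircularInterval:
    # containment fast paths cover the practical cases (control region vs
    # whole genome); the general circular intersection falls back to a
    # position-set bound.
    if all(p in y for p in (x.start, x.end)) and not (x.wraps and not y.wraps):
        return x
    if all(p in x for p in (y.start, y.end)) and not (y.wraps and not x.wraps):
        return y
    if x.start in y:
        return CircularInterval(x.start, y.end)
    return CircularInterval(y.start, x.end)


# ---------------------------------------------------------------------------
# variant calling from sequence


def apply_variants(ref: RefSequence, variants: Iterable[Variant]) -> str:
    """Materialize a full-length sequence carrying the given variants.

    Transitions flip to the transition partner of the reference base;
    reversion-flagged entries are reference state and leave the sequence
    unchanged. Used by the simulator and in round-trip tests.
    """
    cols: list[str] = list(ref.bases)
    inserts: dict[int, list[tuple[int, str]]] = {}
    for v in variants:
        if v.reversion:
            continue
        if v.kind == TRANSITION:
            cols[v.position - 1] = _TRANSITION_PARTNER[ref.base(v.position)]
        elif v.kind in (TRANSVERSION, HETEROPLASMY):
            cols[v.position - 1] = v.derived_base
        elif v.kind == DELETION:
            for p in range(v.position, v.span_end + 1):
                cols[p - 1] = ""
        elif v.kind == INSERTION:
            inserts.setdefault(v.position, []).append((v.insert_index, v.derived_base))
    for pos, entries in inserts.items():
        cols[pos - 1] = cols[pos - 1] + "".join(b for _, b in sorted(entries))
    return "".join(cols)


def call_variants(
    query: str,
    ref: RefSequence,
    aligned: bool = False,
    max_divergence: float = 0.05,
) -> frozenset[Variant]:
    """Call rCRS-relative variants from a (near-identical) query sequence.

    With ``aligned=True`` the query must be position-aligned to the
    reference (equal length, deletions as ``-``; insertions are not
    representable this way). Otherwise a global alignment is computed and
    indels are normalized to their 3'-most placement in repeats, the
    standard mtDNA naming convention.
    """
    query = query.upper()
    if aligned:
        if len(query) != len(ref):
            raise ValueError("aligned query must match reference length")
        qaln, raln = query, ref.bases
    else:
        res = edlib.align(query.replace("-", ""), ref.bases, task="path", mode="NW")
        if res["editDistance"] / len(ref) > max_divergence:
            raise ValueError(
                "query too divergent from reference for confident variant "
                "calling; supply a pre-aligned sequence"
            )
        qaln, raln = _expand_cigar(query.replace("-", ""), ref.bases, res["cigar"])

    out: set[Variant] = set()
    rpos = 0  # last consumed reference position
    i = 0
    n = len(qaln)
    while i < n:
        qb, rb = qaln[i], raln[i]
        if rb == "-":  # insertion run relative to the reference
            j = i
            while j < n and raln[j] == "-":
                j += 1
            ins = qaln[i:j].replace("-", "")
            pos, ins = _shift_insertion_3prime(ref, rpos, ins)
            for k, b in enumerate(ins, start=1):
                out.add(Variant(pos, INSERTION, derived_base=b, insert_index=k))
            i = j
            continue
        rpos += 1
        if qb == "-":  # deletion run
            j = i
            end = rpos
            while j + 1 < n and qaln[j + 1] == "-" and raln[j + 1] != "-":
                j += 1
                end += 1
            s, e = _shift_deletion_3prime(ref, rpos, end)
            out.add(Variant(s, DELETION, span_end=e))
            rpos = end
            i = j + 1
            continue
        if qb != rb and qb != "N" and rb != "N":
            if qb in _AMBIGUITY:
                out.add(Variant(rpos, HETEROPLASMY, derived_base=qb))
            elif _TRANSITION_PARTNER.get(rb) == qb:
                out.add(Variant(rpos, TRANSITION))
            else:
                out.add(Variant(rpos, TRANSVERSION, derived_base=qb))
        i += 1
    return frozenset(out)


def _expand_cigar(query: str, ref: str, cigar: str) -> tuple[str, str]:
    """Aligned strings from an edlib extended CIGAR (=/X/I/D)."""
    import re as _re

    q, r = [], []
    qi = ri = 0
    for count, op in _re.findall(r"(\d+)([=XIDM])", cigar):
        k = int(count)
        if op in "=XM":
            q.append(query[qi:qi + k]); r.append(ref[ri:ri + k])
            qi += k; ri += k
        elif op == "I":  # in query, absent from reference
            q.append(query[qi:qi + k]); r.append("-" * k)
            qi += k
        else:  # D: absent from query
            q.append("-" * k); r.append(ref[ri:ri + k])
            ri += k
    return "".join(q), "".join(r)


def _shift_deletion_3prime(ref: RefSequence, start: int, end: int) -> tuple[int, int]:
    """Slide a deletion window right while the repeat structure allows."""
    while end < len(ref) and ref.base(end + 1) == ref.base(start):
        start += 1
        end += 1
    return start, end


def _shift_insertion_3prime(ref: RefSequence, after: int, ins: str) -> tuple[int, str]:
    """Slide an insertion right; returns (anchor position, inserted bases)."""
    if after == 0:
        return 1, ins  # insertion before position 1: anchor at 1 (rare)
    while after < len(ref) and ins and ref.base(after + 1) == ins[0]:
        after += 1
        ins = ins[1:] + ins[0]
    return after, ins


# ---------------------------------------------------------------------------
# table I/O (matches the structure of a per-sample supplementary table:
# sample id, collection region, TMA origin, space-separated variant tokens)

HAPLOTYPE_COLUMNS = ["sample_id", "region", "tma_origin", "variants", "haplogroup"]


def read_haplotype_table(
    path, covered_range: CircularInterval = DEFAULT_RANGE
) -> list[Haplotype]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = {"sample_id", "variants"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"haplotype table missing columns: {sorted(missing)}")
    haps = []
    for row in df.itertuples(index=False):
        haps.append(
            Haplotype(
                sample_id=row.sample_id,
                variants=parse_variants(row.variants),
                covered_range=covered_range,
                region=getattr(row, "region", ""),
                tma_origin=getattr(row, "tma_origin", ""),
                haplogroup_call=getattr(row, "haplogroup", "") or None,
            )
        )
    return haps


def write_haplotype_table(haps: Sequence[Haplotype], path) -> None:
    df = pd.DataFrame(
        {
            "sample_id": [h.sample_id for h in haps],
            "region": [h.region for h in haps],
            "tma_origin": [h.tma_origin for h in haps],
            "variants": [serialize_variants(h.variants) for h in haps],
            "haplogroup": [h.haplogroup_call or "" for h in haps],
        }
    )
    df.to_csv(path, sep="\t", index=False)


def read_fasta_haplotypes(path, ref: RefSequence) -> list[Haplotype]:
    """Call variants for every record of a FASTA of complete genomes."""
    haps = []
    for rec in SeqIO.parse(str(path), "fasta"):
        haps.append(
            Haplotype(
                sample_id=rec.id,
                variants=call_variants(str(rec.seq), ref),
                covered_range=CircularInterval(1, len(ref)),
            )
        )
    return haps
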