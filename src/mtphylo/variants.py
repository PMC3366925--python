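"""rCRS-relative variant notation: data model, parser and serializer.

Human mtDNA variation is conventionally reported as differences from the
revised Cambridge Reference Sequence (rCRS), a circular molecule of
16,569 bp numbered 1..16569. The notation used throughout the
control-region literature is terse:

``73``        transition at position 73 (base implied by the reference)
``16182C``    transversion to C at 16182
``152Y``      heteroplasmy (IUPAC ambiguity code) at 152
``106-111d``  deletion of positions 106..111 (also printed with en-dash)
``309.1C``    insertion of C, first inserted base after position 309
``64@``       back mutation (reversion) at 64, restoring the upstream state

This module owns the grammar, the circular-coordinate arithmetic, and the
site filters used when mutations are counted.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, replace
from typing import Iterable, Iterator

MT_LENGTH = 16569

_PURINES = {"A", "G"}
_PYRIMIDINES = {"C", "T"}
_AMBIGUITY = set("RYSWKMBDHVN")

#: variant kinds
TRANSITION = "transition"
TRANSVERSION = "transversion"
INSERTION = "insertion"
DELETION = "deletion"
HETEROPLASMY = "heteroplasmy"


class VariantParseError(ValueError):
    """Raised for tokens that do not match the notation grammar."""


@dataclass(frozen=True, order=True)
class Variant:
    """One rCRS-relative mutation event.

    Parameters
    ----------
    position : int
        1-based rCRS coordinate (start of the span for deletions).
    kind : str
        One of ``transition``, ``transversion``, ``insertion``,
        ``deletion``, ``heteroplasmy``.
    span_end : int
        End coordinate for multi-base deletions; equals ``position``
        otherwise.
    derived_base : str
        Derived nucleotide for transversions/insertions, IUPAC code for
        heteroplasmies; empty for transitions and deletions.
    insert_index : int
        Ordinal of an inserted base (the ``1`` in ``309.1C``); 0 unless
        ``kind == "insertion"``.
    reversion : bool
        True when the token carries the ``@`` suffix (back mutation).
    """

    position: int
    kind: str = TRANSITION
    span_end: int = 0
    derived_base: str = ""
    insert_index: int = 0
    reversion: bool = False

    def __post_init__(self) -> None:
        if not 1 <= self.position <= MT_LENGTH:
            raise VariantParseError(
                f"position {self.position} outside 1..{MT_LENGTH}"
            )
        if self.span_end == 0:
            object.__setattr__(self, "span_end", self.position)
        if self.span_end < self.position:
            raise VariantParseError(
                f"span end {self.span_end} before start {self.position}"
            )
        if (self.insert_index >= 1) != (self.kind == INSERTION):
            raise VariantParseError("insert_index >= 1 iff kind=insertion")
        if (self.derived_base == "") != (self.kind in (TRANSITION, DELETION)):
            raise VariantParseError(
                "derived_base must be empty exactly for transitions/deletions"
            )

    # (position, kind, insert_index) identifies a variant slot within a
    # haplotype; two events may not share a slot.
    @property
    def slot(self) -> tuple[int, str, int]:
        return (self.position, self.kind, self.insert_index)

    @property
    def is_indel(self) -> bool:
        return self.kind in (INSERTION, DELETION)

    @property
    def is_substitution(self) -> bool:
        return self.kind in (TRANSITION, TRANSVERSION)

    def without_reversion(self) -> "Variant":
        return replace(self, reversion=False) if self.reversion else self

    def __str__(self) -> str:  # pragma: no cover - delegates
        return serialize_variant(self)


_TOKEN_RE = re.compile(
    r"""^
    (?P<pos>\d{1,5})
    (?:
        [\-–](?P<end>\d{1,5})d        # span deletion, hyphen or en-dash
      | (?P<sd>d)                           # single-position deletion
      | \.(?P<idx>\d+)(?P<insbase>[ACGT])   # insertion
      | (?P<base>[ACGTRYSWKMBDHVN])         # transversion / heteroplasmy
    )?
    (?P<rev>@)?
    $""",
    re.VERBOSE,
)


def parse_variant(token: str) -> Variant:
    """Parse one notation token into a :class:`Variant`.

    Accepts hyphen or en-dash in deletion spans; the canonical
    serialization uses a hyphen.
    """
    m = _TOKEN_RE.match(token.strip())
    if m is None:
        raise VariantParseError(f"malformed variant token: {token!r}")
    pos = int(m.group("pos"))
    if not 1 <= pos <= MT_LENGTH:
        raise VariantParseError(f"position {pos} outside 1..{MT_LENGTH} in {token!r}")
    rev = m.group("rev") is not None
    if m.group("end") is not None or m.group("sd") is not None:
        end = int(m.group("end")) if m.group("end") is not None else pos
        if not 1 <= end <= MT_LENGTH:
            raise VariantParseError(f"span end {end} outside 1..{MT_LENGTH}")
        return Variant(pos, DELETION, span_end=end, reversion=rev)
    if m.group("idx") is not None:
        idx = int(m.group("idx"))
        if idx < 1:
            raise VariantParseError(f"insertion index must be >= 1 in {token!r}")
        return Variant(pos, INSERTION, derived_base=m.group("insbase"),
                       insert_index=idx, reversion=rev)
    base = m.group("base")
    if base is None:
        return Variant(pos, TRANSITION, reversion=rev)
    if base in _AMBIGUITY:
        return Variant(pos, HETEROPLASMY, derived_base=base, reversion=rev)
    return Variant(pos, TRANSVERSION, derived_base=base, reversion=rev)


def serialize_variant(v: Variant) -> str:
    """Canonical token for a variant; inverse of :func:`parse_variant`."""
    if v.kind == DELETION:
        core = f"{v.position}d" if v.span_end == v.position else f"{v.position}-{v.span_end}d"
    elif v.kind == INSERTION:
        core = f"{v.position}.{v.insert_index}{v.derived_base}"
    elif v.kind == TRANSITION:
        core = str(v.position)
    else:  # transversion, heteroplasmy
        core = f"{v.position}{v.derived_base}"
    return core + "@" if v.reversion else core


def parse_variants(text: str) -> frozenset[Variant]:
    """Parse a whitespace- or comma-separated list of tokens."""
    out = set()
    for tok in re.split(r"[,\s]+", text.strip()):
        if tok:
            out.add(parse_variant(tok))
    return frozenset(out)


def serialize_variants(variants: Iterable[Variant]) -> str:
    """Space-separated canonical tokens in control-region reading order.

    Sites are conventionally listed from 16024 onward across the origin,
    i.e. 16xxx positions first, then low positions — matching how
    control-region motifs are printed when the sequenced window wraps the
    origin. Here we sort by plain coordinate, HVS-I block first.
    """
    def keyfun(v: Variant):
        wrapped = 0 if v.position >= 16000 else 1
        return (wrapped, v.position, v.kind, v.insert_index)

    return " ".join(serialize_variant(v) for v in sorted(variants, key=keyfun))


@dataclass(frozen=True)
class CircularInterval:
    """Closed interval on the circular rCRS coordinate system.

    ``start > end`` denotes an interval wrapping the origin, e.g. the
    default sequenced window 16000..580.
    """

    start: int
    end: int

    def __post_init__(self) -> None:
        for p in (self.start, self.end):
            if not 1 <= p <= MT_LENGTH:
                raise ValueError(f"coordinate {p} outside 1..{MT_LENGTH}")

    @property
    def wraps(self) -> bool:
        return self.start > self.end

    def __contains__(self, position: int) -> bool:
        if self.wraps:
            return position >= self.start or position <= self.end
        return self.start <= position <= self.end

    def contains_variant(self, v: Variant) -> bool:
        return v.position in self and v.span_end in self

    def __len__(self) -> int:
        if self.wraps:
            return (MT_LENGTH - self.start + 1) + self.end
        return self.end - self.start + 1

    def positions(self) -> Iterator[int]:
        if self.wraps:
            yield from range(self.start, MT_LENGTH + 1)
            yield from range(1, self.end + 1)
        else:
            yield from range(self.start, self.end + 1)

    def overlaps(self, other: "CircularInterval") -> bool:
        return any(p in other for p in (self.start, self.end)) or \
            any(p in self for p in (other.start, other.end))

    def intersection_positions(self, other: "CircularInterval") -> set[int]:
        return {p for p in self.positions() if p in other}


#: default sequenced window: 1150 bp covering the whole control region
DEFAULT_RANGE = CircularInterval(16000, 580)
WHOLE_GENOME = CircularInterval(1, MT_LENGTH)

# Sites conventionally excluded from mutation counting: the unstable
# 16182C/16183C/16194C transversions tied to the 16189 poly-C and the
# hypermutable 16519.
DEFAULT_EXCLUDED = ("16182C", "16183C", "16194C", "16519")
# Length variation in the two C-stretches is disregarded.
DEFAULT_CSTRETCH = (CircularInterval(303, 315), CircularInterval(16184, 16193))

#: the 6-bp "Huetar" deletion, retained even under the network filter
HUETAR_DELETION = Variant(106, DELETION, span_end=111)


@dataclass(frozen=True)
class SiteFilter:
    """Which variants enter mutation counts.

    ``excluded_positions`` holds notation tokens: a bare position token
    (``16519``) excludes every variant at that position, a token with a
    base (``16182C``) excludes only that event. Length variants
    (insertions/deletions) inside ``cstretch_ranges`` are always dropped.
    """

    excluded_positions: frozenset[str] = frozenset(DEFAULT_EXCLUDED)
    cstretch_ranges: tuple[CircularInterval, ...] = DEFAULT_CSTRETCH

    def _excluded(self, v: Variant) -> bool:
        tok = serialize_variant(v.without_reversion())
        if tok in self.excluded_positions:
            return True
        if str(v.position) in self.excluded_positions and v.kind != INSERTION:
            return True
        if v.is_indel:
            for rng in self.cstretch_ranges:
                if v.position in rng or v.span_end in rng:
                    return True
        return False

    def apply(self, variants: Iterable[Variant], profile: str = "network") -> frozenset[Variant]:
        """Filter a variant set under a counting profile.

        Profiles
        --------
        ``network``
            Substitutions only, except that the 106–111 6-bp deletion is
            retained as a single character; insertions, other deletions
            and heteroplasmies are dropped.
        ``stats``
            Substitutions only (diversity-statistic convention).
        ``none``
            No filtering at all (even excluded positions are kept).

        Reversion-flagged tokens denote the *reference* state and never
        represent a difference, so they are dropped from every profile.
        """
        if profile == "none":
            return frozenset(variants)
        out = set()
        for v in variants:
            if v.reversion or self._excluded(v):
                continue
            if v.is_substitution:
                out.add(v)
            elif profile == "network" and v.without_reversion() == HUETAR_DELETION:
                out.add(v)
        return frozenset(out)


NETWORK_FILTER = SiteFilter()
NO_FILTER = SiteFilter(excluded_positions=frozenset(), cstretch_ranges=())
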