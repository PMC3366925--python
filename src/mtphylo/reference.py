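"""Reference mtDNA sequence handling.

The coordinate system is the 16,569-bp rCRS numbering. Users working with
real data load the rCRS from FASTA; the test-suite and the simulator use a
deterministic synthetic reference of the same length (variant notation is
coordinate-based, so none of the downstream arithmetic depends on the
actual bases).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from Bio import SeqIO

from .variants import MT_LENGTH

_ALPHABET = set("ACGTN")


@dataclass(frozen=True)
class RefSequence:
    """An mtDNA reference: id plus a 16,569-bp circular sequence."""

    id: str
    bases: str

    def __post_init__(self) -> None:
        if len(self.bases) != MT_LENGTH:
            raise ValueError(
                f"reference must be {MT_LENGTH} bp, got {len(self.bases)}"
            )
        bad = set(self.bases) - _ALPHABET
        if bad:
            raise ValueError(f"non-ACGTN characters in reference: {sorted(bad)}")

    def base(self, position: int) -> str:
        """Base at a 1-based rCRS position."""
        if not 1 <= position <= MT_LENGTH:
            raise IndexError(f"position {position} outside 1..{MT_LENGTH}")
        return self.bases[position - 1]

    def __len__(self) -> int:
        return MT_LENGTH


def read_fasta_reference(path) -> RefSequence:
    """Load a reference (e.g. the rCRS, NC_012920) from a FASTA file."""
    rec = next(SeqIO.parse(str(path), "fasta"))
    return RefSequence(id=rec.id, bases=str(rec.seq).upper())


def synthetic_reference(seed: int = 16569) -> RefSequence:
    """Deterministic synthetic 16,569-bp reference (not the real rCRS).

    Base composition loosely follows human mtDNA (A/C-rich light strand).
    Used wherever a concrete sequence is needed but real rCRS bases are
    irrelevant to the result.
    """
    rng = np.random.default_rng(seed)
    bases = rng.choice(list("ACGT"), size=MT_LENGTH, p=[0.31, 0.31, 0.13, 0.25])
    return RefSequence(id=f"synthetic-ref-{seed}", bases="".join(bases))
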