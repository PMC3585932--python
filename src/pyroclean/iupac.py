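"""IUPAC nucleotide alphabet, ambiguity-aware matching and suffix mismatch scoring.

Every downstream denoising step compares pyrosequencing reads to a consensus
reference sequence written in the IUPAC ambiguity alphabet.  A consensus symbol
such as ``R`` stands for the set ``{A, G}``: a read base matches a consensus
column whenever it is contained in (more generally, compatible with) the
column's base set.  The suffix mismatch vector ``m`` scores each read position
``i`` by the number of mismatching columns from ``i`` to the end of the read;
homopolymer indel detection works by asking whether a candidate edit makes this
score drop.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "IUPAC_TO_BASES",
    "BASES_TO_IUPAC",
    "AlphabetError",
    "LengthError",
    "ConsensusReference",
    "base_set",
    "matches",
    "compatible",
    "ambiguity_for",
    "mismatch_mask",
    "suffix_mismatch_counts",
    "hamming",
]

#: Standard IUPAC nucleotide one-letter codes mapped to their base sets.
IUPAC_TO_BASES: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

#: Inverse of :data:`IUPAC_TO_BASES` (base set -> unique symbol).
BASES_TO_IUPAC: dict[frozenset[str], str] = {v: k for k, v in IUPAC_TO_BASES.items()}


class AlphabetError(ValueError):
    """A character outside the IUPAC DNA alphabet was encountered."""


class LengthError(ValueError):
    """A read overhangs the available consensus reference sequence."""


def base_set(symbol: str, position: int | None = None) -> frozenset[str]:
    """Return the nucleotide set denoted by an IUPAC symbol.

    Lowercase input is accepted (uppercased); ``U`` is rejected because the
    pipeline operates on DNA FASTA only.
    """
    try:
        return IUPAC_TO_BASES[symbol.upper()]
    except KeyError:
        where = "" if position is None else f" at position {position}"
        raise AlphabetError(
            f"invalid IUPAC nucleotide symbol {symbol!r}{where}"
        ) from None


def matches(base: str, code: str) -> bool:
    """True iff an unambiguous base is contained in an IUPAC code's base set.

    ``base`` must be one of A/C/G/T; ``code`` may be any IUPAC symbol.
    """
    b = base.upper()
    if b not in "ACGT" or len(b) != 1:
        raise AlphabetError(f"expected an unambiguous base A/C/G/T, got {base!r}")
    return b in base_set(code)


def compatible(a: str, b: str) -> bool:
    """Ambiguity-aware comparison: true iff the two symbols' base sets intersect.

    Reads may themselves carry ambiguity codes (gap filling during deletion
    correction writes them), so the weakest consistent rule is used: two
    symbols agree when some nucleotide satisfies both.
    """
    return not base_set(a).isdisjoint(base_set(b))


def ambiguity_for(bases) -> str:
    """Return the IUPAC symbol whose base set equals ``bases`` (nonempty).

    ``bases`` may contain ambiguity codes; they are expanded first, so
    ``ambiguity_for({'R', 'C'})`` is ``'V'``.
    """
    pooled: set[str] = set()
    for b in bases:
        pooled |= base_set(b)
    if not pooled:
        raise ValueError("ambiguity_for() requires a nonempty base set")
    return BASES_TO_IUPAC[frozenset(pooled)]


@dataclass(frozen=True)
class ConsensusReference:
    """A consensus sequence over the IUPAC alphabet used as positional anchor.

    ``offset`` is the consensus position that read position 0 aligns to;
    reads are compared column-by-column with no realignment.
    """

    sequence: str
    offset: int = 0
    name: str = field(default="consensus", compare=False)

    def __post_init__(self) -> None:
        seq = self.sequence.upper()
        for i, ch in enumerate(seq):
            if ch not in IUPAC_TO_BASES:
                raise AlphabetError(f"invalid IUPAC symbol {ch!r} at position {i}")
        if not seq:
            raise ValueError("consensus sequence must be nonempty")
        if self.offset < 0:
            raise ValueError("consensus offset must be >= 0")
        object.__setattr__(self, "sequence", seq)

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def available(self) -> int:
        """Number of consensus columns available from ``offset`` onwards."""
        return len(self.sequence) - self.offset

    def window(self, length: int) -> str:
        """The consensus columns a read of ``length`` bases aligns against."""
        return self.sequence[self.offset : self.offset + length]


def mismatch_mask(read: str, consensus: ConsensusReference) -> np.ndarray:
    """Boolean array: position ``i`` is True iff the read mismatches there."""
    if len(read) > consensus.available:
        raise LengthError(
            f"read of length {len(read)} overhangs consensus by "
            f"{len(read) - consensus.available} bases "
            f"(consensus length {len(consensus)}, offset {consensus.offset})"
        )
    win = consensus.window(len(read))
    return np.fromiter(
        (not compatible(r, c) for r, c in zip(read, win)),
        dtype=bool,
        count=len(read),
    )


def suffix_mismatch_counts(read: str, consensus: ConsensusReference) -> np.ndarray:
    """Suffix mismatch vector ``m``: ``m[i]`` counts mismatches from ``i`` to the end.

    Computed positionally against the consensus window starting at the
    consensus offset; ``m`` is non-increasing and ``m[i] - m[i+1]`` is 0 or 1.
    """
    mask = mismatch_mask(read, consensus)
    return np.cumsum(mask[::-1])[::-1].astype(np.int64)


def hamming(a: str, b: str) -> int:
    """Ambiguity-aware Hamming distance: compatible positions count as matches."""
    if len(a) != len(b):
        raise LengthError(f"sequences differ in length ({len(a)} vs {len(b)})")
    return sum(1 for x, y in zip(a, b) if not compatible(x, y))
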