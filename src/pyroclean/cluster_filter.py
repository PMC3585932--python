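"""Step 5 — frequency filtering of near-identical low-abundance sequences.

Sequences that pass the consensus filter can still be PCR error, sequencing
error or numts: they sit within a small Hamming distance of a genuine
template but at a much lower read count.  Sequences are processed in
descending count order; a sequence is removed when an already-retained
sequence lies within the divergence threshold and carries at least
``1/min_freq_ratio`` times its count.  The comparison is against retained
sequences only, so removals never chain below an already-removed sequence,
and the globally most frequent sequence is always retained.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .iupac import LengthError, hamming
from .read_prep import UniqueSequence

__all__ = ["ClusterParams", "RemovalRecord", "frequency_filter"]


@dataclass(frozen=True)
class ClusterParams:
    #: maximum divergence, as a fraction of the alignment length, for a
    #: sequence to be considered a variant of a retained sequence (default 1%)
    max_divergence: float = 0.01
    #: minimum count relative to the retained neighbour below which the
    #: sequence is removed (default 10%)
    min_freq_ratio: float = 0.10

    def __post_init__(self) -> None:
        if not 0.0 <= self.max_divergence <= 1.0:
            raise ValueError("max_divergence must be in [0, 1]")
        if not 0.0 < self.min_freq_ratio <= 1.0:
            raise ValueError("min_freq_ratio must be in (0, 1]")


@dataclass(frozen=True)
class RemovalRecord:
    """Why a sequence was removed: its nearest qualifying retained neighbour."""

    name: str
    count: int
    partner: str
    partner_count: int
    distance: int
    ratio: float


def frequency_filter(
    uniques: Sequence[UniqueSequence],
    params: ClusterParams | None = None,
) -> tuple[list[UniqueSequence], list[RemovalRecord]]:
    """Remove low-frequency variants of higher-frequency sequences.

    With the default parameters (1% divergence, 10% frequency) on a 220-base
    alignment, a sequence is removed iff some retained sequence is within
    ``floor(0.01 * 220) = 2`` ambiguity-aware mismatches and has more than
    ten times its count.  Output is invariant to input order (processing is
    by descending count, ties by name).  Returns (retained, removals).
    """
    p = params or ClusterParams()
    pool = sorted(uniques, key=lambda u: (-u.count, u.name))
    if pool:
        lengths = {len(u.sequence) for u in pool}
        if len(lengths) > 1:
            raise LengthError(
                f"frequency_filter requires equal-length sequences, got {sorted(lengths)}"
            )
        threshold = int(p.max_divergence * len(pool[0].sequence))
    retained: list[UniqueSequence] = []
    removed: list[RemovalRecord] = []
    for u in pool:
        hit = None
        for v in retained:
            d = hamming(u.sequence, v.sequence)
            if d <= threshold and u.count < p.min_freq_ratio * v.count:
                if hit is None or d < hit[1]:
                    hit = (v, d)
        if hit is None:
            retained.append(u)
        else:
            v, d = hit
            removed.append(
                RemovalRecord(u.name, u.count, v.name, v.count, d, u.count / v.count)
            )
    return retained, removed
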