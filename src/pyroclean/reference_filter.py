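"""Step 4 — singleton exclusion, consensus-divergence filtering, 3' trimming
and ambiguity-consistent merging.

Homopolymer correction needs downstream anchor points, so it denoises the 3'
end of a read less well; the alignment is therefore trimmed (default 220
bases) before sequences are screened against the consensus.  Sequences more
divergent from the consensus than ``max_mismatch`` are removed, low-frequency
sequences (singletons by default) are excluded a priori, and sequences that
are identical up to consistent ambiguity codes are merged with counts summed.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

from .iupac import ConsensusReference, IUPAC_TO_BASES, hamming
from .read_prep import ConfigError, UniqueSequence

__all__ = [
    "FilterParams",
    "drop_low_count",
    "consensus_filter",
    "merge_ambiguity_consistent",
]


@dataclass(frozen=True)
class FilterParams:
    min_count: int = 2
    max_mismatch: int = 1
    trim_to: int = 220

    def __post_init__(self) -> None:
        if self.min_count < 1:
            raise ConfigError("min_count must be >= 1")
        if self.max_mismatch < 0:
            raise ConfigError("max_mismatch must be >= 0")
        if self.trim_to <= 0:
            raise ConfigError("trim_to must be > 0")


def drop_low_count(
    uniques: Sequence[UniqueSequence], min_count: int = 2
) -> tuple[list[UniqueSequence], list[UniqueSequence]]:
    """Exclude sequences seen fewer than ``min_count`` times (singletons by
    default).  Returns (retained, removed)."""
    retained = [u for u in uniques if u.count >= min_count]
    removed = [u for u in uniques if u.count < min_count]
    return retained, removed


def consensus_filter(
    uniques: Sequence[UniqueSequence],
    consensus: ConsensusReference,
    max_mismatch: int = 1,
    trim_to: int = 220,
) -> tuple[list[UniqueSequence], list[UniqueSequence]]:
    """Trim to ``trim_to`` bases and drop sequences too divergent from the
    consensus.

    Each sequence is truncated to its first ``trim_to`` bases; sequences
    shorter than that are removed (they cannot be scored over the full
    window).  A sequence is retained iff its ambiguity-aware mismatch count
    to the consensus over the trimmed window is at most ``max_mismatch``.
    Returns (retained, removed); the retained set grows monotonically with
    ``max_mismatch``.
    """
    window = consensus.window(trim_to)
    if len(window) < trim_to:
        raise ConfigError(
            f"consensus provides only {len(window)} columns from offset "
            f"{consensus.offset}, need {trim_to}"
        )
    retained, removed = [], []
    for u in uniques:
        if len(u.sequence) < trim_to:
            removed.append(u)
            continue
        trimmed = replace(u, sequence=u.sequence[:trim_to])
        if hamming(trimmed.sequence, window) <= max_mismatch:
            retained.append(trimmed)
        else:
            removed.append(trimmed)
    return retained, removed


def _subset(a: str, b: str) -> bool:
    return IUPAC_TO_BASES[a] <= IUPAC_TO_BASES[b]


def _mergeable(u: str, v: str) -> bool:
    """True iff the sequences are identical except at positions where one
    symbol's base set contains the other's (the ambiguity code is consistent
    with the other sequence's state)."""
    return all(a == b or _subset(a, b) or _subset(b, a) for a, b in zip(u, v))


def _resolve(u: str, v: str) -> str:
    """Merge two mergeable sequences; at each position the more specific
    (smaller base set) symbol wins, removing resolvable ambiguity codes."""
    return "".join(a if _subset(a, b) else b for a, b in zip(u, v))


def merge_ambiguity_consistent(
    uniques: Sequence[UniqueSequence],
) -> list[UniqueSequence]:
    """Merge sequences identical up to consistent ambiguity codes.

    Processing is greedy by descending count (ties by name): each sequence
    merges into the highest-count compatible target already retained, the
    unambiguous states win, and counts are summed.  Repeated to a fixpoint,
    after which no retained pair satisfies the merge predicate.  Total count
    is conserved.  All sequences must have equal length (post-trim).
    """
    pool = list(uniques)
    if pool and len({len(u.sequence) for u in pool}) > 1:
        raise ConfigError("merge requires equal-length sequences (trim first)")
    while True:
        pool.sort(key=lambda u: (-u.count, u.name))
        merged_any = False
        out: list[UniqueSequence] = []
        for u in pool:
            target_idx = None
            for k, v in enumerate(out):
                if u.sequence != v.sequence and _mergeable(u.sequence, v.sequence):
                    target_idx = k
                    break
            if target_idx is None:
                out.append(u)
            else:
                v = out[target_idx]
                out[target_idx] = UniqueSequence(
                    v.name, v.count + u.count, _resolve(u.sequence, v.sequence)
                )
                merged_any = True
        pool = out
        if not merged_any:
            return sorted(pool, key=lambda u: (-u.count, u.name))
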