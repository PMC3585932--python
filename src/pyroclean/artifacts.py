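"""Step 6 support — flagging of uncorrected compensated indels and putative numts.

Two artifact classes can survive the automated filters.  An uncorrected
compensated indel leaves a sequence differing from a related sequence by one
contiguous run of mismatching nucleotides.  A numt (nuclear copy of the
mitochondrial target) typically appears as a low-frequency variant a small
distance from a genuine sequence.  Both signatures are heuristic, so this
module only FLAGS sequences for manual review; removal is an explicit opt-in
at the pipeline level.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .iupac import LengthError, compatible
from .read_prep import UniqueSequence

__all__ = ["ArtifactFlag", "flag_compensated_indels", "flag_putative_numts"]


@dataclass(frozen=True)
class ArtifactFlag:
    name: str
    kind: str  # compensated_indel | putative_numt
    partner: str  # related higher-count sequence (first of partners)
    evidence: str
    partners: tuple[str, ...] = ()


def _diff_positions(a: str, b: str) -> list[int]:
    if len(a) != len(b):
        raise LengthError("artifact flagging requires equal-length sequences")
    return [i for i, (x, y) in enumerate(zip(a, b)) if not compatible(x, y)]


def _ranked(uniques: Sequence[UniqueSequence]) -> list[UniqueSequence]:
    return sorted(uniques, key=lambda u: (-u.count, u.name))


def flag_compensated_indels(
    uniques: Sequence[UniqueSequence], min_run: int = 3
) -> list[ArtifactFlag]:
    """Flag sequences differing from a higher-count sequence only by one
    contiguous run of at least ``min_run`` mismatching positions."""
    ranked = _ranked(uniques)
    flags = []
    for idx, u in enumerate(ranked):
        for v in ranked[:idx]:  # every v here has count >= u.count
            diffs = _diff_positions(u.sequence, v.sequence)
            if len(diffs) >= min_run and diffs == list(
                range(diffs[0], diffs[0] + len(diffs))
            ):
                flags.append(
                    ArtifactFlag(
                        u.name,
                        "compensated_indel",
                        v.name,
                        f"run of {len(diffs)} consecutive mismatches at "
                        f"{diffs[0]}-{diffs[-1]}",
                        (v.name,),
                    )
                )
                break
    return flags


def flag_putative_numts(
    uniques: Sequence[UniqueSequence],
    max_divergence: float = 0.10,
    max_freq_ratio: float = 0.10,
) -> list[ArtifactFlag]:
    """Flag low-frequency sequences phylogenetically close to a much more
    frequent sequence (p-distance <= ``max_divergence`` and count below
    ``max_freq_ratio`` of the partner's).  All qualifying partners are
    reported on one flag."""
    ranked = _ranked(uniques)
    flags = []
    for idx, u in enumerate(ranked):
        partners = []
        length = len(u.sequence)
        for v in ranked[:idx]:
            if u.count >= max_freq_ratio * v.count:
                continue
            d = len(_diff_positions(u.sequence, v.sequence))
            if d / length <= max_divergence:
                partners.append((v.name, d, u.count / v.count))
        if partners:
            flags.append(
                ArtifactFlag(
                    u.name,
                    "putative_numt",
                    partners[0][0],
                    "; ".join(
                        f"{name}: distance {d}, frequency ratio {r:.3f}"
                        for name, d, r in partners
                    ),
                    tuple(name for name, _, _ in partners),
                )
            )
    return flags
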