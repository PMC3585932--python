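"""Step 3 — correction of homopolymer read errors against the consensus reference.

454-style pyrosequencers misread homopolymer runs (two or more adjacent
identical nucleotides), inserting or dropping a base.  Because the target
amplicon is indel-free, such an error frameshifts the remainder of the read
relative to the consensus reference, which shows up as a burst of mismatches
downstream of the error site.  Each read is therefore scanned 5'→3' and three
kinds of repair are attempted at every mismatching position:

* insertion removal — delete one base of the homopolymer adjacent to the
  mismatch (the read suffix shifts one column left);
* deletion filling — insert one base before the mismatch (the suffix shifts
  one column right), extending the adjacent homopolymer when that is
  consistent with the consensus, otherwise writing the consensus symbol;
* compensated indels — an insertion and a nearby deletion in one read leave
  the read length correct but misalign only the interval between them; one
  homopolymer base is removed at one end of the mismatch region and a gap is
  introduced at the other end (both orientations tried), the gap being filled
  from its flanking bases or, on a tie, with their joint ambiguity code.

An edit is kept only if it strictly decreases the total number of
ambiguity-aware mismatches to the consensus; the three passes are iterated to
a fixpoint (bounded by an edit cap), which makes the whole correction
deterministic and idempotent.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from .iupac import ConsensusReference, IUPAC_TO_BASES, ambiguity_for
from .read_prep import UniqueSequence, dereplicate

__all__ = [
    "CorrectionEvent",
    "CorrectionParams",
    "CorrectionResult",
    "fix_insertions",
    "fix_deletions",
    "fix_compensated_indels",
    "correct_read",
    "correct_uniques",
]

# Precomputed 15x15 symbol-compatibility table for the hot scoring loops.
_COMPAT: dict[tuple[str, str], bool] = {
    (a, b): not sa.isdisjoint(sb)
    for a, sa in IUPAC_TO_BASES.items()
    for b, sb in IUPAC_TO_BASES.items()
}


@dataclass(frozen=True)
class CorrectionEvent:
    """Audit record of one accepted homopolymer repair."""

    read_name: str
    kind: str  # insertion_removed | deletion_filled | compensation
    position: int
    before: str
    after: str


@dataclass(frozen=True)
class CorrectionParams:
    max_length: int | None = None
    edit_cap: int = 20


@dataclass(frozen=True)
class CorrectionResult:
    sequence: str
    events: tuple[CorrectionEvent, ...]
    cap_hit: bool = False


def _total_mismatches(chars: Sequence[str], cons: str, off: int) -> int:
    """Mismatches against the consensus window.

    Read positions past the end of the consensus cannot be aligned and are
    counted as mismatches, so that pulling an overhanging suffix back into
    the window (by removing a surplus base) registers as an improvement.
    """
    compat = _COMPAT
    avail = len(cons) - off
    n_over = max(0, len(chars) - avail)
    return n_over + sum(
        1
        for i, c in enumerate(chars[: len(chars) - n_over])
        if not compat[(c, cons[off + i])]
    )


def _mismatch_positions(chars: Sequence[str], cons: str, off: int) -> list[int]:
    compat = _COMPAT
    avail = len(cons) - off
    return [
        i
        for i, c in enumerate(chars)
        if i >= avail or not compat[(c, cons[off + i])]
    ]


def fix_insertions(
    read: str,
    consensus: ConsensusReference,
    read_name: str = "read",
    max_edits: int | None = None,
) -> tuple[str, list[CorrectionEvent]]:
    """Remove single surplus homopolymer bases, scanning 5'→3'.

    At each mismatching position ``i`` the maximal homopolymer run touching
    ``i-1`` (it may extend through ``i`` itself) is located; if it is at
    least two bases long, one base is tentatively deleted and the edit is
    kept iff the total mismatch count strictly drops.  The scan resumes from
    the edit site after every accepted deletion.
    """
    chars = list(read.upper())
    cons, off = consensus.sequence, consensus.offset
    avail = consensus.available
    compat = _COMPAT
    events: list[CorrectionEvent] = []
    total = _total_mismatches(chars, cons, off)
    i = 0
    while i < len(chars):
        if i < avail and compat[(chars[i], cons[off + i])]:
            i += 1
            continue
        j = i - 1
        if j >= 0:
            b = chars[j]
            s = j
            while s > 0 and chars[s - 1] == b:
                s -= 1
            e = j
            while e + 1 < len(chars) and chars[e + 1] == b:
                e += 1
            run_len = e - s + 1
            if run_len >= 2:
                cand = chars[:j] + chars[j + 1 :]
                cand_total = _total_mismatches(cand, cons, off)
                if cand_total < total:
                    events.append(
                        CorrectionEvent(
                            read_name, "insertion_removed", j,
                            b * run_len, b * (run_len - 1),
                        )
                    )
                    chars, total = cand, cand_total
                    if max_edits is not None and len(events) >= max_edits:
                        break
                    i = s
                    continue
        i += 1
    return "".join(chars), events


def fix_deletions(
    read: str,
    consensus: ConsensusReference,
    read_name: str = "read",
    max_length: int | None = None,
    max_edits: int | None = None,
) -> tuple[str, list[CorrectionEvent]]:
    """Fill single missing homopolymer bases, scanning 5'→3'.

    At a mismatch ``b_i`` one base is tentatively inserted before ``i``: a
    copy of the preceding base when that extends a homopolymer consistently
    with the consensus column, otherwise the consensus symbol at that column
    (which may itself be an ambiguity code).  The edit is kept iff the total
    mismatch count strictly drops.  The read grows by one base per accepted
    event; bases shifted past the consensus window or ``max_length`` are
    discarded.
    """
    chars = list(read.upper())
    cons, off = consensus.sequence, consensus.offset
    avail = consensus.available
    compat = _COMPAT
    events: list[CorrectionEvent] = []
    total = _total_mismatches(chars, cons, off)
    i = 0
    while i < len(chars):
        if i >= avail or compat[(chars[i], cons[off + i])]:
            i += 1
            continue
        col = cons[off + i]
        left = chars[i - 1] if i > 0 else None
        fill = left if (left is not None and compat[(left, col)]) else col
        cand = chars[:i] + [fill] + chars[i:]
        if len(cand) > avail:
            cand = cand[:avail]
        if max_length is not None and len(cand) > max_length:
            cand = cand[:max_length]
        cand_total = _total_mismatches(cand, cons, off)
        if cand_total < total:
            events.append(
                CorrectionEvent(
                    read_name, "deletion_filled", i, chars[i], fill + chars[i]
                )
            )
            chars, total = cand, cand_total
            if max_edits is not None and len(events) >= max_edits:
                break
            continue
        i += 1
    return "".join(chars), events


def _hp_indices_left(chars: list[str], i: int) -> list[int]:
    """Removable homopolymer base indices at the 5' end of a mismatch region."""
    out = []
    n = len(chars)
    if 0 <= i < n and (
        (i > 0 and chars[i - 1] == chars[i])
        or (i + 1 < n and chars[i + 1] == chars[i])
    ):
        out.append(i)
    if i - 1 >= 1 and chars[i - 2] == chars[i - 1]:
        out.append(i - 1)
    return out


def _hp_indices_right(chars: list[str], j: int) -> list[int]:
    """Removable homopolymer base indices at the 3' end of a mismatch region."""
    out = []
    n = len(chars)
    if 0 <= j < n and (
        (j > 0 and chars[j - 1] == chars[j])
        or (j + 1 < n and chars[j + 1] == chars[j])
    ):
        out.append(j)
    if j + 2 < n and chars[j + 1] == chars[j + 2]:
        out.append(j + 1)
    return out


def _gap_fill(left: str | None, right: str | None, col: str) -> str | None:
    """Fill symbol for a gap flanked by ``left``/``right`` against consensus ``col``.

    If exactly one distinct flanking state would extend into a homopolymer
    consistent with the consensus column, that state is used; if both or
    neither qualify, the joint ambiguity code of the flanking states is
    written instead.
    """
    flanks = [f for f in (left, right) if f is not None]
    if not flanks:
        return None
    quals = {f for f in flanks if _COMPAT[(f, col)]}
    if len(quals) == 1:
        return next(iter(quals))
    return ambiguity_for(flanks)


def _compensation_candidates(
    chars: list[str], i: int, j: int, cons: str, off: int
) -> list[list[str]]:
    cands: list[list[str]] = []
    avail = len(cons) - off
    # surplus base near the 5' end, missing base at the 3' end
    if j < avail:
        for rm in _hp_indices_left(chars, i):
            tmp = chars[:rm] + chars[rm + 1 :]
            if j > len(tmp):
                continue
            fill = _gap_fill(
                tmp[j - 1] if j - 1 >= 0 else None,
                tmp[j] if j < len(tmp) else None,
                cons[off + j],
            )
            if fill is not None:
                cands.append(tmp[:j] + [fill] + tmp[j:])
    # missing base at the 5' end, surplus base near the 3' end
    if i < avail:
        for rm in _hp_indices_right(chars, j):
            tmp = chars[:rm] + chars[rm + 1 :]
            fill = _gap_fill(
                tmp[i - 1] if i - 1 >= 0 else None,
                tmp[i] if i < len(tmp) else None,
                cons[off + i],
            )
            if fill is not None:
                cands.append(tmp[:i] + [fill] + tmp[i:])
    return cands


def fix_compensated_indels(
    read: str,
    consensus: ConsensusReference,
    read_name: str = "read",
    max_edits: int | None = None,
) -> tuple[str, list[CorrectionEvent]]:
    """Repair insertion+deletion pairs that misalign only a local region.

    A candidate region spans mismatch positions ``i..j`` containing more
    than one mismatch, with at most one mismatching position upstream of
    ``i`` and at most one downstream of ``j``.  Within the region a
    homopolymer base is removed at one end and a gap introduced at the
    other (both orientations are evaluated); the orientation minimising the
    total mismatch count is kept iff it strictly improves on the original.
    """
    chars = list(read.upper())
    cons, off = consensus.sequence, consensus.offset
    events: list[CorrectionEvent] = []
    while max_edits is None or len(events) < max_edits:
        mm = _mismatch_positions(chars, cons, off)
        if len(mm) < 2:
            break
        last = len(mm) - 1
        regions: list[tuple[int, int]] = []
        for a, b in ((0, last), (0, last - 1), (1, last), (1, last - 1)):
            if b - a + 1 >= 2 and (mm[a], mm[b]) not in regions:
                regions.append((mm[a], mm[b]))
        total = _total_mismatches(chars, cons, off)
        edited = False
        for i, j in regions:
            best, best_total = None, total
            for cand in _compensation_candidates(chars, i, j, cons, off):
                t = _total_mismatches(cand, cons, off)
                if t < best_total:
                    best, best_total = cand, t
            if best is not None:
                events.append(
                    CorrectionEvent(
                        read_name, "compensation", i,
                        "".join(chars[i : j + 1]), "".join(best[i : j + 1]),
                    )
                )
                chars = best
                edited = True
                break
        if not edited:
            break
    return "".join(chars), events


def _single_edit_candidates(
    chars: list[str],
    i: int,
    cons: str,
    off: int,
    max_length: int | None,
    read_name: str,
) -> list[tuple[list[str], CorrectionEvent]]:
    """Single-indel repairs available at mismatch position ``i``: removal of
    one base of the homopolymer touching ``i-1`` (insertion error), and a
    one-base fill before ``i`` (deletion error).  Candidates are listed with
    the insertion repair first so score ties resolve toward it."""
    avail = len(cons) - off
    compat = _COMPAT
    out: list[tuple[list[str], CorrectionEvent]] = []
    j = i - 1
    if j >= 0:
        b = chars[j]
        s = j
        while s > 0 and chars[s - 1] == b:
            s -= 1
        e = j
        while e + 1 < len(chars) and chars[e + 1] == b:
            e += 1
        run_len = e - s + 1
        if run_len >= 2:
            out.append(
                (
                    chars[:j] + chars[j + 1 :],
                    CorrectionEvent(
                        read_name, "insertion_removed", j,
                        b * run_len, b * (run_len - 1),
                    ),
                )
            )
    if i < avail:
        col = cons[off + i]
        left = chars[i - 1] if i > 0 else None
        fill = left if (left is not None and compat[(left, col)]) else col
        cand = chars[:i] + [fill] + chars[i:]
        if len(cand) > avail:
            cand = cand[:avail]
        if max_length is not None and len(cand) > max_length:
            cand = cand[:max_length]
        out.append(
            (
                cand,
                CorrectionEvent(
                    read_name, "deletion_filled", i, chars[i], fill + chars[i]
                ),
            )
        )
    return out


def _best_compensation_edit(
    chars: list[str], cons: str, off: int, read_name: str
) -> tuple[list[str], CorrectionEvent] | None:
    """Best strictly-improving compensated-indel repair, or None."""
    mm = _mismatch_positions(chars, cons, off)
    if len(mm) < 2:
        return None
    last = len(mm) - 1
    regions: list[tuple[int, int]] = []
    for a, b in ((0, last), (0, last - 1), (1, last), (1, last - 1)):
        if b - a + 1 >= 2 and (mm[a], mm[b]) not in regions:
            regions.append((mm[a], mm[b]))
    total = _total_mismatches(chars, cons, off)
    for i, j in regions:
        best, best_total = None, total
        for cand in _compensation_candidates(chars, i, j, cons, off):
            t = _total_mismatches(cand, cons, off)
            if t < best_total:
                best, best_total = cand, t
        if best is not None:
            return best, CorrectionEvent(
                read_name, "compensation", i,
                "".join(chars[i : j + 1]), "".join(best[i : j + 1]),
            )
    return None


def correct_read(
    read: str,
    consensus: ConsensusReference,
    params: CorrectionParams | None = None,
    read_name: str = "read",
) -> CorrectionResult:
    """Apply homopolymer repairs until no edit improves the read.

    Mismatch positions are visited 5'→3'; at each, the available
    single-indel repairs (homopolymer base removal, then gap fill) are
    scored together and the one yielding the lowest total mismatch count is
    accepted when it strictly improves on the current read.  Scoring the
    two repair types jointly matters: a read whose true error is a deletion
    presents a frameshifted tail in which a spurious base removal can lower
    the score by chance, but never as far as the genuine fill, so the joint
    minimum tracks the true repair.  When no single-indel repair improves
    any position, compensated-indel repairs are attempted.  The loop runs
    to a fixpoint, bounded by the edit cap (``cap_hit`` is set when the cap
    is reached so the caller can log a warning).

    Deterministic for fixed input and parameters; the result never
    contains gap characters and is truncated to ``params.max_length``.
    """
    p = params or CorrectionParams()
    cons, off = consensus.sequence, consensus.offset
    chars = list(read.upper())
    all_events: list[CorrectionEvent] = []
    cap_hit = False
    while True:
        if len(all_events) >= p.edit_cap:
            cap_hit = True
            break
        total = _total_mismatches(chars, cons, off)
        if total == 0:
            break
        chosen: tuple[list[str], CorrectionEvent] | None = None
        for i in _mismatch_positions(chars, cons, off):
            best, best_total, best_event = None, total, None
            for cand, event in _single_edit_candidates(
                chars, i, cons, off, p.max_length, read_name
            ):
                t = _total_mismatches(cand, cons, off)
                if t < best_total:
                    best, best_total, best_event = cand, t, event
            if best is not None:
                chosen = (best, best_event)
                break
        if chosen is None:
            chosen = _best_compensation_edit(chars, cons, off, read_name)
        if chosen is None:
            break
        chars, event = chosen
        all_events.append(event)
    seq = "".join(chars)
    if p.max_length is not None:
        seq = seq[: p.max_length]
    return CorrectionResult(seq, tuple(all_events), cap_hit)


def correct_uniques(
    uniques: Iterable[UniqueSequence],
    consensus: ConsensusReference,
    params: CorrectionParams | None = None,
) -> tuple[list[UniqueSequence], list[CorrectionEvent], int]:
    """Correct every unique sequence (read counts carried through), then
    re-dereplicate so corrected sequences that collide are merged with their
    counts summed.  Returns (corrected uniques, all events, #cap-hit reads).
    """
    corrected: list[UniqueSequence] = []
    events: list[CorrectionEvent] = []
    n_capped = 0
    for u in uniques:
        res = correct_read(u.sequence, consensus, params=params, read_name=u.name)
        corrected.append(UniqueSequence(u.name, u.count, res.sequence))
        events.extend(res.events)
        n_capped += int(res.cap_hit)
    return dereplicate(corrected), events, n_capped
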