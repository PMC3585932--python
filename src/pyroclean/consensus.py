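"""Step 2 — build an IUPAC-ambiguity consensus reference from a reference alignment.

Equivalent in spirit to EMBOSS ``consambig``: for each alignment column the
observed nucleotide states are pooled (ambiguity codes expanded, gaps
ignored) and the column is summarised by the IUPAC symbol for the union of
surviving states.  With the default ``min_state_freq = 0`` this is pure
union semantics; a nonzero cutoff drops rare states first, which keeps a
consensus built from very large reference sets from degenerating toward N.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

from Bio import SeqIO

from .iupac import AlphabetError, ConsensusReference, IUPAC_TO_BASES, ambiguity_for

__all__ = ["ReferenceAlignment", "build_consensus", "load_alignment", "load_consensus", "write_consensus"]

GAP_CHARS = frozenset("-.")


@dataclass(frozen=True)
class ReferenceAlignment:
    """A multiple alignment of reference sequences (equal-length IUPAC rows)."""

    rows: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.rows:
            raise ValueError("reference alignment must contain at least one row")
        rows = tuple(r.upper() for r in self.rows)
        width = len(rows[0])
        for k, row in enumerate(rows):
            if len(row) != width:
                raise ValueError(
                    f"alignment row {k} has length {len(row)}, expected {width}"
                )
            for i, ch in enumerate(row):
                if ch not in IUPAC_TO_BASES and ch not in GAP_CHARS:
                    raise AlphabetError(
                        f"row {k}: invalid symbol {ch!r} at column {i}"
                    )
        object.__setattr__(self, "rows", rows)

    @property
    def width(self) -> int:
        return len(self.rows[0])


def build_consensus(
    alignment: ReferenceAlignment,
    min_state_freq: float = 0.0,
    offset: int = 0,
) -> ConsensusReference:
    """Summarise each alignment column as one IUPAC ambiguity symbol.

    Per column: expand every row symbol to its base set, ignore gaps, drop
    bases seen in fewer than ``min_state_freq`` of the non-gap rows, and emit
    the ambiguity code for the union of survivors.  An all-gap (or
    all-dropped) column becomes ``N``.
    """
    symbols = []
    for col in range(alignment.width):
        counts: Counter[str] = Counter()
        depth = 0
        for row in alignment.rows:
            ch = row[col]
            if ch in GAP_CHARS:
                continue
            depth += 1
            for b in IUPAC_TO_BASES[ch]:
                counts[b] += 1
        kept = {
            b for b, c in counts.items() if depth and c / depth >= min_state_freq and c > 0
        }
        if min_state_freq == 0.0:
            kept = set(counts)
        symbols.append(ambiguity_for(kept) if kept else "N")
    return ConsensusReference("".join(symbols), offset=offset)


def load_alignment(path) -> ReferenceAlignment:
    """Read an aligned FASTA into a :class:`ReferenceAlignment`."""
    rows = tuple(str(rec.seq) for rec in SeqIO.parse(str(path), "fasta"))
    return ReferenceAlignment(rows)


def load_consensus(path, offset: int = 0) -> ConsensusReference:
    """Read a single-record FASTA holding a precomputed consensus."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if len(records) != 1:
        raise ValueError(
            f"consensus FASTA must hold exactly one record, found {len(records)}"
        )
    rec = records[0]
    cons = ConsensusReference(str(rec.seq), offset=offset)
    object.__setattr__(cons, "name", rec.id)
    return cons


def write_consensus(consensus: ConsensusReference, path) -> None:
    with open(path, "w") as fh:
        fh.write(f">{consensus.name}\n")
        seq = consensus.sequence
        for i in range(0, len(seq), 60):
            fh.write(seq[i : i + 60] + "\n")
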