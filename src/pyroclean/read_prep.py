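"""Step 1 — read ingestion, primer trimming, length filtering and dereplication.

Demultiplexed 454 reads arrive as plain or gzipped FASTA, one file per MID
pool.  Forward-primer bases are trimmed, reads are length-filtered and
truncated, and identical reads are collapsed into unique sequences whose
read count is appended to the name (``>Seq1_2343``).
"""

from __future__ import annotations

import gzip
import io
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .iupac import IUPAC_TO_BASES, compatible

__all__ = [
    "Read",
    "UniqueSequence",
    "FastaParseError",
    "ConfigError",
    "read_fasta",
    "write_fasta",
    "read_unique_fasta",
    "trim_forward_primer",
    "primer_matches",
    "filter_and_truncate",
    "dereplicate",
]


class FastaParseError(ValueError):
    """Malformed FASTA input; the message carries the offending line number."""


class ConfigError(ValueError):
    """Inconsistent pipeline parameters."""


@dataclass(frozen=True)
class Read:
    """One demultiplexed pyrosequence read."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("read id must be nonempty")
        seq = self.sequence.upper()
        for i, ch in enumerate(seq):
            if ch not in IUPAC_TO_BASES:
                raise FastaParseError(
                    f"read {self.id!r}: invalid character {ch!r} at position {i}"
                )
        if not seq:
            raise ValueError(f"read {self.id!r} has an empty sequence")
        object.__setattr__(self, "sequence", seq)

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class UniqueSequence:
    """A dereplicated sequence with its read count.

    Serialized FASTA header is ``>name_count``.
    """

    name: str
    count: int
    sequence: str

    def __post_init__(self) -> None:
        if self.count < 1:
            raise ValueError("unique-sequence count must be >= 1")

    @property
    def header(self) -> str:
        return f"{self.name}_{self.count}"

    def __len__(self) -> int:
        return len(self.sequence)


def _open_text(path) -> io.TextIOBase:
    path = Path(path)
    if path.suffix == ".gz":
        return io.TextIOWrapper(gzip.open(path, "rb"))
    return open(path)


def _validate_fasta_layout(handle: io.TextIOBase) -> None:
    """Cheap structural scan so parse errors can report a line number."""
    header_line = None
    saw_seq = False
    lineno = 0
    for lineno, line in enumerate(handle, start=1):
        stripped = line.strip()
        if not stripped:
            continue
        if stripped.startswith(">"):
            if header_line is not None and not saw_seq:
                raise FastaParseError(
                    f"line {header_line}: FASTA record has no sequence"
                )
            header_line = lineno
            saw_seq = False
        else:
            if header_line is None:
                raise FastaParseError(
                    f"line {lineno}: sequence data before any '>' header"
                )
            saw_seq = True
    if header_line is not None and not saw_seq:
        raise FastaParseError(f"line {header_line}: FASTA record has no sequence")


def read_fasta(path) -> list[Read]:
    """Parse a (possibly gzipped) FASTA file into reads, order preserved.

    Wrapped sequence lines are concatenated.  Structural problems (sequence
    before a header, a header with no sequence) raise :class:`FastaParseError`
    naming the line.
    """
    with _open_text(path) as handle:
        _validate_fasta_layout(handle)
    with _open_text(path) as handle:
        return [Read(rec.id, str(rec.seq)) for rec in SeqIO.parse(handle, "fasta")]


def write_fasta(uniques: Iterable[UniqueSequence], path) -> None:
    """Write unique sequences as FASTA with ``>name_count`` headers."""
    records = [
        SeqRecord(Seq(u.sequence), id=u.header, description="") for u in uniques
    ]
    with open(path, "w") as handle:
        SeqIO.write(records, handle, "fasta")


def read_unique_fasta(path) -> list[UniqueSequence]:
    """Read a FASTA of ``>name_count`` records back into unique sequences."""
    out = []
    for rec in read_fasta(path):
        name, _, count = rec.id.rpartition("_")
        if not name or not count.isdigit():
            raise FastaParseError(
                f"header {rec.id!r} is not of the form name_count"
            )
        out.append(UniqueSequence(name, int(count), rec.sequence))
    return out


def primer_matches(read: Read, primer: str, max_mismatch: int = 0) -> bool:
    """Ambiguity-aware test that the read begins with the primer."""
    if len(read.sequence) < len(primer):
        return False
    mism = sum(
        0 if compatible(b, p) else 1 for b, p in zip(read.sequence, primer)
    )
    return mism <= max_mismatch


def trim_forward_primer(
    read: Read,
    primer: str,
    trim_length: int | str = "full",
    max_mismatch: int = 0,
) -> Read | None:
    """Remove forward-primer bases from the 5' end of a read.

    ``trim_length="full"`` removes ``len(primer)`` bases.  An integer removes
    exactly that many, which allows reproducing datasets where fewer bases
    than the whole primer were cut.  Reads whose prefix does not match the
    primer (ambiguity-aware, ``max_mismatch`` tolerance) are dropped
    (``None`` returned) so the caller can account for them.
    """
    n = len(primer) if trim_length == "full" else int(trim_length)
    if n < 0:
        raise ConfigError("trim_length must be >= 0 or 'full'")
    if not primer_matches(read, primer, max_mismatch):
        return None
    if n >= len(read.sequence):
        return None
    return replace(read, sequence=read.sequence[n:])


def filter_and_truncate(
    reads: Sequence[Read],
    min_length: int = 170,
    max_length: int = 300,
) -> list[Read]:
    """Drop reads shorter than ``min_length``; truncate longer ones at ``max_length``.

    Length is measured after primer trimming; a read of exactly
    ``min_length`` bases is retained (only strictly shorter reads go).
    """
    if min_length > max_length:
        raise ConfigError(
            f"min_length ({min_length}) exceeds max_length ({max_length})"
        )
    out = []
    for r in reads:
        if len(r) < min_length:
            continue
        if len(r) > max_length:
            r = replace(r, sequence=r.sequence[:max_length])
        out.append(r)
    return out


def dereplicate(
    items: Sequence[Read] | Sequence[UniqueSequence],
) -> list[UniqueSequence]:
    """Collapse identical sequences into count-annotated unique sequences.

    Accepts raw reads (each weight 1) or unique sequences (weights = counts,
    so re-dereplicating after correction merges collisions and sums counts).
    The group takes the name of its first member; output is sorted by
    descending count, ties broken by name.  Total count is conserved.
    """
    groups: dict[str, UniqueSequence] = {}
    for item in items:
        seq = item.sequence
        weight = item.count if isinstance(item, UniqueSequence) else 1
        name = item.name if isinstance(item, UniqueSequence) else item.id
        if seq in groups:
            g = groups[seq]
            groups[seq] = UniqueSequence(g.name, g.count + weight, seq)
        else:
            groups[seq] = UniqueSequence(name, weight, seq)
    return sorted(groups.values(), key=lambda u: (-u.count, u.name))
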