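"""Small-RNA read preprocessing: adapter trimming, length filtering, collapsing.

Raw libraries arrive as FASTQ with the 3' sequencing adapter appended to each
insert.  The preprocessing contract is: trim the adapter, drop reads shorter
than ``min_len`` (the software floor; the gel selection upper bound is the
default ``max_len``), discard reads containing N, and collapse the survivors
to unique sequences with per-library counts.  The collapsed count total always
equals the number of retained reads — every downstream table partitions that
total, never duplicates it.

Collapsed sets round-trip through a miRDeep-style FASTA dialect whose headers
carry the count: ``>seq1_x5041``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

from Bio.SeqIO.QualityIO import FastqGeneralIterator

from ._seq import to_dna, to_rna

__all__ = [
    "CollapsedRead",
    "LibraryProfile",
    "trim_adapter",
    "filter_length",
    "collapse",
    "read_fastq",
    "write_collapsed_fasta",
    "read_collapsed_fasta",
    "preprocess_fastq",
]


@dataclass(frozen=True)
class CollapsedRead:
    """A unique small-RNA sequence and its abundance in one library."""

    sequence: str  # DNA alphabet
    count: int

    def __post_init__(self) -> None:
        if self.count < 1:
            raise ValueError("collapsed count must be >= 1")

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def rna(self) -> str:
        return to_rna(self.sequence)


@dataclass
class LibraryProfile:
    """Identity and size of one sequenced library.

    ``total_reads`` is the library size used both as the TPM denominator and
    as N1/N2 in the Audic-Claverie test; it must equal the sum of collapsed
    counts retained after preprocessing.
    """

    library_id: str
    genotype: str = ""  # e.g. HT (higher tolerance) / LT (lower tolerance)
    condition: str = ""  # irrigated / drought / rehydrated
    day: int = 0
    total_reads: int = 0
    extra: dict = field(default_factory=dict)


def trim_adapter(read: str, adapter: str, min_overlap: int = 6) -> str:
    """Remove a 3' adapter from a read.

    The longest read suffix exactly matching a prefix of the adapter is
    removed, provided the overlap is at least ``min_overlap``; a full adapter
    occurring internally is also removed together with everything 3' of it.
    Reads with no hit are returned unchanged.
    """
    if not adapter:
        raise ValueError("adapter must be non-empty")
    if min_overlap < 1:
        raise ValueError("min_overlap must be positive")
    read = to_dna(read)
    adapter = to_dna(adapter)
    # full adapter somewhere inside the read
    pos = read.find(adapter)
    if pos != -1:
        return read[:pos]
    # adapter prefix as read suffix
    longest = min(len(read), len(adapter) - 1)
    for n in range(longest, min_overlap - 1, -1):
        if read.endswith(adapter[:n]):
            return read[: len(read) - n]
    return read


def filter_length(
    reads: Iterable[str], min_len: int = 18, max_len: int = 27
) -> list[str]:
    """Keep reads with ``min_len <= length <= max_len`` (both inclusive)."""
    if min_len > max_len:
        raise ValueError("min_len must not exceed max_len")
    return [r for r in reads if min_len <= len(r) <= max_len]


def collapse(reads: Iterable[str]) -> list[CollapsedRead]:
    """Collapse reads to unique sequences with counts.

    Output is ordered by descending count, then lexicographically, so the
    collapsed set (and its FASTA serialization) is deterministic.  The count
    total equals the number of input reads.
    """
    counts: dict[str, int] = {}
    for r in reads:
        r = to_dna(r)
        counts[r] = counts.get(r, 0) + 1
    ordered = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    return [CollapsedRead(seq, n) for seq, n in ordered]


def read_fastq(path: str | Path) -> Iterator[str]:
    """Yield read sequences from a FASTQ file (qualities ignored)."""
    with open(path) as handle:
        for _title, seq, _qual in FastqGeneralIterator(handle):
            yield seq


def write_collapsed_fasta(reads: Iterable[CollapsedRead], path: str | Path) -> None:
    """Write collapsed reads as ``>seq<rank>_x<count>`` FASTA."""
    with open(path, "w") as out:
        for rank, rec in enumerate(reads, start=1):
            out.write(f">seq{rank}_x{rec.count}\n{rec.sequence}\n")


def read_collapsed_fasta(path: str | Path) -> list[CollapsedRead]:
    """Parse the ``>seq<rank>_x<count>`` dialect back into collapsed reads."""
    out: list[CollapsedRead] = []
    header = None
    chunks: list[str] = []
    with open(path) as handle:
        for line in handle:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                if header is not None:
                    out.append(_collapsed_from(header, "".join(chunks)))
                header, chunks = line[1:], []
            else:
                chunks.append(line)
    if header is not None:
        out.append(_collapsed_from(header, "".join(chunks)))
    return out


def _collapsed_from(header: str, seq: str) -> CollapsedRead:
    name = header.split()[0]
    try:
        count = int(name.rsplit("_x", 1)[1])
    except (IndexError, ValueError) as err:
        raise ValueError(f"not a collapsed-FASTA header: {header!r}") from err
    return CollapsedRead(to_dna(seq), count)


def preprocess_fastq(
    path: str | Path,
    adapter: str,
    min_len: int = 18,
    max_len: int = 27,
    min_overlap: int = 6,
) -> tuple[list[CollapsedRead], int]:
    """Trim, length-filter, drop N-containing reads, and collapse a library.

    Returns the collapsed reads and the retained-read total N (the library
    size for TPM and the count test).  Reads containing N are discarded
    before collapsing because an ambiguous base breaks downstream mismatch
    accounting.
    """
    inserts = []
    for raw in read_fastq(path):
        trimmed = trim_adapter(raw, adapter, min_overlap=min_overlap)
        if "N" in trimmed:
            continue
        if min_len <= len(trimmed) <= max_len:
            inserts.append(trimmed)
    collapsed = collapse(inserts)
    return collapsed, len(inserts)
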