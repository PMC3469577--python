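"""k-mer-indexed, mismatch-bounded mapping of short reads to a reference.

The index stores every k-mer of the forward strand of each reference record.
A read is placed by pigeonhole seeding: with a mismatch budget m, at least one
of m+1 non-overlapping k-mer seeds must be exact, so seed lookups followed by
full-length verification find every placement with <= m substitutions.  Minus
strand hits are found by seeding the read's reverse complement; coordinates
are always reported on the forward strand, 0-based half-open internally.

Reads with more placements than ``max_hits`` are flagged multi-mapped and
excluded from precursor nomination downstream.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
from Bio import SeqIO

from ._seq import revcomp, to_dna

__all__ = ["GenomicLocus", "KmerIndex", "map_read"]


@dataclass(frozen=True, order=True)
class GenomicLocus:
    """One read placement on the reference (0-based half-open)."""

    reference_id: str
    start: int
    end: int
    strand: str  # "+" or "-"
    mismatches: int = 0


class KmerIndex:
    """Exact k-mer positions over the forward strand of each reference."""

    def __init__(self, references: Mapping[str, str], k: int = 12):
        if k < 8:
            raise ValueError("seed length k must be >= 8")
        refs = {rid: to_dna(seq) for rid, seq in references.items()}
        if not refs or all(len(s) == 0 for s in refs.values()):
            raise ValueError("empty reference")
        self.k = k
        self.references = refs
        self._index: dict[str, list[tuple[str, int]]] = {}
        for rid, seq in refs.items():
            for pos in range(0, len(seq) - k + 1):
                self._index.setdefault(seq[pos : pos + k], []).append((rid, pos))
        code = {"A": 0, "C": 1, "G": 2, "T": 3}
        self._codes = {
            rid: np.array([code.get(c, 4) for c in seq], dtype=np.int8)
            for rid, seq in refs.items()
        }

    @classmethod
    def from_fasta(cls, path: str | Path, k: int = 12) -> "KmerIndex":
        refs = {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}
        return cls(refs, k=k)

    def seed_hits(self, kmer: str) -> list[tuple[str, int]]:
        return self._index.get(kmer, [])


def _mismatches(a: str, b: str, bound: int) -> int:
    """Hamming distance with early exit past ``bound``."""
    mm = 0
    for ca, cb in zip(a, b):
        if ca != cb:
            mm += 1
            if mm > bound:
                return mm
    return mm


def _scan_placements(
    seq: str, index: KmerIndex, max_mismatches: int
) -> set[tuple[str, int, int]]:
    """Vectorized full scan; used when pigeonhole seeding cannot be complete
    (read shorter than (m+1) seeds)."""
    code = {"A": 0, "C": 1, "G": 2, "T": 3}
    q = np.array([code.get(c, 5) for c in seq], dtype=np.int8)
    placements: set[tuple[str, int, int]] = set()
    for rid, ref_codes in index._codes.items():
        if len(ref_codes) < len(q):
            continue
        windows = np.lib.stride_tricks.sliding_window_view(ref_codes, len(q))
        mism = (windows != q).sum(axis=1)
        for start in np.nonzero(mism <= max_mismatches)[0]:
            placements.add((rid, int(start), int(mism[start])))
    return placements


def _forward_placements(
    seq: str, index: KmerIndex, max_mismatches: int
) -> set[tuple[str, int, int]]:
    """Placements of ``seq`` against forward reference strands."""
    k = index.k
    n_seeds = max_mismatches + 1
    if len(seq) < n_seeds * k:
        # pigeonhole would be incomplete at this budget; scan exhaustively
        return _scan_placements(seq, index, max_mismatches)
    placements: set[tuple[str, int, int]] = set()
    seen: set[tuple[str, int]] = set()
    for si in range(n_seeds):
        off = si * k
        for rid, pos in index.seed_hits(seq[off : off + k]):
            start = pos - off
            if start < 0 or start + len(seq) > len(index.references[rid]):
                continue
            if (rid, start) in seen:
                continue
            seen.add((rid, start))
            ref = index.references[rid]
            mm = _mismatches(seq, ref[start : start + len(seq)], max_mismatches)
            if mm <= max_mismatches:
                placements.add((rid, start, mm))
    return placements


def map_read(
    seq: str,
    index: KmerIndex,
    max_mismatches: int = 0,
    max_hits: int = 15,
) -> list[GenomicLocus]:
    """All placements of a read on both strands within the mismatch bound.

    Returns an empty list when the read exceeds ``max_hits`` placements
    (multi-mapped; such reads never nominate precursor loci).  Reads long
    enough for ``m+1`` pigeonhole seeds use the index; shorter reads fall
    back to a vectorized exhaustive scan, so results are complete at every
    mismatch budget.
    """
    seq = to_dna(seq)
    if len(seq) < index.k:
        raise ValueError(f"read shorter than seed length k={index.k}")
    loci: list[GenomicLocus] = []
    for rid, start, mm in _forward_placements(seq, index, max_mismatches):
        loci.append(GenomicLocus(rid, start, start + len(seq), "+", mm))
    rc = revcomp(seq)
    for rid, start, mm in _forward_placements(rc, index, max_mismatches):
        loci.append(GenomicLocus(rid, start, start + len(seq), "-", mm))
    loci.sort()
    if len(loci) > max_hits:
        return []
    return loci
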