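"""Classify collapsed reads into annotation categories and summarize libraries.

Every unique read is assigned to exactly one category by exact, full-length
substring matching against per-category annotation sequence sets, walking a
precedence order so that structural-RNA contamination (rRNA, tRNA, ...) can
never inflate the miRNA count.  Reads matching nothing fall into
``unannotated``.  Category totals partition the library size N exactly.

The summaries mirror the standard descriptive views of a small-RNA library:
a category table with unique/total counts and percents, redundant and
non-redundant length histograms, and the first-nucleotide composition of the
21 nt fraction (plant miRNAs are strongly biased toward a 5' U).
"""

from __future__ import annotations

from collections import Counter
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO

from ._seq import revcomp, to_dna, to_rna
from .diffexp import round_half_up
from .reads import CollapsedRead

__all__ = [
    "DEFAULT_PRECEDENCE",
    "AnnotationDB",
    "classify_reads",
    "size_distribution",
    "first_nt_composition",
]

#: Categories in assignment precedence order; ``unannotated`` is implicit.
DEFAULT_PRECEDENCE = (
    "rRNA",
    "tRNA",
    "snRNA",
    "snoRNA",
    "miRNA",
    "siRNA",
    "sense exon",
    "antisense exon",
)

_SEED = 16  # seed k-mer length for the exact-substring index


class AnnotationDB:
    """Per-category annotation sequences with an exact-substring index.

    Matching is sense-strand substring containment for every category except
    ``antisense exon``, which matches when the read's reverse complement is
    contained in an exon sequence.  Lookups use a 16-mer seed index over the
    annotation sequences followed by full-length verification, so queries stay
    fast on libraries with 10^5+ unique reads.
    """

    def __init__(self, sequences: Mapping[str, Sequence[str]]):
        self._seqs: dict[str, list[str]] = {
            cat: [to_dna(s) for s in seqs] for cat, seqs in sequences.items()
        }
        self._index: dict[str, dict[str, list[tuple[int, int]]]] = {}
        for cat, seqs in self._seqs.items():
            idx: dict[str, list[tuple[int, int]]] = {}
            for si, seq in enumerate(seqs):
                for pos in range(0, len(seq) - _SEED + 1):
                    idx.setdefault(seq[pos : pos + _SEED], []).append((si, pos))
            self._index[cat] = idx

    @classmethod
    def from_fasta(cls, paths: Mapping[str, str | Path]) -> "AnnotationDB":
        """Build from one FASTA per category (``{"rRNA": path, ...}``)."""
        seqs = {}
        for cat, path in paths.items():
            seqs[cat] = [str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")]
        return cls(seqs)

    def categories(self) -> list[str]:
        return list(self._seqs)

    def contains(self, category: str, read: str) -> bool:
        """True if ``read`` occurs full-length inside a category sequence."""
        base = "sense exon" if category == "antisense exon" else category
        if base not in self._seqs:
            return False
        query = revcomp(read) if category == "antisense exon" else read
        if len(query) < _SEED:
            return any(query in s for s in self._seqs[base])
        for si, pos in self._index[base].get(query[:_SEED], ()):
            if self._seqs[base][si].startswith(query, pos):
                return True
        return False


def classify_reads(
    reads: Iterable[CollapsedRead],
    db: AnnotationDB,
    precedence: Sequence[str] = DEFAULT_PRECEDENCE,
) -> pd.DataFrame:
    """Assign each unique read to its first matching category.

    Returns a table with one row per category plus a ``total small RNAs``
    row, with unique/total counts and percents (percents rounded half-up to
    two decimals).  Unique counts sum to the number of unique reads and total
    counts sum to the library size N: the classification is a partition.
    """
    if len(set(precedence)) != len(precedence):
        raise ValueError("precedence lists a category more than once")
    unique = Counter()
    total = Counter()
    for rec in reads:
        seq = to_dna(rec.sequence)
        for cat in precedence:
            if db.contains(cat, seq):
                break
        else:
            cat = "unannotated"
        unique[cat] += 1
        total[cat] += rec.count
    n_unique = sum(unique.values())
    n_total = sum(total.values())
    rows = []
    order = sorted([*precedence, "unannotated"], key=str.lower)
    for cat in order:
        rows.append(
            {
                "category": cat,
                "unique": unique[cat],
                "unique_percent": _pct(unique[cat], n_unique),
                "total": total[cat],
                "total_percent": _pct(total[cat], n_total),
            }
        )
    rows.append(
        {
            "category": "total small RNAs",
            "unique": n_unique,
            "unique_percent": float("nan"),
            "total": n_total,
            "total_percent": float("nan"),
        }
    )
    return pd.DataFrame(rows)


def _pct(count: int, total: int) -> float:
    return round_half_up(100.0 * count / total, 2) if total else 0.0


def size_distribution(
    reads: Iterable[CollapsedRead], mode: str = "redundant"
) -> dict[int, int]:
    """Read-length histogram; ``redundant`` weighs by count, ``nonredundant`` by 1."""
    if mode not in ("redundant", "nonredundant"):
        raise ValueError(f"unknown mode {mode!r}")
    hist: Counter = Counter()
    for rec in reads:
        hist[rec.length] += rec.count if mode == "redundant" else 1
    return dict(sorted(hist.items()))


def first_nt_composition(
    reads: Iterable[CollapsedRead], length: int = 21
) -> dict[str, float]:
    """Count-weighted first-nucleotide fractions among reads of one length.

    Fractions are keyed in the RNA alphabet (A/C/G/U) and sum to 1.  An empty
    result (no reads of that length) is returned as an empty dict.
    """
    counts: Counter = Counter()
    for rec in reads:
        if rec.length == length:
            counts[to_rna(rec.sequence[0])] += rec.count
    total = sum(counts.values())
    if total == 0:
        return {}
    return {nt: counts[nt] / total for nt in "ACGU" if counts[nt]}
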