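"""Homology-based family assignment and naming of candidate mature miRNAs.

Candidates are compared ungapped against a reference set of known mature
miRNAs (sorghum-like, miRBase-style names such as ``sbi-MIR164b``), sliding
over every offset compatible with a length difference of at most
``max_len_diff``.  A candidate is assigned to the family of the reference(s)
it matches with the fewest mismatches, up to ``max_mm`` (default 2, the
conventional plant-homolog allowance).  Candidates equally close to two
different families are flagged ambiguous rather than silently resolved.

Within a family, a single distinct sequence is named ``ssp-miR<fam>``;
multiple distinct sequences are numbered ``seq1..seqN`` by descending total
abundance, then lexicographically.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from ._seq import to_dna, to_rna

__all__ = ["MatureAssignment", "family_of", "match_mature", "assign_names"]

_FAMILY_RE = re.compile(r"(?:^|-)(?:miR|MIR)(\d+)", re.IGNORECASE)


def family_of(reference_name: str) -> str:
    """Family label from a miRBase-style name: ``sbi-MIR164b`` -> ``miR164``."""
    m = _FAMILY_RE.search(reference_name)
    if not m:
        raise ValueError(f"cannot parse family from {reference_name!r}")
    return f"miR{m.group(1)}"


def _best_offset_mismatches(a: str, b: str, max_len_diff: int) -> int:
    """Minimum mismatch count over ungapped offsets of the shorter in the longer.

    The shorter sequence slides along the longer; overhanging positions of the
    longer sequence are not counted as mismatches (length tolerance is capped
    by ``max_len_diff`` before calling).
    """
    if len(a) > len(b):
        a, b = b, a
    best = len(a) + 1
    for off in range(0, len(b) - len(a) + 1):
        mm = sum(1 for x, y in zip(a, b[off:]) if x != y)
        best = min(best, mm)
    return best


@dataclass
class MatureAssignment:
    candidate: str  # DNA alphabet
    matched_references: list[str]
    family: str | None
    mismatches: int | None
    ambiguous: bool = False
    assigned_name: str = ""
    total_count: int = 0

    @property
    def rna(self) -> str:
        return to_rna(self.candidate)


def match_mature(
    candidate: str,
    reference_set: dict[str, str],
    max_mm: int = 2,
    max_len_diff: int = 2,
) -> MatureAssignment:
    """Best ungapped matches of a candidate against the reference mature set.

    Returns every reference achieving the minimum mismatch count when that
    minimum is <= ``max_mm``; the family is taken from the matched references
    and flagged ambiguous when two families tie at the minimum.
    """
    if not reference_set:
        raise ValueError("empty reference set")
    cand = to_dna(candidate)
    best_mm = max_mm + 1
    hits: list[str] = []
    for name, refseq in reference_set.items():
        ref = to_dna(refseq)
        if abs(len(ref) - len(cand)) > max_len_diff:
            continue
        mm = _best_offset_mismatches(cand, ref, max_len_diff)
        if mm < best_mm:
            best_mm, hits = mm, [name]
        elif mm == best_mm:
            hits.append(name)
    if best_mm > max_mm:
        return MatureAssignment(cand, [], None, None)
    families = sorted({family_of(h) for h in hits})
    return MatureAssignment(
        candidate=cand,
        matched_references=sorted(hits),
        family=families[0],
        mismatches=best_mm,
        ambiguous=len(families) > 1,
    )


def assign_names(
    assignments: list[MatureAssignment], prefix: str = "ssp"
) -> list[MatureAssignment]:
    """Apply the naming scheme in place and return the assignments.

    Families with one distinct assigned sequence get ``<prefix>-miR<fam>``;
    families with several get ``seq1..seqN`` suffixes ordered by descending
    ``total_count``, then sequence.  Unassigned candidates keep an empty name.
    """
    by_family: dict[str, list[MatureAssignment]] = {}
    for a in assignments:
        if a.family is not None:
            by_family.setdefault(a.family, []).append(a)
    for family, members in by_family.items():
        distinct: dict[str, list[MatureAssignment]] = {}
        for a in members:
            distinct.setdefault(a.candidate, []).append(a)
        if len(distinct) == 1:
            name = f"{prefix}-{family}"
            for a in members:
                a.assigned_name = name
        else:
            ordered = sorted(
                distinct.items(),
                key=lambda kv: (-max(a.total_count for a in kv[1]), kv[0]),
            )
            for i, (_seq, group) in enumerate(ordered, start=1):
                for a in group:
                    a.assigned_name = f"{prefix}-{family}seq{i}"
    return assignments
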