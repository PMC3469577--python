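"""Hairpin precursor excision, folding, and the four acceptance criteria.

A mapped read nominates a candidate precursor: a 250 nt window centered on
the read is excised from the reference, folded, and judged against four
criteria: (1) the window folds into a stem-loop with the mature read in one
arm, (2) at most six mature positions are unpaired against the star arm,
(3) the minimum free energy is negative, and (4) the G/C content lies within
30-70%.

Folding minimizes a simple additive base-pair energy model (G-C -3.0,
A-U -2.0, G-U -1.0 kcal/mol, minimum hairpin loop of 3 unpaired bases, no
pseudoknots) by Nussinov-style dynamic programming with a deterministic
traceback: pairing (i, j) is preferred over bifurcation, and among
bifurcations the smallest split point wins.  The model is intentionally not a
nearest-neighbor thermodynamic model; its MFE values are comparable only
within this package (structure topology, not published free energies, is
what the criteria consume).  An external folder honouring the same
``fold(seq) -> (dot-bracket, MFE)`` contract can be slotted in where
published-grade energies are wanted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._seq import to_dna
from .mapping import GenomicLocus

try:  # pragma: no cover - exercised implicitly by every fold call
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def wrap(f):
            return f

        return wrap(args[0]) if args and callable(args[0]) else wrap


__all__ = [
    "PAIR_ENERGY",
    "MIN_LOOP",
    "HairpinCandidate",
    "fold",
    "gc_content",
    "extract_window",
    "locate_star",
    "evaluate_precursor",
    "discover_hairpins",
]

MIN_LOOP = 3  # minimum unpaired bases in a hairpin loop

_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}

# pair energies, kcal/mol in model units; 0.0 = not pairable
PAIR_ENERGY = np.zeros((4, 4))
PAIR_ENERGY[_CODE["G"], _CODE["C"]] = PAIR_ENERGY[_CODE["C"], _CODE["G"]] = -3.0
PAIR_ENERGY[_CODE["A"], _CODE["T"]] = PAIR_ENERGY[_CODE["T"], _CODE["A"]] = -2.0
PAIR_ENERGY[_CODE["G"], _CODE["T"]] = PAIR_ENERGY[_CODE["T"], _CODE["G"]] = -1.0


def _encode(seq: str) -> np.ndarray:
    seq = to_dna(seq)
    try:
        return np.array([_CODE[c] for c in seq], dtype=np.int8)
    except KeyError as err:
        raise ValueError(f"invalid nucleotide {err.args[0]!r}") from err


@njit(cache=False)
def _fill(codes, energy, min_loop):  # pragma: no cover - numba kernel
    n = codes.shape[0]
    e = np.zeros((n, n))
    for span in range(min_loop + 1, n):
        for i in range(0, n - span):
            j = i + span
            best = e[i][i] + e[i + 1][j]  # k = i bifurcation (i unpaired)
            for k in range(i + 1, j):
                v = e[i][k] + e[k + 1][j]
                if v < best:
                    best = v
            pe = energy[codes[i], codes[j]]
            if pe < 0.0:
                v = e[i + 1][j - 1] + pe
                if v < best:
                    best = v
            e[i][j] = best
    return e


def _traceback(e: np.ndarray, codes: np.ndarray) -> list[tuple[int, int]]:
    """Recover one optimal structure; pair beats bifurcation, smallest split wins."""
    n = codes.shape[0]
    tol = 1e-9
    pairs: list[tuple[int, int]] = []
    stack = [(0, n - 1)]
    while stack:
        i, j = stack.pop()
        if j - i <= MIN_LOOP:
            continue
        if e[i, j] >= -tol:
            continue
        pe = PAIR_ENERGY[codes[i], codes[j]]
        if pe < 0.0 and abs(e[i, j] - (e[i + 1, j - 1] + pe)) < tol:
            pairs.append((i, j))
            stack.append((i + 1, j - 1))
            continue
        for k in range(i, j):
            if abs(e[i, j] - (e[i, k] + e[k + 1, j])) < tol:
                stack.append((i, k))
                stack.append((k + 1, j))
                break
        else:  # pragma: no cover - defensive; recurrence guarantees a split
            raise AssertionError("traceback failed to find an optimal split")
    return pairs


def fold(sequence: str) -> tuple[str, float]:
    """Minimum-energy structure of ``sequence`` as (dot-bracket, MFE).

    MFE is 0.0 for a sequence admitting no pair; otherwise negative.
    """
    codes = _encode(sequence)
    n = codes.shape[0]
    if n < 2:
        return "." * n, 0.0
    e = _fill(codes, PAIR_ENERGY, MIN_LOOP)
    pairs = _traceback(e, codes)
    db = ["."] * n
    for i, j in pairs:
        db[i], db[j] = "(", ")"
    return "".join(db), float(e[0, n - 1])


def pair_partners(structure: str) -> list[int]:
    """Partner index per position from dot-bracket (-1 = unpaired)."""
    partners = [-1] * len(structure)
    stack: list[int] = []
    for i, c in enumerate(structure):
        if c == "(":
            stack.append(i)
        elif c == ")":
            if not stack:
                raise ValueError("unbalanced structure string")
            j = stack.pop()
            partners[i], partners[j] = j, i
    if stack:
        raise ValueError("unbalanced structure string")
    return partners


def gc_content(sequence: str) -> float:
    """G+C percentage of a sequence."""
    if not sequence:
        raise ValueError("empty sequence")
    seq = to_dna(sequence)
    return 100.0 * sum(c in "GC" for c in seq) / len(seq)


def extract_window(
    reference: str, locus: GenomicLocus, window: int = 250
) -> tuple[str, int]:
    """Excise a window centered on a mapped read.

    Returns the window sequence (reverse-complemented for minus-strand loci)
    and the 0-based offset of the mature read within the window.  Windows are
    truncated at reference ends rather than shifted.
    """
    from ._seq import revcomp

    ref = to_dna(reference)
    if not (0 <= locus.start < locus.end <= len(ref)):
        raise ValueError("locus outside reference")
    read_len = locus.end - locus.start
    if window < read_len:
        raise ValueError("window smaller than the mapped read")
    left = (window - read_len) // 2
    w_start = max(0, locus.start - left)
    w_end = min(len(ref), w_start + window)
    w_start = max(0, min(w_start, w_end - read_len))
    seq = ref[w_start:w_end]
    if locus.strand == "-":
        seq = revcomp(seq)
        offset = w_end - locus.end
    else:
        offset = locus.start - w_start
    return seq, offset


def locate_star(
    structure: str, mature_span: tuple[int, int]
) -> tuple[tuple[int, int], int]:
    """Star span and unpaired-mature count for a folded candidate.

    The star span covers the positions pairing with the mature, extended by
    the canonical 2 nt 3' overhang of the mature/star duplex.  Raises
    ``ValueError`` when the mature is not confined to one arm (it pairs with
    itself across the terminal loop, or has partners on both sides).
    """
    ms, me = mature_span
    partners = pair_partners(structure)
    if not (0 <= ms < me <= len(structure)):
        raise ValueError("mature span outside structure")
    mature_partners = [partners[i] for i in range(ms, me)]
    paired = [p for p in mature_partners if p >= 0]
    mismatches = sum(1 for p in mature_partners if p < 0)
    if not paired:
        raise ValueError("mature entirely unpaired: no arm")
    if any(ms <= p < me for p in paired):
        raise ValueError("mature span crosses the hairpin loop")
    left = [p for p in paired if p < ms]
    right = [p for p in paired if p >= me]
    if left and right:
        raise ValueError("mature pairs into both arms")
    lo, hi = min(paired), max(paired) + 1
    # 2 nt 3' overhang: the star's 3' end is its right end in sequence coords
    hi = min(len(structure), hi + 2)
    return (lo, hi), mismatches


def _is_stem_loop(structure: str, mature_span: tuple[int, int]) -> bool:
    """Mature confined to one arm of a single stem: partners of successive
    mature positions strictly decrease (a nested ladder through one loop),
    and at least 60% of mature positions are paired."""
    ms, me = mature_span
    partners = pair_partners(structure)
    mature_partners = [partners[i] for i in range(ms, me)]
    paired = [p for p in mature_partners if p >= 0]
    if len(paired) < 0.6 * (me - ms):
        return False
    if any(ms <= p < me for p in paired):
        return False
    if [p for p in paired if p < ms] and [p for p in paired if p >= me]:
        return False
    return all(a > b for a, b in zip(paired, paired[1:]))


@dataclass
class HairpinCandidate:
    """An excised window with structure, energy, and the criteria verdict."""

    window_seq: str
    window_locus: GenomicLocus | None
    structure: str
    mfe: float
    gc: float
    mature_span: tuple[int, int]
    arm: str = ""
    star_span: tuple[int, int] | None = None
    star_mismatches: int | None = None
    passed: bool = False
    failed_criteria: list[str] = field(default_factory=list)


def evaluate_precursor(
    window_seq: str,
    mature_span: tuple[int, int],
    window_locus: GenomicLocus | None = None,
    max_star_mismatches: int = 6,
    gc_min: float = 30.0,
    gc_max: float = 70.0,
    criteria: tuple[str, ...] = ("stem_loop", "star", "mfe", "gc"),
) -> HairpinCandidate:
    """Fold a window and apply the precursor criteria.

    The verdict is the conjunction of the enabled criteria; every violated
    criterion is listed in ``failed_criteria``.
    """
    structure, mfe = fold(window_seq)
    gc = gc_content(window_seq)
    cand = HairpinCandidate(
        window_seq=to_dna(window_seq),
        window_locus=window_locus,
        structure=structure,
        mfe=mfe,
        gc=gc,
        mature_span=mature_span,
    )
    failed = []
    stem_ok = _is_stem_loop(structure, mature_span)
    if "stem_loop" in criteria and not stem_ok:
        failed.append("stem_loop")
    try:
        star_span, star_mm = locate_star(structure, mature_span)
        cand.star_span = star_span
        cand.star_mismatches = star_mm
        cand.arm = "5p" if star_span[0] >= mature_span[1] else "3p"
        if "star" in criteria and star_mm > max_star_mismatches:
            failed.append("star")
    except ValueError:
        if "star" in criteria:
            failed.append("star")
        if "stem_loop" in criteria and "stem_loop" not in failed:
            failed.append("stem_loop")
    if "mfe" in criteria and not mfe < 0:
        failed.append("mfe")
    if "gc" in criteria and not (gc_min <= gc <= gc_max):
        failed.append("gc")
    cand.failed_criteria = failed
    cand.passed = not failed
    return cand


def discover_hairpins(
    references: dict[str, str],
    loci: list[tuple[str, GenomicLocus]],
    window: int = 250,
    max_star_mismatches: int = 6,
    gc_min: float = 30.0,
    gc_max: float = 70.0,
) -> dict[str, HairpinCandidate]:
    """Evaluate one candidate per (read sequence, locus) pair.

    ``loci`` pairs each candidate mature sequence with one of its genomic
    placements; windows identical in (reference, span, strand) are folded
    once.  Returns the best candidate per mature sequence (a pass wins over
    any fail; ties keep the first in locus order).
    """
    best: dict[str, HairpinCandidate] = {}
    cache: dict[tuple, HairpinCandidate] = {}
    for seq, locus in loci:
        key = (locus.reference_id, locus.start, locus.end, locus.strand)
        if key in cache:
            cand = cache[key]
        else:
            wseq, offset = extract_window(
                references[locus.reference_id], locus, window=window
            )
            cand = evaluate_precursor(
                wseq,
                (offset, offset + (locus.end - locus.start)),
                window_locus=locus,
                max_star_mismatches=max_star_mismatches,
                gc_min=gc_min,
                gc_max=gc_max,
            )
            cache[key] = cand
        if seq not in best or (cand.passed and not best[seq].passed):
            best[seq] = cand
    return best
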