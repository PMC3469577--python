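"""Complementarity-based miRNA target scanning and expectation scoring.

A miRNA is paired antiparallel against every window of a sense-strand
transcript (miRNA 5'->3' against target 3'->5') and the alignment is scored
with an additive expectation penalty: Watson-Crick pair 0, G:U wobble 0.5,
mismatch 1.0, with every penalty doubled at miRNA positions 2-13 from the 5'
end (the seed region, where pairing defects disable silencing most strongly).
E = 0 means perfect complementarity; sites with E <= e_max are reported.

The inhibition-type call follows the central-site rule: a single
non-Watson-Crick position anywhere in miRNA positions 9-11 predicts
translational inhibition (the slicing site is blocked); otherwise cleavage.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np

from ._seq import to_dna, to_rna

__all__ = [
    "TargetHit",
    "expectation_score",
    "position_penalties",
    "inhibition_type",
    "scan_targets",
]

MISMATCH_PENALTY = 1.0
WOBBLE_PENALTY = 0.5
GAP_PENALTY = 2.0  # reserved for the gapped variant
SEED_SPAN = (2, 13)  # 1-based inclusive miRNA positions with doubled penalty
CENTRAL_SPAN = (9, 11)  # central positions deciding cleavage vs translation

_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}

# per-pair base penalty, indexed [mirna_base, target_base]
_PAIR_PENALTY = np.full((4, 4), MISMATCH_PENALTY)
for _a, _b in (("A", "T"), ("T", "A"), ("G", "C"), ("C", "G")):
    _PAIR_PENALTY[_CODE[_a], _CODE[_b]] = 0.0
for _a, _b in (("G", "T"), ("T", "G")):
    _PAIR_PENALTY[_CODE[_a], _CODE[_b]] = WOBBLE_PENALTY


def _encode(seq: str) -> np.ndarray:
    seq = to_dna(seq)
    if set(seq) - set("ACGT"):
        raise ValueError("sequence contains non-ACGU characters")
    return np.array([_CODE[c] for c in seq], dtype=np.int8)


def position_penalties(mirna: str, target_site: str) -> np.ndarray:
    """Per-position penalties of an ungapped antiparallel duplex.

    ``mirna`` and ``target_site`` are both given 5'->3'; position i of the
    miRNA pairs with position L-i+1 of the target fragment.  Seed doubling is
    applied.  Raises on length mismatch (ungapped register).
    """
    mi = _encode(mirna)
    ta = _encode(target_site)[::-1]  # antiparallel register
    if mi.shape != ta.shape:
        raise ValueError("ungapped scoring requires equal fragment lengths")
    pen = _PAIR_PENALTY[mi, ta]
    pos = np.arange(1, len(mi) + 1)
    seed = (pos >= SEED_SPAN[0]) & (pos <= SEED_SPAN[1])
    pen = pen * np.where(seed, 2.0, 1.0)
    return pen


def expectation_score(mirna: str, target_site: str) -> float:
    """Total expectation penalty E of a miRNA/target duplex (0 = perfect)."""
    return float(position_penalties(mirna, target_site).sum())


def inhibition_type(mirna: str, target_site: str) -> str:
    """``"translation"`` if any central position (9-11) is non-Watson-Crick,
    else ``"cleavage"``.  A wobble counts as a pairing defect here."""
    mi = _encode(mirna)
    ta = _encode(target_site)[::-1]
    if mi.shape != ta.shape:
        raise ValueError("ungapped scoring requires equal fragment lengths")
    base = _PAIR_PENALTY[mi, ta]
    lo, hi = CENTRAL_SPAN
    central = base[lo - 1 : hi]
    return "translation" if np.any(central > 0) else "cleavage"


@dataclass
class TargetHit:
    """One predicted miRNA binding site on a transcript."""

    mirna_name: str
    transcript_id: str
    start: int  # 1-based inclusive on the transcript
    end: int
    expectation: float
    mirna_fragment: str  # RNA, 5'->3'
    target_fragment: str  # RNA, 5'->3'
    inhibition: str


def scan_targets(
    mirna: str,
    transcript: str,
    e_max: float = 3.0,
    mirna_name: str = "",
    transcript_id: str = "",
) -> list[TargetHit]:
    """All ungapped sites on a sense-strand transcript with E <= e_max.

    The transcript is scanned window by window at the miRNA's length; spans
    are reported 1-based inclusive.  Scoring is vectorized over windows.
    """
    mi = _encode(mirna)
    tr_str = to_dna(transcript)
    tr = _encode(tr_str)
    m, n = len(mi), len(tr)
    if n < m:
        raise ValueError("transcript shorter than miRNA")
    # windows[w, i] = transcript base at window w, antiparallel register i
    idx = np.arange(n - m + 1)[:, None] + np.arange(m)[None, :][:, ::-1]
    pen = _PAIR_PENALTY[mi[None, :], tr[idx]]
    pos = np.arange(1, m + 1)
    seed = (pos >= SEED_SPAN[0]) & (pos <= SEED_SPAN[1])
    scores = (pen * np.where(seed, 2.0, 1.0)[None, :]).sum(axis=1)
    hits = []
    for w in np.nonzero(scores <= e_max + 1e-9)[0]:
        frag = tr_str[w : w + m]
        hits.append(
            TargetHit(
                mirna_name=mirna_name,
                transcript_id=transcript_id,
                start=int(w) + 1,
                end=int(w) + m,
                expectation=float(scores[w]),
                mirna_fragment=to_rna(to_dna(mirna)),
                target_fragment=to_rna(to_dna(frag)),
                inhibition=inhibition_type(mirna, frag),
            )
        )
    return hits


def scan_transcriptome(
    mirnas: dict[str, str],
    transcripts: dict[str, str],
    e_max: float = 3.0,
) -> list[TargetHit]:
    """Scan every miRNA against every transcript."""
    hits: list[TargetHit] = []
    for name, mir in mirnas.items():
        for tid, tseq in transcripts.items():
            if len(tseq) >= len(mir):
                hits.extend(
                    scan_targets(
                        mir, tseq, e_max=e_max, mirna_name=name, transcript_id=tid
                    )
                )
    return hits
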