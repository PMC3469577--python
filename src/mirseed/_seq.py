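"""Small sequence utilities shared across the package.

Sequences are stored in the DNA alphabet (A/C/G/T) and converted to RNA
(U for T) only at report time, so mismatch accounting is uniform internally.
"""

from __future__ import annotations

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def to_dna(seq: str) -> str:
    """Normalize a nucleotide string to upper-case DNA (U -> T)."""
    return seq.upper().replace("U", "T")


def to_rna(seq: str) -> str:
    """Render a stored DNA string in the RNA alphabet (T -> U)."""
    return seq.upper().replace("T", "U")


def revcomp(seq: str) -> str:
    """Reverse complement in the DNA alphabet."""
    return seq.translate(_COMPLEMENT)[::-1]


def is_valid(seq: str, allow_n: bool = True) -> bool:
    allowed = set("ACGTN" if allow_n else "ACGT")
    return bool(seq) and set(to_dna(seq)) <= allowed
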