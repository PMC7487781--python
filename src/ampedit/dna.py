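"""Small DNA sequence helpers shared across modules."""

from __future__ import annotations

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

#: IUPAC nucleotide codes used for PAM patterns.
IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
    "N": "ACGT",
}


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (case preserved, N allowed)."""
    return seq.translate(_COMPLEMENT)[::-1]


def is_strict_dna(seq: str) -> bool:
    """True if *seq* is non-empty and contains only uppercase A/C/G/T."""
    return bool(seq) and all(c in "ACGT" for c in seq)


def matches_iupac(seq: str, pattern: str) -> bool:
    """Match *seq* against an IUPAC *pattern* of equal length."""
    if len(seq) != len(pattern):
        return False
    return all(base in IUPAC[p] for base, p in zip(seq, pattern.upper()))
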