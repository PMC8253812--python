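"""Small nucleotide-sequence helpers shared across the package.

Coordinates are 0-based half-open everywhere. Sequences are uppercase
ACGTN strings; IUPAC ambiguity codes are supported only where a PAM
pattern is matched.
"""

from __future__ import annotations

COMPLEMENT = str.maketrans("ACGTNRYSWKMBDHV", "TGCANYRSWMKVHDB")

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
    "N": "ACGT",
}


def revcomp(seq: str) -> str:
    return seq.translate(COMPLEMENT)[::-1]


def gc_content(seq: str) -> float:
    """GC fraction of a sequence (N excluded from the denominator)."""
    s = seq.upper()
    acgt = sum(s.count(b) for b in "ACGT")
    if acgt == 0:
        return 0.0
    return (s.count("G") + s.count("C")) / acgt


def hamming(a: str, b: str) -> int:
    """Substitution count between equal-length strings; N mismatches everything."""
    if len(a) != len(b):
        raise ValueError("hamming() requires equal-length sequences")
    return sum(1 for x, y in zip(a, b) if x != y or x == "N" or y == "N")


def matches_iupac(seq: str, pattern: str) -> bool:
    """True if `seq` matches the IUPAC `pattern` position by position."""
    if len(seq) != len(pattern):
        return False
    return all(base in IUPAC.get(code, "") for base, code in zip(seq, pattern))


def concrete_from_iupac(pattern: str, rng) -> str:
    """Draw one concrete ACGT realization of an IUPAC pattern."""
    return "".join(IUPAC[code][rng.integers(len(IUPAC[code]))] for code in pattern)


def phred_to_scores(qual: str, offset: int = 33) -> list[int]:
    return [ord(c) - offset for c in qual]
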