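"""Low-level DNA string helpers used across modules.

Coordinates are 0-based, half-open, on the top strand throughout the package.
Circular sequences are compared via their lexicographically minimal rotation.
"""

from __future__ import annotations

from Bio.Data import CodonTable

from .errors import AlphabetError

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")

_STANDARD = CodonTable.unambiguous_dna_by_id[1]
CODON_TO_AA: dict[str, str] = dict(_STANDARD.forward_table)
STOP_CODONS: frozenset[str] = frozenset(_STANDARD.stop_codons)

DNA_ALPHABET = frozenset("ACGT")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (case preserved)."""
    return seq.translate(_COMPLEMENT)[::-1]


def is_dna(seq: str) -> bool:
    return bool(seq) and set(seq.upper()) <= DNA_ALPHABET


def require_dna(seq: str, what: str = "sequence") -> str:
    """Uppercase ``seq`` after checking it is a nonempty A/C/G/T string."""
    if not seq or not is_dna(seq):
        raise AlphabetError(f"{what} must be a nonempty string over A/C/G/T, got {seq!r}")
    return seq.upper()


def min_rotation(s: str) -> str:
    """Lexicographically minimal rotation of ``s`` (Booth's algorithm)."""
    if not s:
        return s
    doubled = s + s
    n = len(s)
    f = [-1] * len(doubled)
    k = 0
    for j in range(1, len(doubled)):
        sj = doubled[j]
        i = f[j - k - 1]
        while i != -1 and sj != doubled[k + i + 1]:
            if sj < doubled[k + i + 1]:
                k = j - i - 1
            i = f[i]
        if sj != doubled[k + i + 1]:
            if sj < doubled[k]:
                k = j
            f[j - k] = -1
        else:
            f[j - k] = i + 1
    return doubled[k:k + n]


def rotations_equal(a: str, b: str) -> bool:
    """True iff circular sequences ``a`` and ``b`` are equal up to rotation."""
    return len(a) == len(b) and min_rotation(a) == min_rotation(b)


def circular_slice(seq: str, start: int, end: int) -> str:
    """Slice [start, end) of a circular sequence; wraps when end <= start."""
    n = len(seq)
    start %= n
    end %= n
    if end > start:
        return seq[start:end]
    return seq[start:] + seq[:end]


def translate_codon(codon: str) -> str:
    """Single-letter amino acid for ``codon``; '*' for stop."""
    if codon in STOP_CODONS:
        return "*"
    return CODON_TO_AA[codon]


def translate(seq: str) -> str:
    """Translate in-frame codons of ``seq`` (truncated to a codon multiple).

    Stops are rendered as '*' and translation does NOT halt at them; callers
    that care about open reading frames handle stops explicitly.
    """
    return "".join(translate_codon(seq[i:i + 3]) for i in range(0, len(seq) - 2, 3))
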