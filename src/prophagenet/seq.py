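"""Basic nucleotide utilities: GC content, IUPAC-aware reverse complement,
and degenerate-motif matching.

All functions uppercase their input, so comparisons are case-insensitive.
Ambiguous bases (``N`` and the other IUPAC degeneracy codes) are handled
explicitly: ``N`` never contributes to GC/AT content, and motif matching
expands every degeneracy code to its base set.
"""

from __future__ import annotations

import re

# IUPAC nucleotide degeneracy codes -> set of concrete bases.
IUPAC_BASES: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

IUPAC_COMPLEMENT: dict[str, str] = {
    "A": "T", "T": "A", "C": "G", "G": "C",
    "R": "Y", "Y": "R", "K": "M", "M": "K",
    "B": "V", "V": "B", "D": "H", "H": "D",
    "S": "S", "W": "W", "N": "N",
}

DNA_ALPHABET = frozenset("ACGTN")
# 20 standard residues plus X (unknown).
PROTEIN_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYX")


def gc_content(sequence: str) -> float:
    """Fraction (#G + #C) / (#A + #C + #G + #T) of a DNA sequence.

    ``N`` bases are excluded from both numerator and denominator; a sequence
    consisting only of ``N`` raises ``ValueError`` ("no informative bases").
    """
    seq = sequence.upper()
    if not seq:
        raise ValueError("empty sequence")
    bad = set(seq) - DNA_ALPHABET
    if bad:
        raise ValueError(f"non-DNA characters in sequence: {sorted(bad)}")
    informative = sum(seq.count(b) for b in "ACGT")
    if informative == 0:
        raise ValueError("no informative bases")
    return (seq.count("G") + seq.count("C")) / informative


def at_content(sequence: str) -> float:
    """Complement of :func:`gc_content` over informative bases."""
    return 1.0 - gc_content(sequence)


def reverse_complement(motif: str) -> str:
    """Reverse complement of a (possibly degenerate) IUPAC DNA string."""
    seq = motif.upper()
    try:
        return "".join(IUPAC_COMPLEMENT[b] for b in reversed(seq))
    except KeyError as exc:
        raise ValueError(f"non-IUPAC character in motif: {exc.args[0]!r}") from None


def is_palindrome(motif: str) -> bool:
    """True when a motif equals its own reverse complement (e.g. GAATTC, GANTC)."""
    seq = motif.upper()
    return seq == reverse_complement(seq)


def iupac_regex(motif: str) -> re.Pattern[str]:
    """Compile a degenerate motif to a regex over concrete A/C/G/T text.

    The pattern matches windows made of concrete bases only: an ``N`` in the
    *motif* matches any base, but an ``N`` in the *sequence* matches nothing.
    """
    parts = []
    for b in motif.upper():
        if b not in IUPAC_BASES:
            raise ValueError(f"non-IUPAC character in motif: {b!r}")
        bases = sorted(IUPAC_BASES[b])
        parts.append(bases[0] if len(bases) == 1 else "[" + "".join(bases) + "]")
    return re.compile("".join(parts))


def matches_iupac(motif: str, window: str) -> bool:
    """True if a concrete DNA window matches a degenerate motif position-wise."""
    motif = motif.upper()
    window = window.upper()
    if len(motif) != len(window):
        return False
    for m, w in zip(motif, window):
        if m not in IUPAC_BASES:
            raise ValueError(f"non-IUPAC character in motif: {m!r}")
        if w not in IUPAC_BASES[m]:
            return False
    return True
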