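"""IUPAC nucleotide-code utilities shared by assay design and coverage matching.

A degenerate oligonucleotide is written in the IUPAC one-letter alphabet, where
each letter denotes a set of plain bases (e.g. D = {A,G,T}, W = {A,T}).  These
helpers expand, complement and pattern-match such strings.  Matching follows
the convention used for in silico primer coverage work: a degenerate letter on
the *pattern* (oligo) side matches any base in its class, while any ambiguity
character on the *target* side is treated as unmatchable.
"""
from __future__ import annotations

import itertools
import re
from functools import lru_cache
from typing import Iterator

#: IUPAC code -> the set of plain bases it denotes (as a sorted string).
IUPAC_CLASSES: dict[str, str] = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")

#: plain-base alphabet set -> IUPAC code, inverse of :data:`IUPAC_CLASSES`.
CODE_FOR_ALLELES: dict[frozenset[str], str] = {
    frozenset(bases): code for code, bases in IUPAC_CLASSES.items()
}


def validate_iupac(sequence: str) -> str:
    """Upper-case *sequence* and raise ``ValueError`` on non-IUPAC characters."""
    seq = sequence.upper()
    bad = set(seq) - IUPAC_CLASSES.keys()
    if bad:
        raise ValueError(f"non-IUPAC characters in sequence: {sorted(bad)}")
    return seq


def class_size(code: str) -> int:
    return len(IUPAC_CLASSES[code])


def degeneracy(sequence: str) -> int:
    """Number of expanded plain sequences = product of per-position class sizes."""
    seq = validate_iupac(sequence)
    n = 1
    for c in seq:
        n *= class_size(c)
    return n


def count_degenerate_positions(sequence: str) -> int:
    """Number of positions whose IUPAC class covers more than one base."""
    seq = validate_iupac(sequence)
    return sum(1 for c in seq if class_size(c) > 1)


def iter_expansions(sequence: str) -> Iterator[str]:
    seq = validate_iupac(sequence)
    for combo in itertools.product(*(IUPAC_CLASSES[c] for c in seq)):
        yield "".join(combo)


def expand(sequence: str) -> set[str]:
    """All plain ACGT sequences covered by a degenerate string."""
    return set(iter_expansions(sequence))


def reverse_complement(sequence: str) -> str:
    return validate_iupac(sequence).translate(_COMPLEMENT)[::-1]


@lru_cache(maxsize=256)
def compile_pattern(sequence: str) -> re.Pattern[str]:
    """Regex whose character classes contain only plain bases.

    Because every class is built from A/C/G/T, a target window containing an
    ambiguity character (N, R, ...) can never match — which is exactly the
    conservative non-match rule used for coverage analysis.
    """
    seq = validate_iupac(sequence)
    parts = []
    for c in seq:
        bases = IUPAC_CLASSES[c]
        parts.append(bases if len(bases) == 1 else f"[{bases}]")
    return re.compile("".join(parts))


def matches(pattern: str, window: str) -> bool:
    """Position-wise IUPAC match of equal-length *pattern* against *window*.

    The window must consist of plain A/C/G/T at every position for a match;
    any other character (ambiguity code, gap) makes the position a mismatch.
    """
    pat = validate_iupac(pattern)
    if len(pat) != len(window):
        raise ValueError(
            f"pattern length {len(pat)} != window length {len(window)}"
        )
    return compile_pattern(pat).fullmatch(window.upper()) is not None
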