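"""Degenerate-base algebra over the 15-letter IUPAC DNA alphabet.

Every ambiguity code denotes a nonempty subset of {A, C, G, T}; a degenerate
primer is synthesized as the equimolar mixture of all its expansions.  This
module provides the primitives the rest of the package is built on:

* position-wise matching semantics (exact / degenerate match / mismatch),
* the minimal covering code for two codes (set union, e.g. A/G -> R),
* complementation and reverse complementation of degenerate sequences,
* expansion enumeration and the degeneracy product (expansion count).

Sequences are plain Python strings, normalized to uppercase DNA (RNA ``U``
is mapped to ``T``) before any operation.
"""

from __future__ import annotations

from itertools import product
from math import prod
from typing import Iterable, Optional

__all__ = [
    "IUPAC_CODES",
    "EXACT",
    "DEGENERATE",
    "MISMATCH",
    "AlphabetError",
    "BoundedExpansionError",
    "normalize",
    "base_set",
    "base_union",
    "degeneracy",
    "matches",
    "complement",
    "complement_sequence",
    "reverse_complement",
    "degeneracy_product",
    "expand",
]

#: code -> set of plain bases it stands for
IUPAC_CODES: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "M": frozenset("AC"),
    "K": frozenset("GT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "H": frozenset("ACT"),
    "B": frozenset("CGT"),
    "V": frozenset("ACG"),
    "D": frozenset("AGT"),
    "N": frozenset("ACGT"),
}

_SET_TO_CODE: dict[frozenset[str], str] = {s: c for c, s in IUPAC_CODES.items()}

_BASE_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: code -> complementary code (R<->Y, M<->K, S, W self, H<->D, B<->V, N self)
_CODE_COMPLEMENT: dict[str, str] = {
    code: _SET_TO_CODE[frozenset(_BASE_COMPLEMENT[b] for b in bases)]
    for code, bases in IUPAC_CODES.items()
}

# match classes
EXACT = "exact"
DEGENERATE = "degenerate"
MISMATCH = "mismatch"


class AlphabetError(ValueError):
    """A character outside the 15-letter IUPAC DNA alphabet (or an empty
    sequence where one residue is required)."""


class BoundedExpansionError(ValueError):
    """Expansion would exceed the caller's limit; carries the count."""

    def __init__(self, count: int, limit: int):
        self.count = count
        self.limit = limit
        super().__init__(
            f"expansion count {count} exceeds the limit of {limit} sequences"
        )


def _bad_char(char: str, position: int, context: Optional[str]) -> AlphabetError:
    where = f" in {context!r}" if context else ""
    return AlphabetError(
        f"invalid IUPAC DNA character {char!r} at position {position}{where}"
    )


def normalize(sequence: str, context: Optional[str] = None) -> str:
    """Uppercase, map RNA U to T, and validate against the IUPAC alphabet.

    Gap characters are *not* accepted here; strip them before calling
    (database loaders do, primers must not contain them).  Raises
    :class:`AlphabetError` on the first offending character, naming it and
    its 1-based position.
    """
    out = sequence.upper().replace("U", "T")
    for i, char in enumerate(out, start=1):
        if char not in IUPAC_CODES:
            raise _bad_char(char, i, context)
    if not out:
        raise AlphabetError(
            "empty sequence" + (f" in {context!r}" if context else "")
        )
    return out


def base_set(code: str) -> frozenset[str]:
    """The set of plain bases a code stands for (A -> {A}, N -> {A,C,G,T})."""
    try:
        return IUPAC_CODES[code]
    except KeyError:
        raise _bad_char(code, 1, None) from None


def degeneracy(code: str) -> int:
    """Number of plain bases the code stands for (1-4)."""
    return len(base_set(code))


def base_union(a: str, b: str) -> str:
    """Minimal IUPAC code covering both inputs: the code of the set union.

    This realizes the degenerate-replacement table (A/G -> R, C/T -> Y, ...,
    G/H -> N) as one generic rule.  Commutative, associative, idempotent.
    """
    return _SET_TO_CODE[base_set(a) | base_set(b)]


def matches(template_base: str, primer_base: str) -> str:
    """Classify a template/primer base pair.

    ``exact``      -- identical codes (A vs A, R vs R, ...).
    ``degenerate`` -- different codes, but every base the template can be is
                      covered by the primer code (G vs R, R vs N, ...).
    ``mismatch``   -- anything else.
    """
    t, p = base_set(template_base), base_set(primer_base)
    if template_base == primer_base:
        return EXACT
    if t <= p:
        return DEGENERATE
    return MISMATCH


def complement(code: str) -> str:
    """Complementary code (element-wise A<->T, C<->G on the base set)."""
    try:
        return _CODE_COMPLEMENT[code]
    except KeyError:
        raise _bad_char(code, 1, None) from None


def complement_sequence(sequence: str) -> str:
    seq = normalize(sequence)
    return "".join(complement(c) for c in seq)


def reverse_complement(sequence: str) -> str:
    """Reverse complement of a (possibly degenerate) 5'->3' sequence.

    Complement each position's base set, then read 3'->5' as the new 5'->3'
    sequence; an involution that preserves the degeneracy product.
    """
    return complement_sequence(sequence)[::-1]


def degeneracy_product(sequence: str) -> int:
    """Product over positions of each code's set size == |expand(sequence)|."""
    seq = normalize(sequence)
    return prod(degeneracy(c) for c in seq)


def expand(sequence: str, limit: Optional[int] = None) -> set[str]:
    """All distinct plain-DNA sequences a degenerate sequence stands for.

    If *limit* is given and the expansion count exceeds it, raises
    :class:`BoundedExpansionError` without materializing the expansion.
    """
    seq = normalize(sequence)
    count = degeneracy_product(seq)
    if limit is not None and count > limit:
        raise BoundedExpansionError(count, limit)
    sets: Iterable[frozenset[str]] = (base_set(c) for c in seq)
    return {"".join(choice) for choice in product(*(sorted(s) for s in sets))}
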