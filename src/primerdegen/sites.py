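"""Locating the primer-corresponding window of a template gene.

A reverse primer reads 5'->3' on the antisense strand, so its template is
the reverse complement of the gene; a forward primer reads the gene as-is
("orienting" the template).  The oriented template is then scanned with a
sliding primer-length window and each position classified as exact match,
degenerate match, or mismatch under IUPAC subset semantics: a template code
matches a primer code iff every base the template can be is contained in the
primer code's set.

Windows are 0-based half-open internally; reported mismatch positions are
1-based 5'->3' on the primer, the convention primer positions are quoted in.

The per-window mismatch counting is vectorized by encoding each code as a
4-bit base mask: template code t matches primer code p iff ``t & ~p == 0``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Union

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .iupac import DEGENERATE, EXACT, IUPAC_CODES, MISMATCH, normalize, reverse_complement
from .seqio import FORWARD, REVERSE, AnnotatedSequence, PrimerRecord

__all__ = [
    "PrimerSiteAlignment",
    "ShortTemplateError",
    "orient_template",
    "window_mismatch_counts",
    "find_sites",
    "locate_site",
]

_BASE_BIT = {"A": 1, "C": 2, "G": 4, "T": 8}
#: IUPAC code -> 4-bit mask of the bases it stands for
CODE_BITS = {
    code: sum(_BASE_BIT[b] for b in bases) for code, bases in IUPAC_CODES.items()
}
_ENCODE_LUT = np.zeros(128, dtype=np.uint8)
for _code, _bits in CODE_BITS.items():
    _ENCODE_LUT[ord(_code)] = _bits


class ShortTemplateError(ValueError):
    """Template shorter than the primer: no window exists to align."""


def _encode(sequence: str) -> np.ndarray:
    return _ENCODE_LUT[np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)]


@dataclass(frozen=True)
class PrimerSiteAlignment:
    """Best-matching window of an oriented template for one primer.

    ``window_start`` is the 0-based offset on the oriented template (the
    gene itself for forward primers, its reverse complement for reverse
    primers).  ``mismatch_positions`` are 1-based on the primer, 5'->3'.
    ``valid`` is True iff the mismatch count is within the caller's
    allowance (default 5; beyond that the window is unlikely to be the
    primer-corresponding site at all, and repairing it would blow the
    degeneracy budget anyway).
    """

    template_id: str
    window_start: int
    window: str
    match_classes: tuple[str, ...]
    mismatch_positions: tuple[int, ...]
    mismatch_count: int
    valid: bool


def orient_template(
    gene: Union[AnnotatedSequence, str], orientation: str
) -> str:
    """The strand a primer actually reads: the gene for forward primers,
    its reverse complement for reverse primers."""
    sequence = gene.sequence if isinstance(gene, AnnotatedSequence) else gene
    sequence = normalize(sequence)
    if orientation in (REVERSE, "R", "r"):
        return reverse_complement(sequence)
    if orientation in (FORWARD, "F", "f"):
        return sequence
    raise ValueError(f"orientation must be 'forward' or 'reverse' (got {orientation!r})")


def window_mismatch_counts(primer: str, template: str) -> np.ndarray:
    """Mismatch count of every primer-length window of *template*.

    Entry ``i`` is the number of primer positions whose subset-match test
    fails in the window starting at offset ``i``.  Raises
    :class:`ShortTemplateError` if no window exists.
    """
    if len(template) < len(primer):
        raise ShortTemplateError(
            f"template length {len(template)} is shorter than primer length "
            f"{len(primer)}"
        )
    t = _encode(template)
    p = _encode(primer)
    windows = sliding_window_view(t, len(primer))
    return ((windows & ~p) != 0).sum(axis=1)


def find_sites(primer: str, template: str, max_mismatches: int = 0) -> list[int]:
    """Window start offsets whose mismatch count is <= *max_mismatches*,
    ascending.  Empty list (rather than an error) for short templates."""
    if len(template) < len(primer):
        return []
    counts = window_mismatch_counts(primer, template)
    return np.flatnonzero(counts <= max_mismatches).tolist()


def locate_site(
    primer: Union[PrimerRecord, str],
    gene: Union[AnnotatedSequence, str],
    orientation: Optional[str] = None,
    max_mismatches: int = 5,
) -> PrimerSiteAlignment:
    """Best-matching window of the oriented template for *primer*.

    Scans every primer-length window, returns the one with the fewest
    mismatches (ties broken by smallest offset) together with per-position
    match classes.  ``valid`` is False when the count exceeds
    *max_mismatches*.  Raises :class:`ShortTemplateError` when the template
    is shorter than the primer — the failure mode of very partial database
    sequences, which cannot be improved against.
    """
    if isinstance(primer, PrimerRecord):
        primer_seq = primer.sequence
        orientation = orientation or primer.orientation
    else:
        primer_seq = normalize(primer)
        if orientation is None:
            raise ValueError("orientation is required for a bare primer string")

    template_id = gene.identifier if isinstance(gene, AnnotatedSequence) else ""
    oriented = orient_template(gene, orientation)
    counts = window_mismatch_counts(primer_seq, oriented)
    start = int(np.argmin(counts))  # argmin takes the first minimum
    window = oriented[start : start + len(primer_seq)]
    classes = tuple(
        _classify(t, p) for t, p in zip(window, primer_seq)
    )
    mismatch_positions = tuple(
        i for i, cls in enumerate(classes, start=1) if cls == MISMATCH
    )
    count = len(mismatch_positions)
    return PrimerSiteAlignment(
        template_id=template_id,
        window_start=start,
        window=window,
        match_classes=classes,
        mismatch_positions=mismatch_positions,
        mismatch_count=count,
        valid=count <= max_mismatches,
    )


def _classify(template_code: str, primer_code: str) -> str:
    if template_code == primer_code:
        return EXACT
    if CODE_BITS[template_code] & ~CODE_BITS[primer_code] & 0xF:
        return MISMATCH
    return DEGENERATE
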