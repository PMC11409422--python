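"""Iterative degenerate-base improvement of a universal primer.

One step aligns the primer to one uncovered gene, replaces every mismatched
primer position with the minimal IUPAC code covering both the primer's and
the template's bases (set union — a 2-fold code when possible, else 3-fold,
else N), and accepts the result only if the alignment had at most
``max_mismatches`` mismatches and the new primer's expansion count stays
within ``max_expansion`` (default 60, the bound SILVA enforces on submitted
degenerate primers).  The iterative driver repeats steps against whichever
target-taxon sequences the current primer still fails to match at a
0-mismatch allowance, until none remain or every remaining candidate is
rejected.

Because replacements only ever enlarge per-position base sets, every
sequence covered by the input primer stays covered by the output primer:
per-taxon coverage is non-decreasing across accepted steps, and expansion
strictly increases on every non-identity accepted step, which (with the
60-expansion cap) bounds the number of accepted steps.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass
from typing import Optional, Union

import numpy as np

from .coverage import ReferenceDatabase, sequence_matched
from .iupac import base_union, degeneracy_product
from .seqio import AnnotatedSequence, PrimerRecord
from .sites import ShortTemplateError, locate_site

__all__ = [
    "REJECT_NONE",
    "REJECT_TOO_MANY_MISMATCHES",
    "REJECT_EXPANSION_LIMIT",
    "REJECT_SHORT_TEMPLATE",
    "Replacement",
    "ImprovementStep",
    "ImprovementTrace",
    "improve_once",
    "improve_iteratively",
]

logger = logging.getLogger(__name__)

REJECT_NONE = "none"
REJECT_TOO_MANY_MISMATCHES = "too_many_mismatches"
REJECT_EXPANSION_LIMIT = "expansion_limit"
REJECT_SHORT_TEMPLATE = "short_template"

GREEDY = "greedy"
RANDOM = "random"

STOP_NO_UNCOVERED = "no_uncovered_sequences"
STOP_ALL_REJECTED = "all_candidates_rejected"
STOP_ITERATION_CAP = "iteration_cap"


@dataclass(frozen=True)
class Replacement:
    """One primer position widened to cover the template base."""

    position: int  # 1-based, 5'->3' on the primer
    old_code: str
    template_code: str
    new_code: str


@dataclass(frozen=True)
class ImprovementStep:
    input_primer: str
    template_id: str
    replacements: tuple[Replacement, ...]
    output_primer: str
    output_expansion: int
    accepted: bool
    reject_reason: str = REJECT_NONE


@dataclass(frozen=True)
class ImprovementTrace:
    """Ordered record of every attempted step, accepted or not.

    ``final_primer`` is the output of the last accepted step, or the
    initial primer when no step was accepted.
    """

    initial_primer: str
    steps: tuple[ImprovementStep, ...]
    final_primer: str
    stop_reason: str

    @property
    def accepted_steps(self) -> tuple[ImprovementStep, ...]:
        return tuple(s for s in self.steps if s.accepted)

    def to_dict(self) -> dict:
        return asdict(self)

    def to_json(self, path: Optional[str] = None, indent: int = 2) -> str:
        text = json.dumps(self.to_dict(), indent=indent)
        if path is not None:
            with open(path, "w") as handle:
                handle.write(text + "\n")
        return text


def improve_once(
    primer: Union[PrimerRecord, str],
    gene: AnnotatedSequence,
    orientation: Optional[str] = None,
    max_mismatches: int = 5,
    max_expansion: int = 60,
) -> ImprovementStep:
    """One improvement step against one gene.

    Aligns the primer (best window of the oriented template), unions every
    mismatched position with the template's code, and accepts the tentative
    primer unless the alignment exceeded *max_mismatches* or the result's
    expansion count exceeds *max_expansion*.  A rejected step still reports
    the tentative primer so the user can see what was attempted.
    """
    if not isinstance(primer, PrimerRecord):
        primer = PrimerRecord("primer", orientation or "forward", primer)
    try:
        alignment = locate_site(
            primer, gene, max_mismatches=max_mismatches
        )
    except ShortTemplateError:
        logger.info(
            "gene %s is shorter than primer %s: cannot improve against it",
            gene.identifier,
            primer.name,
        )
        return ImprovementStep(
            input_primer=primer.sequence,
            template_id=gene.identifier,
            replacements=(),
            output_primer=primer.sequence,
            output_expansion=degeneracy_product(primer.sequence),
            accepted=False,
            reject_reason=REJECT_SHORT_TEMPLATE,
        )

    residues = list(primer.sequence)
    replacements = []
    for pos in alignment.mismatch_positions:
        old = residues[pos - 1]
        template_code = alignment.window[pos - 1]
        new = base_union(old, template_code)
        replacements.append(Replacement(pos, old, template_code, new))
        residues[pos - 1] = new
    output = "".join(residues)
    expansion = degeneracy_product(output)

    if not alignment.valid:
        return ImprovementStep(
            input_primer=primer.sequence,
            template_id=gene.identifier,
            replacements=tuple(replacements),
            output_primer=output,
            output_expansion=expansion,
            accepted=False,
            reject_reason=REJECT_TOO_MANY_MISMATCHES,
        )
    if expansion > max_expansion:
        logger.warning(
            "improving %s against %s would expand to %d sequences "
            "(limit %d); consider manually reducing the primer's existing "
            "degeneracy to make room",
            primer.name,
            gene.identifier,
            expansion,
            max_expansion,
        )
        return ImprovementStep(
            input_primer=primer.sequence,
            template_id=gene.identifier,
            replacements=tuple(replacements),
            output_primer=output,
            output_expansion=expansion,
            accepted=False,
            reject_reason=REJECT_EXPANSION_LIMIT,
        )
    return ImprovementStep(
        input_primer=primer.sequence,
        template_id=gene.identifier,
        replacements=tuple(replacements),
        output_primer=output,
        output_expansion=expansion,
        accepted=True,
    )


def _candidate_order(
    primer: PrimerRecord,
    candidates: list[AnnotatedSequence],
    policy: str,
    rng: np.random.Generator,
) -> list[AnnotatedSequence]:
    if policy == RANDOM:
        order = list(candidates)
        rng.shuffle(order)
        return order
    if policy != GREEDY:
        raise ValueError(f"unknown candidate policy {policy!r}")

    def mismatches(gene: AnnotatedSequence) -> tuple[int, str]:
        try:
            alignment = locate_site(primer, gene)
        except ShortTemplateError:
            return (len(primer) + 1, gene.identifier)
        return (alignment.mismatch_count, gene.identifier)

    return sorted(candidates, key=mismatches)


def improve_iteratively(
    primer: PrimerRecord,
    database: ReferenceDatabase,
    target_taxon: Optional[str] = None,
    max_mismatches: int = 5,
    max_expansion: int = 60,
    max_iterations: int = 20,
    policy: str = GREEDY,
    seed: int = 0,
) -> ImprovementTrace:
    """Improve a primer against a database until coverage cannot grow.

    Each round: find the target-taxon sequences the current primer does not
    match at 0 mismatches; order them (``greedy`` = fewest mismatches first,
    deterministic; ``random`` = seeded shuffle); attempt steps in that order,
    adopting the first accepted non-identity result.  Stops when no
    uncovered sequence remains, every candidate yields a rejected or
    identity step, or the iteration cap is hit.  Forward and reverse primers
    are improved by separate invocations.
    """
    candidates = database.select(target_taxon)
    rng = np.random.default_rng(seed)
    current = primer
    steps: list[ImprovementStep] = []
    stop_reason = STOP_ITERATION_CAP
    for _ in range(max_iterations):
        uncovered = [
            gene
            for gene in candidates
            if not sequence_matched(current, gene, max_mismatches=0)
        ]
        if not uncovered:
            stop_reason = STOP_NO_UNCOVERED
            break
        adopted = False
        for gene in _candidate_order(current, uncovered, policy, rng):
            step = improve_once(
                current,
                gene,
                max_mismatches=max_mismatches,
                max_expansion=max_expansion,
            )
            steps.append(step)
            if step.accepted and step.output_primer != current.sequence:
                current = current.with_sequence(step.output_primer)
                adopted = True
                break
        if not adopted:
            stop_reason = STOP_ALL_REJECTED
            break
    return ImprovementTrace(
        initial_primer=primer.sequence,
        steps=tuple(steps),
        final_primer=current.sequence,
        stop_reason=stop_reason,
    )
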