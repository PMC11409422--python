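"""Local in-silico PCR coverage evaluation (TestPrime-style).

Coverage of a taxonomic group is the percentage of its sequences matched by
a primer (or primer pair) at a given mismatch allowance — 0 by default, the
strictest setting.  A single primer matches a sequence iff some window of
the appropriately oriented template is within the allowance; a pair matches
iff the forward primer hits the sense strand, the reverse primer hits the
antisense strand, and the forward site ends strictly before the reverse
site begins in sense coordinates, so the amplicon has positive length.

Unlike SILVA's TestPrime, matching is anywhere on the unaligned sequence
(no annotated gene boundaries, no elongation-zone weighting) with uniform
mismatch counting; at a 0-mismatch allowance these semantics coincide with
"some expansion of the primer is an exact substring of the oriented
template".
"""

from __future__ import annotations

import difflib
import logging
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import pandas as pd

from .iupac import reverse_complement
from .seqio import FORWARD, REVERSE, AnnotatedSequence, PrimerRecord, read_fasta
from .sites import find_sites, orient_template

__all__ = [
    "RANK_DEPTH",
    "OVERALL_LABEL",
    "UnknownTaxonError",
    "ReferenceDatabase",
    "SequenceMatch",
    "CoverageRow",
    "CoverageReport",
    "sequence_matched",
    "coverage",
    "compare_coverage",
]

logger = logging.getLogger(__name__)

#: conventional SILVA lineage depths, 0-based
RANK_DEPTH = {
    "domain": 0,
    "phylum": 1,
    "class": 2,
    "order": 3,
    "family": 4,
    "genus": 5,
    "species": 6,
}

OVERALL_LABEL = "all sequences"

PrimerInput = Union[PrimerRecord, tuple[PrimerRecord, PrimerRecord]]


class UnknownTaxonError(ValueError):
    """A taxon label absent from the database, with near-miss suggestions."""

    def __init__(self, label: str, candidates: Iterable[str]):
        self.label = label
        self.suggestions = difflib.get_close_matches(
            label, list(candidates), n=5, cutoff=0.5
        )
        hint = (
            f"; close matches: {', '.join(self.suggestions)}"
            if self.suggestions
            else ""
        )
        super().__init__(f"unknown taxon label {label!r}{hint}")


class ReferenceDatabase:
    """Taxonomy-annotated SSU sequence collection supporting coverage queries.

    Indexes every rank label, every full semicolon-joined path, and every
    path prefix, so ``select`` accepts a bare label ("Dehalococcoides") or
    a lineage path ("Bacteria;Chloroflexi;...").
    """

    def __init__(self, sequences: Sequence[AnnotatedSequence]):
        if not sequences:
            raise ValueError("reference database is empty")
        seen: set[str] = set()
        for seq in sequences:
            if seq.identifier in seen:
                raise ValueError(f"duplicate identifier {seq.identifier!r}")
            seen.add(seq.identifier)
        self.sequences: list[AnnotatedSequence] = list(sequences)
        self._by_id = {s.identifier: s for s in self.sequences}
        self.taxon_index: dict[str, list[str]] = {}
        for seq in self.sequences:
            labels = set(seq.taxonomy_path)
            labels.update(
                ";".join(seq.taxonomy_path[: depth + 1])
                for depth in range(len(seq.taxonomy_path))
            )
            for label in labels:
                self.taxon_index.setdefault(label, []).append(seq.identifier)

    @classmethod
    def from_fasta(
        cls,
        path: Union[str, Path],
        taxonomy_table: Optional[Union[str, Path, dict]] = None,
    ) -> "ReferenceDatabase":
        return cls(read_fasta(path, taxonomy_table=taxonomy_table))

    def __len__(self) -> int:
        return len(self.sequences)

    def __iter__(self):
        return iter(self.sequences)

    def __getitem__(self, identifier: str) -> AnnotatedSequence:
        return self._by_id[identifier]

    def select(self, taxon: Optional[str]) -> list[AnnotatedSequence]:
        """Sequences carrying *taxon* (rank label or lineage path) in their
        taxonomy; the whole database when *taxon* is None."""
        if taxon is None:
            return list(self.sequences)
        if taxon not in self.taxon_index:
            raise UnknownTaxonError(taxon, self.taxon_index)
        return [self._by_id[i] for i in self.taxon_index[taxon]]


@dataclass(frozen=True)
class SequenceMatch:
    """Outcome of matching one primer (or pair) against one sequence.

    Site coordinates are present only when matched: 0-based window starts
    in sense coordinates (``reverse_start`` is where the reverse site
    begins on the sense strand).
    """

    matched: bool
    forward_start: Optional[int] = None
    reverse_start: Optional[int] = None

    def __bool__(self) -> bool:
        return self.matched


def _single_sites(
    primer: PrimerRecord, seq: AnnotatedSequence, max_mismatches: int
) -> list[int]:
    if len(seq) < len(primer):
        logger.debug(
            "sequence %s (%d nt) shorter than primer %s (%d nt): unmatched",
            seq.identifier,
            len(seq),
            primer.name,
            len(primer),
        )
        return []
    oriented = orient_template(seq, primer.orientation)
    return find_sites(primer.sequence, oriented, max_mismatches)


def sequence_matched(
    primers: PrimerInput,
    seq: AnnotatedSequence,
    max_mismatches: int = 0,
) -> SequenceMatch:
    """Does the primer (or pair) match the sequence within the allowance?

    A sequence shorter than a primer counts as unmatched, not as an error.
    For a pair, any ordered combination of a forward site and a downstream
    reverse site qualifies.
    """
    if isinstance(primers, PrimerRecord):
        sites = _single_sites(primers, seq, max_mismatches)
        if not sites:
            return SequenceMatch(False)
        start = sites[0]
        if primers.orientation == REVERSE:
            return SequenceMatch(True, reverse_start=len(seq) - start - len(primers))
        return SequenceMatch(True, forward_start=start)

    fwd, rev = _as_pair(primers)
    f_sites = _single_sites(fwd, seq, max_mismatches)
    if not f_sites:
        return SequenceMatch(False)
    r_sites = _single_sites(rev, seq, max_mismatches)
    if not r_sites:
        return SequenceMatch(False)
    # reverse sites were found on the antisense strand; map to sense coords
    r_sense_starts = [len(seq) - start - len(rev) for start in r_sites]
    f_end_min = min(f_sites) + len(fwd)
    r_start_max = max(r_sense_starts)
    if f_end_min <= r_start_max:
        f_start = min(f_sites)
        r_start = max(s for s in r_sense_starts if s >= f_start + len(fwd))
        return SequenceMatch(True, forward_start=f_start, reverse_start=r_start)
    return SequenceMatch(False)


def _as_pair(primers: PrimerInput) -> tuple[PrimerRecord, PrimerRecord]:
    fwd, rev = primers
    if fwd.orientation != FORWARD or rev.orientation != REVERSE:
        raise ValueError(
            "a primer pair is (forward, reverse); got orientations "
            f"({fwd.orientation}, {rev.orientation})"
        )
    return fwd, rev


def round_percent(matched: int, total: int) -> float:
    """100*matched/total, rounded half-up to one decimal place."""
    if total == 0:
        return 0.0
    pct = Decimal(100 * matched) / Decimal(total)
    return float(pct.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class CoverageRow:
    taxon: str
    matched: int
    total: int
    percent: float


@dataclass(frozen=True)
class CoverageReport:
    """Per-taxon matched/total counts and percentages.

    ``mode`` is ``single_primer`` or ``primer_pair``; the overall row counts
    every sequence in the database. Percentages are sequence-level (every
    database record counts once), not deduplicated-species-level.
    """

    rows: tuple[CoverageRow, ...]
    overall: CoverageRow
    mode: str

    def to_frame(self) -> pd.DataFrame:
        data = [
            (r.taxon, r.matched, r.total, r.percent)
            for r in (*self.rows, self.overall)
        ]
        return pd.DataFrame(
            data, columns=["taxon", "matched", "total", "percent"]
        )

    def to_tsv(self, path: Union[str, Path]) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    def percent_of(self, taxon: str) -> float:
        if taxon == OVERALL_LABEL:
            return self.overall.percent
        for row in self.rows:
            if row.taxon == taxon:
                return row.percent
        raise UnknownTaxonError(taxon, [r.taxon for r in self.rows])


def _grouping(
    database: ReferenceDatabase,
    rank: Optional[Union[str, int]],
    taxa: Optional[Sequence[str]],
) -> dict[str, list[AnnotatedSequence]]:
    groups: dict[str, list[AnnotatedSequence]] = {}
    if taxa:
        for label in taxa:
            groups[label] = database.select(label)
    if rank is not None:
        depth = RANK_DEPTH[rank.lower()] if isinstance(rank, str) else int(rank)
        for seq in database:
            label = (
                seq.taxonomy_path[depth]
                if depth < len(seq.taxonomy_path)
                else "unclassified"
            )
            groups.setdefault(label, []).append(seq)
    return groups


def coverage(
    primers: PrimerInput,
    database: ReferenceDatabase,
    rank: Optional[Union[str, int]] = None,
    taxa: Optional[Sequence[str]] = None,
    max_mismatches: int = 0,
) -> CoverageReport:
    """Per-taxon coverage of a primer or primer pair.

    Rows come from *taxa* (explicit labels or lineage paths) and/or from
    grouping every sequence at *rank* (name like "genus" or 0-based depth);
    an overall row over the whole database is always present.  Rows are
    sorted alphabetically.
    """
    matched_ids = {
        seq.identifier
        for seq in database
        if sequence_matched(primers, seq, max_mismatches)
    }
    groups = _grouping(database, rank, taxa)
    rows = tuple(
        CoverageRow(
            taxon=label,
            matched=sum(1 for s in members if s.identifier in matched_ids),
            total=len(members),
            percent=round_percent(
                sum(1 for s in members if s.identifier in matched_ids),
                len(members),
            ),
        )
        for label, members in sorted(groups.items())
    )
    overall = CoverageRow(
        OVERALL_LABEL,
        len(matched_ids),
        len(database),
        round_percent(len(matched_ids), len(database)),
    )
    mode = "single_primer" if isinstance(primers, PrimerRecord) else "primer_pair"
    return CoverageReport(rows=rows, overall=overall, mode=mode)


def compare_coverage(
    old: PrimerInput,
    new: PrimerInput,
    database: ReferenceDatabase,
    rank: Optional[Union[str, int]] = None,
    taxa: Optional[Sequence[str]] = None,
    max_mismatches: int = 0,
) -> pd.DataFrame:
    """Per-taxon old%, new% and delta for two primers/pairs, sorted by
    delta descending (ties alphabetical); the overall row is included."""
    old_report = coverage(old, database, rank=rank, taxa=taxa, max_mismatches=max_mismatches)
    new_report = coverage(new, database, rank=rank, taxa=taxa, max_mismatches=max_mismatches)
    old_rows = {r.taxon: r for r in (*old_report.rows, old_report.overall)}
    new_rows = {r.taxon: r for r in (*new_report.rows, new_report.overall)}
    records = []
    for taxon in old_rows:
        o, n = old_rows[taxon], new_rows[taxon]
        records.append(
            {
                "taxon": taxon,
                "total": o.total,
                "old_matched": o.matched,
                "new_matched": n.matched,
                "old_percent": o.percent,
                "new_percent": n.percent,
                "delta": round(n.percent - o.percent, 1),
            }
        )
    frame = pd.DataFrame.from_records(records)
    return frame.sort_values(
        ["delta", "taxon"], ascending=[False, True], ignore_index=True
    )
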