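"""Reading and writing primers and taxonomy-annotated reference sequences.

Reference databases are FASTA files whose description lines follow the SILVA
export convention: accession, a space, then a semicolon-delimited taxonomy
path (``>X80725.1.1479 Bacteria;Proteobacteria;...;Escherichia-Shigella``).
A two-column TSV sidecar (identifier, taxonomy path) is also accepted and
takes precedence over header taxonomy.  Sequences are normalized to
uppercase DNA (U -> T) and alignment gap characters ('-', '.') are stripped
with a warning: matching downstream is on contiguous, unaligned windows.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Union

from Bio import SeqIO

from .iupac import AlphabetError, normalize

__all__ = [
    "FORWARD",
    "REVERSE",
    "AnnotatedSequence",
    "PrimerRecord",
    "FastaFormatError",
    "read_fasta",
    "write_fasta",
    "read_taxonomy_table",
    "read_primer",
]

logger = logging.getLogger(__name__)

FORWARD = "forward"
REVERSE = "reverse"

_GAP_CHARS = str.maketrans("", "", "-.")

_ORIENTATION_ALIASES = {
    "forward": FORWARD,
    "f": FORWARD,
    "reverse": REVERSE,
    "r": REVERSE,
}


class FastaFormatError(ValueError):
    """Malformed FASTA / primer input (empty file, duplicate identifiers,
    invalid residues, multiple records where one is expected)."""


def _canonical_orientation(orientation: str) -> str:
    try:
        return _ORIENTATION_ALIASES[orientation.strip().lower()]
    except (KeyError, AttributeError):
        raise ValueError(
            f"orientation must be 'forward' or 'reverse' (got {orientation!r})"
        ) from None


@dataclass(frozen=True)
class AnnotatedSequence:
    """One reference (or target-gene) sequence with its taxonomy lineage.

    ``taxonomy_path`` is the ordered SILVA-style lineage (domain -> ... ->
    genus); it may be empty, in which case coverage aggregates the sequence
    only at the "all sequences" level.
    """

    identifier: str
    taxonomy_path: tuple[str, ...]
    sequence: str

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def taxonomy(self) -> str:
        return ";".join(self.taxonomy_path)


@dataclass(frozen=True)
class PrimerRecord:
    """A named primer with an explicit orientation (never inferred)."""

    name: str
    orientation: str
    sequence: str

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "orientation", _canonical_orientation(self.orientation)
        )
        object.__setattr__(
            self, "sequence", normalize(self.sequence, context=self.name)
        )

    def __len__(self) -> int:
        return len(self.sequence)

    def with_sequence(self, sequence: str) -> "PrimerRecord":
        return PrimerRecord(self.name, self.orientation, sequence)


def _parse_header(description: str) -> tuple[str, tuple[str, ...]]:
    parts = description.split(None, 1)
    identifier = parts[0]
    if len(parts) == 1:
        return identifier, ()
    taxonomy = tuple(
        label.strip() for label in parts[1].split(";") if label.strip()
    )
    return identifier, taxonomy


def read_taxonomy_table(path: Union[str, Path]) -> dict[str, tuple[str, ...]]:
    """Two-column TSV sidecar: identifier <TAB> semicolon-joined taxonomy."""
    table: dict[str, tuple[str, ...]] = {}
    with open(path) as handle:
        for line_no, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise FastaFormatError(
                    f"{path}: line {line_no}: expected 2 tab-separated "
                    f"columns, got {len(fields)}"
                )
            identifier, path_str = fields
            table[identifier] = tuple(
                label.strip() for label in path_str.split(";") if label.strip()
            )
    return table


def read_fasta(
    path: Union[str, Path],
    taxonomy_table: Optional[Union[str, Path, dict]] = None,
) -> list[AnnotatedSequence]:
    """Load a FASTA file as a list of :class:`AnnotatedSequence`, in order.

    Taxonomy comes from the description line (SILVA convention) unless a
    sidecar table is given, which takes precedence per identifier.  Gap
    characters are stripped with a warning; any other character outside the
    IUPAC alphabet after normalization is a :class:`FastaFormatError`
    naming the record.
    """
    if taxonomy_table is not None and not isinstance(taxonomy_table, dict):
        taxonomy_table = read_taxonomy_table(taxonomy_table)

    records: list[AnnotatedSequence] = []
    seen: set[str] = set()
    for index, rec in enumerate(SeqIO.parse(str(path), "fasta"), start=1):
        identifier, taxonomy = _parse_header(rec.description)
        if taxonomy_table and identifier in taxonomy_table:
            taxonomy = tuple(taxonomy_table[identifier])
        if identifier in seen:
            raise FastaFormatError(
                f"{path}: record {index}: duplicate identifier {identifier!r}"
            )
        seen.add(identifier)
        raw = str(rec.seq)
        stripped = raw.translate(_GAP_CHARS)
        if len(stripped) != len(raw):
            logger.warning(
                "%s: record %r: stripped %d gap character(s)",
                path,
                identifier,
                len(raw) - len(stripped),
            )
        try:
            sequence = normalize(stripped, context=identifier)
        except AlphabetError as err:
            raise FastaFormatError(
                f"{path}: record {index} ({identifier!r}): {err}"
            ) from err
        records.append(AnnotatedSequence(identifier, taxonomy, sequence))
    if not records:
        raise FastaFormatError(f"{path}: no FASTA records found")
    return records


def write_fasta(
    records: Iterable[AnnotatedSequence],
    path: Union[str, Path],
    width: int = 70,
) -> None:
    """Write records with SILVA-style ``>identifier taxonomy;...`` headers."""
    with open(path, "w") as handle:
        for rec in records:
            header = rec.identifier
            if rec.taxonomy_path:
                header += " " + rec.taxonomy
            handle.write(f">{header}\n")
            for i in range(0, len(rec.sequence), width):
                handle.write(rec.sequence[i : i + width] + "\n")


def read_primer(
    source: Union[str, Path],
    orientation: str,
    name: Optional[str] = None,
) -> PrimerRecord:
    """Read a primer from a bare IUPAC string or a one-record FASTA/text file.

    Whitespace is stripped and the sequence normalized.  A file holding more
    than one record (or more than one sequence line without a header) is an
    error: a primer file means exactly one primer.
    """
    orientation = _canonical_orientation(orientation)
    text: Optional[str] = None
    if isinstance(source, Path) or (
        isinstance(source, str) and os.path.isfile(source)
    ):
        with open(source) as handle:
            text = handle.read()
        default_name = Path(source).stem
    else:
        text = str(source)
        default_name = "primer"

    text = text.strip()
    if text.startswith(">"):
        lines = text.splitlines()
        headers = [ln for ln in lines if ln.startswith(">")]
        if len(headers) != 1:
            raise FastaFormatError(
                f"expected exactly one primer record, found {len(headers)}"
            )
        default_name = headers[0][1:].split(None, 1)[0] or default_name
        sequence = "".join(ln.strip() for ln in lines[1:])
    else:
        lines = [ln.strip() for ln in text.splitlines() if ln.strip()]
        if len(lines) > 1:
            raise FastaFormatError(
                f"expected exactly one primer sequence, found {len(lines)} lines"
            )
        sequence = lines[0] if lines else ""
    sequence = "".join(sequence.split())
    return PrimerRecord(name or default_name, orientation, sequence)
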