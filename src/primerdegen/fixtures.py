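"""Seeded generator of SSU-like reference databases with planted primer sites.

Each generated sequence is uniform-random A/C/G/T background carrying one
forward-primer binding site, a spacer (the planted amplicon interior), and
one reverse-primer binding site (reverse-complemented into the sense
strand).  Mismatches are planted deliberately: at a chosen primer position
the template base is replaced by a base *outside* the primer code's base
set, so the planned per-sequence mismatch spectrum is exact ground truth.
A guard re-draws any sequence whose random background happens to contain a
spurious extra binding site, so planted offsets are the only sites.

Backgrounds are i.i.d. uniform — no rRNA secondary structure or conserved
regions; the fixtures exercise matching logic, not biology.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import yaml

from .coverage import ReferenceDatabase
from .iupac import base_set, normalize, reverse_complement
from .seqio import FORWARD, REVERSE, AnnotatedSequence, write_fasta
from .sites import find_sites

__all__ = [
    "FixtureSpecError",
    "PlantedMismatch",
    "MismatchPlan",
    "TaxonSpec",
    "FixtureSpec",
    "PlantedSite",
    "generate_database",
]

logger = logging.getLogger(__name__)

_BASES = np.array(list("ACGT"))


class FixtureSpecError(ValueError):
    """Inconsistent fixture specification (sites don't fit, impossible
    mismatch substitution, counts exceed the taxon's sequence count)."""


@dataclass(frozen=True)
class PlantedMismatch:
    """One deliberate template-vs-primer mismatch.

    ``position`` is 1-based on the primer, 5'->3'; ``base`` is the template
    base to plant there (must lie outside the primer code's base set), or
    None to pick one at random.
    """

    orientation: str  # 'forward' | 'reverse'
    position: int
    base: Optional[str] = None


@dataclass(frozen=True)
class MismatchPlan:
    """Apply ``sites`` to ``count`` sequences of a taxon."""

    count: int
    sites: tuple[PlantedMismatch, ...]


@dataclass(frozen=True)
class TaxonSpec:
    taxonomy: tuple[str, ...]
    n_sequences: int
    plans: tuple[MismatchPlan, ...] = ()


@dataclass(frozen=True)
class FixtureSpec:
    """Full recipe for a synthetic reference database.

    ``f_r_spacing`` is the number of background bases between the end of
    the planted forward site and the start of the planted reverse site on
    the sense strand (the amplicon interior).
    """

    seed: int
    forward_primer: str
    reverse_primer: str
    taxa: tuple[TaxonSpec, ...]
    background_length: int = 800
    f_r_spacing: int = 150

    def __post_init__(self) -> None:
        object.__setattr__(self, "forward_primer", normalize(self.forward_primer))
        object.__setattr__(self, "reverse_primer", normalize(self.reverse_primer))
        needed = len(self.forward_primer) + self.f_r_spacing + len(self.reverse_primer)
        if needed > self.background_length:
            raise FixtureSpecError(
                f"planted sites need {needed} nt but background_length is "
                f"{self.background_length}"
            )
        for taxon in self.taxa:
            planned = sum(plan.count for plan in taxon.plans)
            if planned > taxon.n_sequences:
                raise FixtureSpecError(
                    f"taxon {';'.join(taxon.taxonomy)}: mismatch plans cover "
                    f"{planned} sequences but only {taxon.n_sequences} exist"
                )
            for plan in taxon.plans:
                for site in plan.sites:
                    self._check_site(site)

    def _check_site(self, site: PlantedMismatch) -> None:
        primer = (
            self.forward_primer
            if site.orientation == FORWARD
            else self.reverse_primer
        )
        if site.orientation not in (FORWARD, REVERSE):
            raise FixtureSpecError(
                f"mismatch orientation must be 'forward' or 'reverse', got "
                f"{site.orientation!r}"
            )
        if not 1 <= site.position <= len(primer):
            raise FixtureSpecError(
                f"mismatch position {site.position} outside the "
                f"{site.orientation} primer (length {len(primer)})"
            )
        allowed = base_set(primer[site.position - 1])
        outside = frozenset("ACGT") - allowed
        if not outside:
            raise FixtureSpecError(
                f"no base can mismatch the {site.orientation} primer at "
                f"position {site.position}: the code there is N"
            )
        if site.base is not None and site.base.upper() in allowed:
            raise FixtureSpecError(
                f"planted base {site.base!r} at {site.orientation} primer "
                f"position {site.position} would not be a mismatch "
                f"(primer code covers it)"
            )

    @classmethod
    def from_dict(cls, data: dict) -> "FixtureSpec":
        taxa = tuple(
            TaxonSpec(
                taxonomy=tuple(
                    label.strip()
                    for label in str(t["taxonomy"]).split(";")
                    if label.strip()
                ),
                n_sequences=int(t["n_sequences"]),
                plans=tuple(
                    MismatchPlan(
                        count=int(plan["count"]),
                        sites=tuple(
                            PlantedMismatch(
                                orientation=str(site["orientation"]).lower(),
                                position=int(site["position"]),
                                base=site.get("base"),
                            )
                            for site in plan.get("sites", [])
                        ),
                    )
                    for plan in t.get("mismatches", [])
                ),
            )
            for t in data["taxa"]
        )
        return cls(
            seed=int(data.get("seed", 0)),
            forward_primer=str(data["forward_primer"]),
            reverse_primer=str(data["reverse_primer"]),
            taxa=taxa,
            background_length=int(data.get("background_length", 800)),
            f_r_spacing=int(data.get("f_r_spacing", 150)),
        )

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "FixtureSpec":
        with open(path) as handle:
            return cls.from_dict(yaml.safe_load(handle))


@dataclass(frozen=True)
class PlantedSite:
    """Ground truth for one generated sequence: where the sites were
    planted (0-based, sense coordinates for the forward site, oriented
    antisense-template coordinates for the reverse site) and which
    mismatches were applied."""

    forward_start: int
    reverse_start_sense: int
    reverse_start_oriented: int
    mismatches: tuple[PlantedMismatch, ...]


def _concretize(primer: str, rng: np.random.Generator) -> list[str]:
    """One exact-matching template realization of a degenerate primer."""
    return [
        sorted(base_set(code))[rng.integers(len(base_set(code)))]
        for code in primer
    ]


def _apply_mismatches(
    site: list[str],
    primer: str,
    planted: Sequence[PlantedMismatch],
    rng: np.random.Generator,
) -> None:
    for mm in planted:
        allowed = base_set(primer[mm.position - 1])
        if mm.base is not None:
            site[mm.position - 1] = mm.base.upper()
        else:
            outside = sorted(frozenset("ACGT") - allowed)
            site[mm.position - 1] = outside[rng.integers(len(outside))]


def _spurious_sites(spec: FixtureSpec, sense: str, truth: PlantedSite) -> bool:
    # the planted offsets are the only allowed exact sites; anything else is
    # a background collision and forces a redraw
    f_hits = set(find_sites(spec.forward_primer, sense, 0))
    r_hits = set(find_sites(spec.reverse_primer, reverse_complement(sense), 0))
    return bool(
        (f_hits - {truth.forward_start})
        or (r_hits - {truth.reverse_start_oriented})
    )


def _generate_sequence(
    spec: FixtureSpec,
    planted: Sequence[PlantedMismatch],
    rng: np.random.Generator,
) -> tuple[str, PlantedSite]:
    len_f = len(spec.forward_primer)
    len_r = len(spec.reverse_primer)
    needed = len_f + spec.f_r_spacing + len_r
    for _ in range(50):
        f_start = int(rng.integers(spec.background_length - needed + 1))
        background = rng.choice(_BASES, size=spec.background_length)
        f_site = _concretize(spec.forward_primer, rng)
        _apply_mismatches(
            f_site,
            spec.forward_primer,
            [m for m in planted if m.orientation == FORWARD],
            rng,
        )
        r_site = _concretize(spec.reverse_primer, rng)
        _apply_mismatches(
            r_site,
            spec.reverse_primer,
            [m for m in planted if m.orientation == REVERSE],
            rng,
        )
        sense = list(background)
        sense[f_start : f_start + len_f] = f_site
        r_start_sense = f_start + len_f + spec.f_r_spacing
        sense[r_start_sense : r_start_sense + len_r] = list(
            reverse_complement("".join(r_site))
        )
        sequence = "".join(sense)
        truth = PlantedSite(
            forward_start=f_start,
            reverse_start_sense=r_start_sense,
            reverse_start_oriented=spec.background_length - r_start_sense - len_r,
            mismatches=tuple(planted),
        )
        if not _spurious_sites(spec, sequence, truth):
            return sequence, truth
        logger.debug("spurious background site; redrawing sequence")
    raise FixtureSpecError(
        "could not draw a background without spurious primer sites in 50 "
        "attempts; the primers may be too permissive for this background "
        "length"
    )


def generate_database(
    spec: FixtureSpec,
    fasta_path: Optional[Union[str, Path]] = None,
) -> tuple[ReferenceDatabase, dict[str, PlantedSite]]:
    """Generate the database a :class:`FixtureSpec` describes.

    Returns the in-memory database and a ground-truth map from sequence
    identifier to its :class:`PlantedSite`.  Byte-identical across runs
    with the same spec (one seeded RNG drives every draw); optionally also
    written to *fasta_path* with SILVA-style taxonomy headers.
    """
    rng = np.random.default_rng(spec.seed)
    records: list[AnnotatedSequence] = []
    truth: dict[str, PlantedSite] = {}
    counter = 0
    for taxon in spec.taxa:
        per_sequence: list[tuple[PlantedMismatch, ...]] = []
        for plan in taxon.plans:
            per_sequence.extend([plan.sites] * plan.count)
        per_sequence.extend(
            [()] * (taxon.n_sequences - len(per_sequence))
        )
        for planted in per_sequence:
            counter += 1
            identifier = f"SYN{counter:05d}"
            sequence, site = _generate_sequence(spec, planted, rng)
            records.append(
                AnnotatedSequence(identifier, taxon.taxonomy, sequence)
            )
            truth[identifier] = site
    database = ReferenceDatabase(records)
    if fasta_path is not None:
        write_fasta(records, fasta_path)
    return database, truth
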