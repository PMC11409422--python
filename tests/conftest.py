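import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from primerdegen import (
    FixtureSpec,
    MismatchPlan,
    PlantedMismatch,
    PrimerRecord,
    TaxonSpec,
    example_fixture_spec,
    generate_database,
)
from primerdegen.iupac import IUPAC_CODES, base_set

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

# Earth Microbiome Project V4 pair and its Dehalococcoides-targeted variant
FWD_515 = "GTGYCAGCMGCCGCGGTAA"
REV_806 = "GGACTACNVGGGTWTCTAAT"
REV_806_M1 = "GGACTACNVGRGTWTCTAAT"


@pytest.fixture(scope="session")
def pair_515_806():
    return (
        PrimerRecord("515F", "forward", FWD_515),
        PrimerRecord("806R", "reverse", REV_806),
    )


@pytest.fixture(scope="session")
def dehalo_fixture():
    """Packaged 38-sequence Dehalococcoides scenario plus backdrop taxa."""
    spec = example_fixture_spec("dehalococcoides")
    database, truth = generate_database(spec)
    return spec, database, truth


@pytest.fixture(scope="session")
def expansion_limit_fixture():
    spec = example_fixture_spec("expansion_limit")
    database, truth = generate_database(spec)
    return spec, database, truth


def _mismatchable_positions(primer: str) -> list[int]:
    # positions (1-based) where some base can fall outside the primer's set
    return [i for i, c in enumerate(primer, start=1) if c != "N"]


def random_fixture_spec(seed: int, n_taxa: int = 2, max_seqs: int = 4) -> FixtureSpec:
    """A small random planted-site database recipe for property tests:
    per taxon, a random share of sequences carries 1-2 planted mismatches
    at random (non-N) primer positions, in either orientation."""
    rng = np.random.default_rng(seed)
    domains = ("Bacteria", "Archaea", "Eukaryota")
    taxa = []
    for i in range(n_taxa):
        n = int(rng.integers(2, max_seqs + 1))
        plans = ()
        n_mismatched = int(rng.integers(0, n + 1))
        if n_mismatched:
            sites = []
            for _ in range(int(rng.integers(1, 3))):
                orientation = "forward" if rng.random() < 0.5 else "reverse"
                primer = FWD_515 if orientation == "forward" else REV_806
                candidates = _mismatchable_positions(primer)
                pos = int(rng.choice(candidates))
                outside = sorted(frozenset("ACGT") - base_set(primer[pos - 1]))
                sites.append(
                    PlantedMismatch(
                        orientation, pos, outside[rng.integers(len(outside))]
                    )
                )
            plans = (MismatchPlan(n_mismatched, tuple(sites)),)
        taxa.append(
            TaxonSpec(
                taxonomy=(domains[i % 3], f"Phylum{i}", f"Genus{i}"),
                n_sequences=n,
                plans=plans,
            )
        )
    return FixtureSpec(
        seed=seed,
        forward_primer=FWD_515,
        reverse_primer=REV_806,
        taxa=tuple(taxa),
        background_length=160,
        f_r_spacing=30,
    )


def random_degenerate_primer(
    rng: np.random.Generator, max_expansion: int = 1024, length_range=(8, 25)
) -> str:
    """Random IUPAC primer whose expansion count stays within a budget."""
    codes = list(IUPAC_CODES)
    while True:
        length = int(rng.integers(*length_range))
        primer = []
        product = 1
        for _ in range(length):
            code = codes[rng.integers(len(codes))]
            if product * len(IUPAC_CODES[code]) > max_expansion:
                code = "ACGT"[rng.integers(4)]
            primer.append(code)
            product *= len(IUPAC_CODES[code])
        if product <= max_expansion:
            return "".join(primer)
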