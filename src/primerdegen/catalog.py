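"""Packaged data: the universal-primer catalog and example fixture specs."""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .fixtures import FixtureSpec

__all__ = ["load_catalog", "catalog_primer_pair", "example_fixture_spec"]

EXAMPLE_SPECS = ("dehalococcoides", "expansion_limit")


def _data(name: str):
    return resources.files("primerdegen").joinpath("data", name)


def load_catalog() -> pd.DataFrame:
    """Catalog of original and improved universal SSU primer pairs
    (columns: name, target_taxon, forward, reverse)."""
    with resources.as_file(_data("primer_catalog.tsv")) as path:
        return pd.read_csv(path, sep="\t")


def catalog_primer_pair(name: str) -> tuple[str, str]:
    """(forward, reverse) sequences of a catalog pair by name."""
    frame = load_catalog()
    hit = frame[frame["name"] == name]
    if hit.empty:
        raise KeyError(
            f"no catalog pair named {name!r}; known: {', '.join(frame['name'])}"
        )
    row = hit.iloc[0]
    return str(row["forward"]), str(row["reverse"])


def example_fixture_spec(name: str) -> FixtureSpec:
    """A packaged synthetic-database recipe (one of EXAMPLE_SPECS)."""
    if name not in EXAMPLE_SPECS:
        raise KeyError(f"no example spec {name!r}; known: {', '.join(EXAMPLE_SPECS)}")
    with resources.as_file(_data(f"{name}.yaml")) as path:
        return FixtureSpec.from_yaml(path)
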