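"""Loaders for the shipped surrogate resource tables.

All resources are plain UTF-8: one-per-line word lists and two-column
tab-separated mapping tables.  Users can point the pseudonymizer at their
own directory with the same file names to override any of them.
"""

from __future__ import annotations

from importlib import resources as ilres
from pathlib import Path

_DATA = "data"

WORD_LISTS = (
    "first_names_female", "first_names_male", "last_names",
    "locations_region", "locations_city", "locations_street",
    "locations_place", "locations_country",
)
TABLES = ("occupations", "companies", "healthcare_units", "location_types")

LOCATION_TYPES = ("region", "city", "street", "place", "country")


def _read_text(name: str, directory: str | Path | None) -> str:
    if directory is not None:
        return (Path(directory) / name).read_text(encoding="utf-8")
    return ilres.files("clindeid").joinpath(_DATA, name).read_text(
        encoding="utf-8")


def load_word_list(name: str, directory: str | Path | None = None) -> list[str]:
    text = _read_text(f"{name}.txt", directory)
    return [line.strip() for line in text.splitlines() if line.strip()]


def load_table(name: str, directory: str | Path | None = None) -> dict[str, str]:
    text = _read_text(f"{name}.tsv", directory)
    table: dict[str, str] = {}
    for lineno, line in enumerate(text.splitlines(), 1):
        if not line.strip():
            continue
        try:
            surface, replacement = line.split("\t")
        except ValueError:
            raise ValueError(f"{name}.tsv:{lineno}: expected two tab-separated "
                             f"columns, got {line!r}")
        table[surface.strip()] = replacement.strip()
    return table


def load_location_lists(directory: str | Path | None = None) -> dict[str, list[str]]:
    return {t: load_word_list(f"locations_{t}", directory)
            for t in LOCATION_TYPES}
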