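"""Genus-level taxonomy reference: trophic guild and colonizer-persister score.

Every faunal index downstream needs two facts about a genus: its trophic
guild -- bacterivore (Ba), fungivore (Fu), plant parasite (Pp) or
omnivore/predator (Op, carnivores folded in) -- and its life-history
(c-p) score on the 1-5 colonizer-persister scale.  A reference table maps
genus names to both.  A default table covering the 35 alpine-meadow genera
of the study system ships with the package; the c-p scores follow the
canonical family-level colonizer-persister assignments from the faunal
analysis literature and can be overridden with a user CSV.
"""
from __future__ import annotations

import csv
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable

from .errors import ParseError, UnknownTaxonError, ValidationError

GUILDS = ("Ba", "Fu", "Pp", "Op")
CP_VALUES = (1, 2, 3, 4, 5)

#: guild code for individuals that could not be resolved; they stay in N for
#: diversity indices but are excluded from every guild-based index.
UNKNOWN_GUILD = "unknown"


@dataclass(frozen=True)
class TaxonEntry:
    """One genus with its trophic guild and c-p life-history score."""

    genus_name: str
    guild: str
    cp_value: int

    def __post_init__(self):
        if self.guild not in GUILDS:
            raise ValidationError(
                f"{self.genus_name!r}: unknown guild code {self.guild!r} "
                f"(expected one of {', '.join(GUILDS)})"
            )
        if self.cp_value not in CP_VALUES:
            raise ValidationError(
                f"{self.genus_name!r}: c-p value {self.cp_value!r} outside 1..5"
            )
        if not self.genus_name:
            raise ValidationError("empty genus name")


class TaxonomyTable:
    """A validated genus -> TaxonEntry mapping with case-insensitive lookup."""

    def __init__(self, entries: Iterable[TaxonEntry]):
        self._by_key: dict[str, TaxonEntry] = {}
        for entry in entries:
            key = entry.genus_name.lower()
            if key in self._by_key:
                raise ValidationError(f"duplicate genus {entry.genus_name!r}")
            self._by_key[key] = entry

    def __len__(self) -> int:
        return len(self._by_key)

    def __iter__(self):
        return iter(self._by_key.values())

    def __contains__(self, genus: str) -> bool:
        return genus.lower() in self._by_key

    def entries(self) -> list[TaxonEntry]:
        return sorted(self._by_key.values(), key=lambda e: e.genus_name)


def classify(genus: str, table: TaxonomyTable) -> TaxonEntry:
    """Resolve a genus name to its TaxonEntry (case-insensitive).

    Raises :class:`UnknownTaxonError` if the genus is absent.
    """
    if len(table) == 0:
        raise ValidationError("taxonomy table is empty")
    entry = table._by_key.get(genus.lower())
    if entry is None:
        raise UnknownTaxonError([genus])
    return entry


def load_taxonomy(path: str | Path) -> TaxonomyTable:
    """Load a taxonomy CSV with header ``genus,guild,cp_value``."""
    path = Path(path)
    entries = []
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise ParseError(f"{path}: empty file") from None
        if [h.strip() for h in header] != ["genus", "guild", "cp_value"]:
            raise ParseError(
                f"{path}: expected header 'genus,guild,cp_value', got {','.join(header)!r}"
            )
        for lineno, row in enumerate(reader, start=2):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if len(row) != 3:
                raise ParseError(f"{path}:{lineno}: expected 3 fields, got {len(row)}")
            genus, guild, cp_raw = (field.strip() for field in row)
            try:
                cp = int(cp_raw)
            except ValueError:
                raise ParseError(
                    f"{path}:{lineno}: c-p value {cp_raw!r} is not an integer"
                ) from None
            entries.append(TaxonEntry(genus, guild, cp))
    try:
        return TaxonomyTable(entries)
    except ValidationError as exc:
        raise ValidationError(f"{path}: {exc}") from None


def write_taxonomy(table: TaxonomyTable, path: str | Path) -> None:
    """Write a taxonomy table back to the CSV interchange format."""
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["genus", "guild", "cp_value"])
        for entry in table.entries():
            writer.writerow([entry.genus_name, entry.guild, entry.cp_value])


def default_taxonomy() -> TaxonomyTable:
    """The bundled 35-genus reference table for the alpine-meadow system."""
    ref = resources.files("nemafauna.data").joinpath("default_taxonomy.csv")
    with resources.as_file(ref) as path:
        return load_taxonomy(path)
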