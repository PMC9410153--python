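"""Versioned weight tables for the two regimen-complexity instruments.

The MRCI (medication regimen complexity index) is the weighted sum of three
sections — dosage form (A), dosing frequency (B) and additional
administration directions (C) — while the critical-care score (MRC-ICU)
assigns a fixed point weight to each listed agent or agent class.  The
scoring engine is weight-table independent: tables are data, shipped as
editable TSV files with a ``# version:`` header, and every item key used by
an order must resolve in the matching table.
"""

from __future__ import annotations

import csv
import difflib
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

INSTRUMENTS = ("MRCI_A", "MRCI_B", "MRCI_C", "MRC_ICU")

#: default file name for each instrument inside a weights directory
WEIGHT_FILENAMES = {
    "MRCI_A": "mrci_section_a.tsv",
    "MRCI_B": "mrci_section_b.tsv",
    "MRCI_C": "mrci_section_c.tsv",
    "MRC_ICU": "mrc_icu_items.tsv",
}

#: the two anchor weights printed for the critical-care instrument; any
#: MRC_ICU table must reproduce them (vancomycin 3 points, continuous
#: intravenous saline 1 point).
MRC_ICU_ANCHORS = {"vancomycin": 3.0, "continuous_iv_saline": 1.0}


class WeightTableError(ValueError):
    """Malformed weight table or unresolvable item key."""


class UnknownItemKeyError(WeightTableError, KeyError):
    """An order references an item key absent from its weight table."""

    def __init__(self, instrument: str, key: str, suggestions: list[str]):
        self.instrument = instrument
        self.key = key
        self.suggestions = suggestions
        hint = f"; closest known keys: {suggestions}" if suggestions else ""
        super().__init__(f"unknown {instrument} item key {key!r}{hint}")


@dataclass(frozen=True)
class WeightTable:
    """Mapping from instrument item keys to nonnegative point weights."""

    instrument: str
    entries: Mapping[str, float]
    version: str = "unversioned"
    notes: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self):
        if self.instrument not in INSTRUMENTS:
            raise WeightTableError(
                f"instrument must be one of {INSTRUMENTS}, got {self.instrument!r}"
            )
        for key, w in self.entries.items():
            if not (float(w) >= 0.0):
                raise WeightTableError(
                    f"{self.instrument} weight for {key!r} must be >= 0, got {w}"
                )
        if self.instrument == "MRC_ICU":
            for key, w in MRC_ICU_ANCHORS.items():
                if key not in self.entries:
                    raise WeightTableError(
                        f"MRC_ICU table must contain the anchor item {key!r}"
                    )
                if float(self.entries[key]) != w:
                    raise WeightTableError(
                        f"MRC_ICU anchor {key!r} must weigh {w}, "
                        f"got {self.entries[key]}"
                    )

    def __contains__(self, key: str) -> bool:
        return key in self.entries

    def weight(self, key: str) -> float:
        try:
            return float(self.entries[key])
        except KeyError:
            raise UnknownItemKeyError(self.instrument, key, self.suggest(key)) from None

    def suggest(self, key: str, n: int = 3) -> list[str]:
        """Nearest known item keys, for actionable load errors."""
        return difflib.get_close_matches(key, list(self.entries), n=n, cutoff=0.4)


def load_weight_table(path: str | Path, instrument: str) -> WeightTable:
    """Read one TSV weight table.

    Lines starting with ``#`` are comments; a leading ``# version:`` line sets
    the table version.  Columns: ``item_key``, ``weight``, optional ``notes``.
    """
    path = Path(path)
    version = "unversioned"
    rows: list[dict[str, str]] = []
    with path.open(newline="") as fh:
        data_lines = []
        for line in fh:
            stripped = line.strip()
            if stripped.startswith("#"):
                body = stripped.lstrip("#").strip()
                if body.lower().startswith("version:"):
                    version = body.split(":", 1)[1].strip()
                continue
            if stripped:
                data_lines.append(line)
        reader = csv.DictReader(data_lines, delimiter="\t")
        if reader.fieldnames is None or "item_key" not in reader.fieldnames \
                or "weight" not in reader.fieldnames:
            raise WeightTableError(
                f"{path}: expected tab-separated columns 'item_key' and 'weight'"
            )
        rows = list(reader)

    entries: dict[str, float] = {}
    notes: dict[str, str] = {}
    for row in rows:
        key = row["item_key"].strip()
        if key in entries:
            raise WeightTableError(f"{path}: duplicate item key {key!r}")
        try:
            entries[key] = float(row["weight"])
        except ValueError:
            raise WeightTableError(
                f"{path}: non-numeric weight {row['weight']!r} for {key!r}"
            ) from None
        if row.get("notes"):
            notes[key] = row["notes"].strip()
    return WeightTable(instrument=instrument, entries=entries,
                       version=version, notes=notes)


def load_weight_dir(path: str | Path) -> dict[str, WeightTable]:
    """Load the four instrument tables from a directory of TSV files."""
    path = Path(path)
    tables = {}
    for instrument, fname in WEIGHT_FILENAMES.items():
        fpath = path / fname
        if not fpath.exists():
            raise WeightTableError(f"missing weight table file {fpath}")
        tables[instrument] = load_weight_table(fpath, instrument)
    return tables


def default_weight_tables() -> dict[str, WeightTable]:
    """The packaged default tables (editable anchors-plus-defaults set)."""
    base = resources.files("mrcomplexity").joinpath("data/weights")
    with resources.as_file(base) as dirpath:
        return load_weight_dir(dirpath)
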