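"""Curated reference tables shipped with the package.

Machine-readable transcriptions of the published result tables from the
carp skeletal-muscle small-RNA survey this pipeline re-implements:

- T1: the 7 novel carp miRNAs with mature sequence and read frequency;
- T2: the 31 carp miRNAs whose catalog presence is restricted to teleosts,
  with the species carrying each one;
- T3: the 16 carp miRNAs with demonstrated muscle roles in other species;

plus the 11-miRNA muscle panel profiled by qPCR.  The files are frozen and
checksummed: they are an acceptance surface, never regenerated.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from importlib import resources
from typing import Optional

_CHECKSUMS = {
    "T1": "3b300d31a94ccc62c83c34633648b1a483bcfad4dd3af81aaf4e3f445e1ac377",
    "T2": "9e1c3ab50665a3c30e17ac8efaa12c1b87248f2dedf928d2d81fa07e133b84f8",
    "T3": "f3f15215a0e0e1bda7361676dcca922c53d872c6f94e89d8defc4fa4807e21c8",
}

TABLE_IDS = tuple(_CHECKSUMS)


@dataclass(frozen=True)
class PrintedTableRow:
    table_id: str
    mirna: str
    sequence: str  # RNA, uppercase
    frequency: int
    conserved_species: Optional[tuple[str, ...]] = None  # T2
    literature_species: Optional[tuple[str, ...]] = None  # T3


def _read_raw(table_id: str) -> str:
    path = resources.files("carpmir").joinpath(f"data/paper_tables/table_{table_id}.tsv")
    return path.read_text()


def load_table(table_id: str) -> list[PrintedTableRow]:
    """Load one of the frozen tables (T1, T2 or T3) with checksum verification."""
    if table_id not in _CHECKSUMS:
        raise ValueError(f"unknown table id {table_id!r}; expected one of {TABLE_IDS}")
    raw = _read_raw(table_id)
    digest = hashlib.sha256(raw.encode()).hexdigest()
    if digest != _CHECKSUMS[table_id]:
        raise RuntimeError(f"table {table_id} fixture corrupted (checksum mismatch)")
    lines = raw.strip().split("\n")
    rows = []
    for line in lines[1:]:
        fields = line.split("\t")
        name, seq, freq = fields[0], fields[1].upper(), int(fields[2])
        if set(seq) - set("ACGU"):
            raise RuntimeError(f"table {table_id}: non-RNA sequence for {name}")
        conserved = literature = None
        if table_id == "T2":
            conserved = tuple(fields[3].split())
            if not conserved:
                raise RuntimeError(f"table T2 row {name} lacks species codes")
        elif table_id == "T3":
            literature = tuple(fields[3].split())
        rows.append(
            PrintedTableRow(
                table_id=table_id,
                mirna=name,
                sequence=seq,
                frequency=freq,
                conserved_species=conserved,
                literature_species=literature,
            )
        )
    return rows


def table_summary(rows: list[PrintedTableRow]) -> tuple[int, PrintedTableRow, int]:
    """(row count, highest-frequency row, total frequency) of a loaded table."""
    if not rows:
        raise ValueError("empty table")
    max_row = max(rows, key=lambda r: r.frequency)
    return len(rows), max_row, sum(r.frequency for r in rows)


def load_muscle_panel() -> list[str]:
    """The 11 muscle-development miRNAs profiled across tissues and stages."""
    path = resources.files("carpmir").joinpath("data/muscle_panel.txt")
    return [l for l in path.read_text().strip().split("\n") if l]
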