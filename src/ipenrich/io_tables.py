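"""Reading and writing MaxQuant-style proteinGroups tables and result tables.

The input dialect is the tab-separated ``proteinGroups.txt`` file MaxQuant
writes: one header row, one row per protein group, ``+`` in the QC flag
columns (``Potential contaminant``, ``Reverse``, ``Only identified by
site``), and LFQ intensity columns in which a stored ``0`` (or an empty
cell) means "not quantified".  Column headers are never hard-coded; a
role -> header map selects the bait/control/peptide/flag columns.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Mapping, Optional, Sequence

import pandas as pd

#: Roles that must be present in every column map.
REQUIRED_ROLES = ("protein_ids", "peptides", "bait", "control")

#: Optional roles and the MaxQuant headers they default to.
OPTIONAL_ROLES = ("gene_names", "contaminant", "reverse", "site_only")

#: Default role -> header map for a stock proteinGroups.txt.  The bait and
#: control headers carry MaxQuant sample names and must usually be overridden.
DEFAULT_COLUMN_MAP: dict[str, str] = {
    "protein_ids": "Protein IDs",
    "gene_names": "Gene names",
    "peptides": "Razor + unique peptides",
    "bait": "LFQ intensity bait",
    "control": "LFQ intensity control",
    "contaminant": "Potential contaminant",
    "reverse": "Reverse",
    "site_only": "Only identified by site",
}


class ColumnMappingError(KeyError):
    """A mapped column is absent from the file, or a required role is unmapped."""


class TableParseError(ValueError):
    """A cell could not be parsed; the message carries the data-row index."""


@dataclass
class ProteinRecord:
    """One row of a proteinGroups-style table.

    ``lfq_bait`` / ``lfq_control`` are strictly positive intensities or
    ``None`` for missing (the source dialect stores 0 for "not quantified").
    """

    protein_ids: str
    gene_names: str = ""
    peptides_razor_unique: int = 0
    lfq_bait: Optional[float] = None
    lfq_control: Optional[float] = None
    is_contaminant: bool = False
    is_reverse: bool = False
    is_site_only: bool = False

    def __post_init__(self) -> None:
        if self.peptides_razor_unique < 0:
            raise ValueError("peptides_razor_unique must be >= 0")
        for value in (self.lfq_bait, self.lfq_control):
            if value is not None and not value > 0:
                raise ValueError("LFQ intensities must be strictly positive or None")


@dataclass
class ProteinTable:
    """An ordered collection of :class:`ProteinRecord` plus its column map."""

    records: list[ProteinRecord]
    column_map: dict[str, str] = field(default_factory=lambda: dict(DEFAULT_COLUMN_MAP))

    def __post_init__(self) -> None:
        missing = [r for r in REQUIRED_ROLES if r not in self.column_map]
        if missing:
            raise ColumnMappingError(
                "column map misses required role(s): " + ", ".join(missing)
            )
        ids = [rec.protein_ids for rec in self.records]
        if len(ids) != len(set(ids)):
            seen: set[str] = set()
            dup = next(i for i in ids if i in seen or seen.add(i))  # type: ignore[func-returns-value]
            raise ValueError(f"duplicate protein_ids in table: {dup!r}")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[ProteinRecord]:
        return iter(self.records)


def _parse_intensity(cell: object, row_index: int, column: str) -> Optional[float]:
    if cell is None or (isinstance(cell, float) and math.isnan(cell)):
        return None
    text = str(cell).strip()
    if text == "" or text.upper() == "NAN":
        return None
    try:
        value = float(text)
    except ValueError as exc:
        raise TableParseError(
            f"non-numeric intensity {text!r} in column {column!r} at data row {row_index}"
        ) from exc
    if value < 0:
        raise TableParseError(
            f"negative intensity {value} in column {column!r} at data row {row_index}"
        )
    return None if value == 0 else value


def _parse_flag(cell: object) -> bool:
    if cell is None or (isinstance(cell, float) and math.isnan(cell)):
        return False
    return str(cell).strip() == "+"


def _parse_count(cell: object, row_index: int, column: str) -> int:
    text = "" if cell is None else str(cell).strip()
    if text == "" or text.upper() == "NAN":
        return 0
    try:
        value = int(float(text))
    except ValueError as exc:
        raise TableParseError(
            f"non-numeric peptide count {text!r} in column {column!r} "
            f"at data row {row_index}"
        ) from exc
    if value < 0:
        raise TableParseError(
            f"negative peptide count {value} in column {column!r} at data row {row_index}"
        )
    return value


def read_protein_groups(
    path: str | Path, column_map: Mapping[str, str] | None = None
) -> ProteinTable:
    """Read a tab-separated proteinGroups-style table.

    Parameters
    ----------
    path:
        Tab-separated file with a header row.
    column_map:
        Role -> header mapping; defaults to :data:`DEFAULT_COLUMN_MAP`.
        Roles ``protein_ids``, ``peptides``, ``bait`` and ``control`` are
        mandatory.  Optional roles whose header is absent from the map are
        filled with defaults (empty gene names, all flags false).

    Raises
    ------
    ColumnMappingError
        If a mapped column does not exist in the file.
    TableParseError
        If an intensity or count cell cannot be parsed.
    """
    cmap = dict(DEFAULT_COLUMN_MAP if column_map is None else column_map)
    missing_roles = [r for r in REQUIRED_ROLES if r not in cmap]
    if missing_roles:
        raise ColumnMappingError(
            "column map misses required role(s): " + ", ".join(missing_roles)
        )
    frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for role in REQUIRED_ROLES:
        if cmap[role] not in frame.columns:
            raise ColumnMappingError(
                f"mapped column {cmap[role]!r} (role {role!r}) not found in {path}"
            )
    # Optional roles mapped to absent columns are dropped, MaxQuant omits
    # some flag columns in reduced exports.
    present = {
        role: header
        for role, header in cmap.items()
        if header in frame.columns
    }
    records: list[ProteinRecord] = []
    for row_index, row in enumerate(frame.itertuples(index=False)):
        row_map = dict(zip(frame.columns, row))
        records.append(
            ProteinRecord(
                protein_ids=str(row_map[present["protein_ids"]]).strip(),
                gene_names=str(row_map.get(present.get("gene_names", ""), "")).strip(),
                peptides_razor_unique=_parse_count(
                    row_map[present["peptides"]], row_index, present["peptides"]
                ),
                lfq_bait=_parse_intensity(
                    row_map[present["bait"]], row_index, present["bait"]
                ),
                lfq_control=_parse_intensity(
                    row_map[present["control"]], row_index, present["control"]
                ),
                is_contaminant=_parse_flag(row_map.get(present.get("contaminant", ""))),
                is_reverse=_parse_flag(row_map.get(present.get("reverse", ""))),
                is_site_only=_parse_flag(row_map.get(present.get("site_only", ""))),
            )
        )
    return ProteinTable(records=records, column_map=cmap)


def write_protein_groups(path: str | Path, table: ProteinTable) -> None:
    """Write a :class:`ProteinTable` back to the proteinGroups dialect.

    Missing intensities are stored as 0 and flags as ``+``/empty, so the
    output re-parses to an identical table.
    """
    cmap = table.column_map
    columns = {
        cmap["protein_ids"]: [r.protein_ids for r in table],
        cmap.get("gene_names", "Gene names"): [r.gene_names for r in table],
        cmap["peptides"]: [r.peptides_razor_unique for r in table],
        cmap["bait"]: [0 if r.lfq_bait is None else r.lfq_bait for r in table],
        cmap["control"]: [0 if r.lfq_control is None else r.lfq_control for r in table],
        cmap.get("contaminant", "Potential contaminant"): [
            "+" if r.is_contaminant else "" for r in table
        ],
        cmap.get("reverse", "Reverse"): ["+" if r.is_reverse else "" for r in table],
        cmap.get("site_only", "Only identified by site"): [
            "+" if r.is_site_only else "" for r in table
        ],
    }
    pd.DataFrame(columns).to_csv(path, sep="\t", index=False, float_format="%.12g")


#: Fixed column order of the result table (documented in the README).
ENRICHMENT_COLUMNS = (
    "protein_ids",
    "gene_names",
    "peptides_razor_unique",
    "log10_bait",
    "log10_control",
    "control_imputed",
    "log2_ratio",
    "bin_index",
    "significance",
    "direction",
)


def write_enrichment_table(path: str | Path, results: Sequence) -> None:
    """Write enrichment records as a tab-separated table with a fixed column
    order; floats are stored with 12 significant digits so a round trip
    reproduces ratios to better than 1e-9."""
    rows = {
        col: [getattr(rec, col) for rec in results] for col in ENRICHMENT_COLUMNS
    }
    pd.DataFrame(rows, columns=list(ENRICHMENT_COLUMNS)).to_csv(
        path, sep="\t", index=False, float_format="%.12g"
    )


def read_enrichment_table(path: str | Path) -> list:
    """Read a table written by :func:`write_enrichment_table`."""
    from .enrichment import EnrichmentRecord  # local import avoids a cycle

    frame = pd.read_csv(path, sep="\t", keep_default_na=False, dtype=str)
    missing = [c for c in ENRICHMENT_COLUMNS if c not in frame.columns]
    if missing:
        raise ColumnMappingError(
            "enrichment table misses column(s): " + ", ".join(missing)
        )
    records = []
    for row in frame.itertuples(index=False):
        row_map = dict(zip(frame.columns, row))
        records.append(
            EnrichmentRecord(
                protein_ids=row_map["protein_ids"],
                gene_names=row_map["gene_names"],
                peptides_razor_unique=int(row_map["peptides_razor_unique"]),
                log10_bait=float(row_map["log10_bait"]),
                log10_control=float(row_map["log10_control"]),
                control_imputed=row_map["control_imputed"] in ("True", "true", "1"),
                log2_ratio=float(row_map["log2_ratio"]),
                bin_index=int(row_map["bin_index"]),
                significance=int(row_map["significance"]),
                direction=row_map["direction"],
            )
        )
    return records
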