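"""Microarray-style differential-expression tables and volcano filtering.

Each table row carries an isoform-level identifier (``seqname``), a gene-level
identifier (``GeneSymbol``), an absolute (non-log) fold change, a t-test
p-value and a regulation direction.  The volcano filter keeps records with
FC(abs) >= fc_min and p <= p_max — boundary values are kept on both axes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Union

import pandas as pd

log = logging.getLogger(__name__)

#: default header names, overridable via ``columns=`` mappings
DEFAULT_COLUMNS = {
    "seqname": "seqname",
    "gene_symbol": "GeneSymbol",
    "fold_change_abs": "FCAbs",
    "p_value": "PValue",
    "direction": "direction",
}


class SchemaError(ValueError):
    """A DEG table is missing required columns."""


@dataclass(frozen=True)
class DEGRecord:
    """One microarray row: isoform id, gene id, FC(abs), p, direction."""

    seqname: str
    gene_symbol: str
    fold_change_abs: float
    p_value: float
    direction: str
    condition: str = ""

    def __post_init__(self):
        if self.fold_change_abs < 0:
            raise ValueError(f"{self.seqname}: fold_change_abs must be >= 0")
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError(f"{self.seqname}: p_value must lie in [0,1]")
        if self.direction not in ("up", "down"):
            raise ValueError(f"{self.seqname}: direction must be 'up' or 'down'")


@dataclass
class ConditionList:
    """Volcano-passing records of one condition and one direction."""

    condition: str
    records: List[DEGRecord] = field(default_factory=list)

    @property
    def size(self) -> int:
        return len(self.records)

    @property
    def direction(self) -> Optional[str]:
        return self.records[0].direction if self.records else None

    def seqnames(self) -> set:
        return {r.seqname for r in self.records}

    def gene_symbols(self) -> set:
        return {r.gene_symbol for r in self.records}

    def by_gene(self) -> Dict[str, List[DEGRecord]]:
        out: Dict[str, List[DEGRecord]] = {}
        for r in self.records:
            out.setdefault(r.gene_symbol, []).append(r)
        return out

    def validate(self) -> "ConditionList":
        if len({r.seqname for r in self.records}) != len(self.records):
            raise ValueError(f"{self.condition}: duplicate seqnames in condition list")
        if len({r.direction for r in self.records}) > 1:
            raise ValueError(f"{self.condition}: mixed regulation directions")
        return self


def read_deg_table(
    path: Union[str, Path],
    condition: str,
    columns: Optional[Mapping[str, str]] = None,
) -> List[DEGRecord]:
    """Read one TSV of microarray output into DEGRecords.

    Rows with a blank seqname or gene symbol are dropped with a logged count.
    Duplicate seqnames keep the smallest-p row (a warning is logged; vendor
    tables are not guaranteed unique).
    """
    colmap = dict(DEFAULT_COLUMNS)
    if columns:
        colmap.update(columns)
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    missing = [v for v in colmap.values() if v not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required columns {missing}")

    records: List[DEGRecord] = []
    n_blank = 0
    for lineno, row in enumerate(df.itertuples(index=False), 2):
        row = dict(zip(df.columns, row))
        seqname = (row[colmap["seqname"]] or "").strip() if row[colmap["seqname"]] == row[colmap["seqname"]] else ""
        gene = (row[colmap["gene_symbol"]] or "").strip() if row[colmap["gene_symbol"]] == row[colmap["gene_symbol"]] else ""
        if not seqname or not gene:
            n_blank += 1
            continue
        try:
            fc = float(row[colmap["fold_change_abs"]])
            p = float(row[colmap["p_value"]])
        except (TypeError, ValueError) as exc:
            raise ValueError(f"{path}: line {lineno}: non-numeric FC or p-value") from exc
        records.append(
            DEGRecord(seqname, gene, fc, p, str(row[colmap["direction"]]).strip(), condition)
        )
    if n_blank:
        log.info("%s: dropped %d rows with blank seqname/GeneSymbol", path, n_blank)

    dedup: Dict[str, DEGRecord] = {}
    n_dup = 0
    for r in records:
        prev = dedup.get(r.seqname)
        if prev is None or r.p_value < prev.p_value:
            if prev is not None:
                n_dup += 1
            dedup[r.seqname] = r
        elif prev is not None:
            n_dup += 1
    if n_dup:
        log.warning("%s: %d duplicate seqname rows collapsed (kept smallest p)", path, n_dup)
        records = list(dedup.values())
    return records


def volcano_filter(
    records: Iterable[DEGRecord],
    fc_min: float = 2.0,
    p_max: float = 0.05,
    direction: Optional[str] = None,
    condition: Optional[str] = None,
) -> ConditionList:
    """Keep records with FC(abs) >= fc_min and p <= p_max (boundaries kept)."""
    if fc_min < 1:
        raise ValueError(f"fc_min must be >= 1, got {fc_min}")
    if not 0 < p_max <= 1:
        raise ValueError(f"p_max must lie in (0, 1], got {p_max}")
    records = list(records)
    kept = [
        r
        for r in records
        if r.fold_change_abs >= fc_min
        and r.p_value <= p_max
        and (direction is None or r.direction == direction)
    ]
    label = condition or (kept[0].condition if kept else (records[0].condition if records else ""))
    return ConditionList(condition=label, records=kept).validate()


def merge_and_sort(a: ConditionList, b: ConditionList) -> List[DEGRecord]:
    """Concatenate two condition lists and stably sort by gene symbol.

    The sort is case-insensitive on the gene symbol with ties broken by
    condition label then seqname, mirroring the merge of two per-condition
    spreadsheets into a single symbol-sorted column.
    """
    if a.records and b.records and a.direction != b.direction:
        raise ValueError("merge_and_sort requires lists of the same regulation direction")
    merged = list(a.records) + list(b.records)
    merged.sort(key=lambda r: (r.gene_symbol.lower(), r.condition, r.seqname))
    return merged


def write_deg_table(records: Sequence[DEGRecord], path: Union[str, Path],
                    columns: Optional[Mapping[str, str]] = None,
                    header_lines: Sequence[str] = ()) -> None:
    """Write records as a TSV readable by :func:`read_deg_table`."""
    colmap = dict(DEFAULT_COLUMNS)
    if columns:
        colmap.update(columns)
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        fh.write(
            "\t".join(
                colmap[k]
                for k in ("seqname", "gene_symbol", "fold_change_abs", "p_value", "direction")
            )
            + "\n"
        )
        for r in records:
            fh.write(
                f"{r.seqname}\t{r.gene_symbol}\t{r.fold_change_abs:.6g}\t"
                f"{r.p_value:.6g}\t{r.direction}\n"
            )
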