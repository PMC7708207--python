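"""Count tables: strata × categories matrices of non-negative integers.

A table is read from CSV/TSV (first column = stratum label, header row =
category labels, strictly integer cells) and sliced into
:class:`~sdi.counts.CountVector` rows or columns.  Both orientations are
meaningful: a district analysed across age classes uses its *row* (S =
number of age classes, n = row total), while an age profile analysed
across districts uses its *column* (S = number of districts, n = column
total).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .counts import CountVector
from .errors import ParseError

__all__ = ["CountTable", "read_count_table", "write_count_table"]


@dataclass(frozen=True)
class CountTable:
    """Rectangular table of counts with unique stratum/category labels."""

    data: pd.DataFrame  # index = strata, columns = categories, int cells

    def __post_init__(self):
        df = self.data
        if df.empty:
            raise ParseError("count table is empty")
        if df.index.duplicated().any():
            dup = df.index[df.index.duplicated()][0]
            raise ParseError(f"duplicate stratum label {dup!r}")
        if df.columns.duplicated().any():
            dup = df.columns[df.columns.duplicated()][0]
            raise ParseError(f"duplicate category label {dup!r}")
        if (df.values < 0).any():
            r, c = np.argwhere(df.values < 0)[0]
            raise ParseError(
                f"negative count at row {df.index[r]!r}, column {df.columns[c]!r}")

    @property
    def strata(self) -> list[str]:
        return list(self.data.index)

    @property
    def categories(self) -> list[str]:
        return list(self.data.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    @property
    def grand_total(self) -> int:
        return int(self.data.values.sum())

    def row_vector(self, stratum: str) -> CountVector:
        """Counts of one stratum across categories (n = row total)."""
        if stratum not in self.data.index:
            raise KeyError(stratum)
        row = self.data.loc[stratum]
        return CountVector(row.tolist(), labels=self.categories)

    def col_vector(self, category: str) -> CountVector:
        """Counts of one category across strata (n = column total)."""
        if category not in self.data.columns:
            raise KeyError(category)
        col = self.data[category]
        return CountVector(col.tolist(), labels=self.strata)

    def iter_rows(self):
        for s in self.strata:
            yield s, self.row_vector(s)

    def iter_cols(self):
        for c in self.categories:
            yield c, self.col_vector(c)


def _sniff_delimiter(path: Path, dialect: str | None) -> str:
    if dialect == "csv":
        return ","
    if dialect == "tsv":
        return "\t"
    if dialect is not None:
        raise ParseError(f"unknown dialect {dialect!r} (use 'csv' or 'tsv')")
    if path.suffix.lower() in (".tsv", ".tab"):
        return "\t"
    return ","


def read_count_table(path, dialect: str | None = None) -> CountTable:
    """Read and validate a count table from a delimited text file.

    Strict integer coercion: floats, blanks, negatives and ragged rows
    are parse errors naming the offending row/column.
    """
    path = Path(path)
    delim = _sniff_delimiter(path, dialect)
    with open(path, newline="", encoding="utf-8") as fh:
        rows = list(csv.reader(fh, delimiter=delim))
    if len(rows) < 2:
        raise ParseError(f"{path}: need a header row and at least one data row")
    header = rows[0]
    if len(header) < 2:
        raise ParseError(f"{path}: header must list at least one category")
    categories = [c.strip() for c in header[1:]]
    strata, matrix = [], []
    for lineno, row in enumerate(rows[1:], start=2):
        if len(row) != len(header):
            raise ParseError(
                f"{path}:{lineno}: expected {len(header)} cells, got {len(row)}")
        strata.append(row[0].strip())
        vals = []
        for cat, cell in zip(categories, row[1:]):
            cell = cell.strip()
            try:
                if cell == "" or not cell.lstrip("-").isdigit():
                    raise ValueError
                v = int(cell)
            except ValueError:
                raise ParseError(
                    f"{path}:{lineno}: non-integer cell {cell!r} in column {cat!r}"
                ) from None
            vals.append(v)
        matrix.append(vals)
    df = pd.DataFrame(matrix, index=strata, columns=categories, dtype=int)
    return CountTable(df)


def write_count_table(table: CountTable, path, dialect: str | None = None) -> None:
    """Write a table back out; round-trips exactly through read."""
    path = Path(path)
    delim = _sniff_delimiter(path, dialect)
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter=delim)
        writer.writerow(["stratum", *table.categories])
        for s in table.strata:
            writer.writerow([s, *table.data.loc[s].tolist()])
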