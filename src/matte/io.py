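"""Reading and writing the pipeline's plain-text formats.

Expression files are TSV/CSV with genes in rows (first column = gene id,
header = sample ids).  Phenotype files are two-column sample/label text.
Delimiters are inferred from the extension (``.csv`` -> comma, anything
else -> tab) unless given explicitly.
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .datatypes import ExpressionMatrix, PhenotypeTable
from .errors import ParseError, ValidationError

FLOAT_FORMAT = "%.10g"


def detect_delimiter(path: str | Path, delimiter: str | None = None) -> str:
    if delimiter is not None:
        return delimiter
    return "," if str(path).endswith(".csv") else "\t"


def read_expression(
    path: str | Path,
    delimiter: str | None = None,
    unit: str = "arbitrary",
) -> ExpressionMatrix:
    """Read a genes x samples matrix; errors name the offending cell."""
    sep = detect_delimiter(path, delimiter)
    raw = pd.read_csv(path, sep=sep, index_col=0, dtype=str)
    raw.index = raw.index.astype(str)
    raw.columns = raw.columns.astype(str)
    numeric = raw.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & raw.notna()
    if bad.to_numpy().any():
        g, s = np.argwhere(bad.to_numpy())[0]
        raise ParseError(
            f"non-numeric cell {raw.iat[g, s]!r} at gene {raw.index[g]!r} "
            f"(row {g + 2}), sample {raw.columns[s]!r} (column {s + 2})"
        )
    if numeric.isna().to_numpy().any():
        g, s = np.argwhere(numeric.isna().to_numpy())[0]
        raise ParseError(
            f"missing value at gene {raw.index[g]!r}, sample {raw.columns[s]!r}"
        )
    return ExpressionMatrix(numeric.astype(float), unit=unit)


def write_expression(
    expr: ExpressionMatrix, path: str | Path, delimiter: str | None = None
) -> None:
    sep = detect_delimiter(path, delimiter)
    expr.values.to_csv(path, sep=sep, float_format=FLOAT_FORMAT)


def read_phenotypes(path: str | Path, delimiter: str | None = None) -> PhenotypeTable:
    """Read a two-column sample/phenotype table; header row auto-detected."""
    sep = detect_delimiter(path, delimiter)
    pairs: list[tuple[str, str]] = []
    with open(path, newline="") as fh:
        for i, row in enumerate(csv.reader(fh, delimiter=sep)):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if len(row) < 2:
                raise ParseError(f"line {i + 1}: expected 2 columns, got {len(row)}")
            sample, label = row[0].strip(), row[1].strip()
            if i == 0 and label.lower() == "phenotype":
                continue  # header row
            pairs.append((sample, label))
    if not pairs:
        raise ParseError(f"no sample/phenotype rows in {path}")
    return PhenotypeTable.from_pairs(pairs)


def write_phenotypes(
    pheno: PhenotypeTable, path: str | Path, delimiter: str | None = None
) -> None:
    sep = detect_delimiter(path, delimiter)
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter=sep, lineterminator="\n")
        w.writerow(["sample", "phenotype"])
        for sample, label in pheno.assignments.items():
            w.writerow([sample, label])


def read_label_file(path: str | Path, delimiter: str | None = None) -> pd.Series:
    """Read an id/value two-column file into a Series (used by ``matte eval``)."""
    sep = detect_delimiter(path, delimiter)
    df = pd.read_csv(path, sep=sep, header=None, dtype=str, comment="#")
    if df.shape[1] < 2:
        raise ValidationError(f"{path}: expected two columns (id, value)")
    first = df.iloc[0, 0]
    # tolerate a header row
    if first.lower() in ("id", "gene", "sample", "item"):
        df = df.iloc[1:]
    return pd.Series(df.iloc[:, 1].to_numpy(), index=df.iloc[:, 0].to_numpy())


def write_tsv(df: pd.DataFrame, path: str | Path, index: bool = True) -> None:
    df.to_csv(path, sep="\t", float_format=FLOAT_FORMAT, index=index)


def write_gene_list(genes: Sequence[str], path: str | Path) -> None:
    Path(path).write_text("".join(f"{g}\n" for g in genes))
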