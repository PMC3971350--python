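"""Reading and writing the delimited-text formats.

Expression input is the lingua franca downstream of RMA-style
preprocessing: a delimited matrix, first column gene ids, header row of
sample ids, values on a log-like scale. TSV or CSV is auto-detected from
the header line unless forced.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .containers import validate_expression
from .errors import ValidationError

__all__ = ["read_expression", "write_expression", "read_covariates", "write_rank_table"]

RANK_COLUMNS = ["sample_id", "gene_id", "rank", "method", "statistic", "sign", "expression"]


def _detect_sep(path: Path, dialect: str | None) -> str:
    if dialect in ("tsv", "\t"):
        return "\t"
    if dialect in ("csv", ","):
        return ","
    if dialect is not None:
        raise ValidationError(f"unknown dialect {dialect!r}; use 'tsv' or 'csv'")
    header = path.open().readline()
    return "\t" if header.count("\t") >= header.count(",") else ","


def read_expression(path, dialect: str | None = None) -> pd.DataFrame:
    """Load and validate a genes x samples expression matrix.

    Rejects duplicate gene/sample ids and missing or non-numeric cells,
    naming the offending coordinates in the error message.
    """
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"no such file: {path}")
    sep = _detect_sep(path, dialect)
    try:
        raw = pd.read_csv(path, sep=sep, index_col=0)
    except Exception as exc:  # parser errors carry the line number
        raise ValidationError(f"cannot parse {path}: {exc}") from exc
    if raw.shape[1] == 0:
        raise ValidationError(f"{path}: no sample columns found (separator {sep!r})")
    raw.index = raw.index.astype(str)
    raw.columns = raw.columns.astype(str)
    return validate_expression(raw)


def write_expression(expr: pd.DataFrame, path, dialect: str = "tsv") -> None:
    """Write a matrix in the same shape ``read_expression`` accepts,
    at full float precision (round-trips exactly)."""
    sep = "\t" if dialect == "tsv" else ","
    expr.to_csv(path, sep=sep, index_label="gene_id", float_format="%.17g")


def read_covariates(path) -> pd.DataFrame:
    """Load a covariate table: delimited text with header, first column
    sample_id (becomes the index)."""
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"no such file: {path}")
    sep = _detect_sep(path, None)
    table = pd.read_csv(path, sep=sep, index_col=0)
    table.index = table.index.astype(str)
    dup = table.index[table.index.duplicated()].unique().tolist()
    if dup:
        raise ValidationError(f"duplicated sample id(s) in covariate table: {dup[:5]}")
    return table


def write_rank_table(table: pd.DataFrame, path) -> None:
    """Write a rank table as TSV with the stable column order
    sample_id, gene_id, rank, method, statistic, sign, expression."""
    if table.empty and not len(table.columns):
        table = pd.DataFrame(columns=RANK_COLUMNS)
    missing = [c for c in RANK_COLUMNS if c not in table.columns]
    if missing:
        raise ValidationError(f"rank table missing column(s): {missing}")
    table[RANK_COLUMNS].to_csv(path, sep="\t", index=False, float_format="%.10g")
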