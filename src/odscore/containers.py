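"""In-memory containers and validation.

Expression data is carried as a pandas DataFrame of shape genes x samples
(float values on a log-like scale, gene ids as index, sample ids as columns).
``validate_expression`` enforces the matrix contract once at the boundary;
the scoring functions then assume a clean matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd

from .errors import ValidationError

__all__ = ["validate_expression", "ScoreMatrix"]


def validate_expression(expr: pd.DataFrame, min_samples: int = 2) -> pd.DataFrame:
    """Validate a genes x samples expression matrix.

    Requirements: at least one gene, at least ``min_samples`` samples, unique
    gene and sample identifiers, fully numeric with no missing values.
    Returns the matrix as float64 (a cheap view when already float64).

    Raises
    ------
    ValidationError
        With the offending identifier or cell coordinates in the message.
    """
    if not isinstance(expr, pd.DataFrame):
        raise ValidationError("expression matrix must be a pandas DataFrame (genes x samples)")
    n, m = expr.shape
    if n < 1:
        raise ValidationError("expression matrix has no gene rows")
    if m < min_samples:
        raise ValidationError(
            f"expression matrix has {m} sample column(s); at least {min_samples} required"
        )
    dup_genes = expr.index[expr.index.duplicated()].unique().tolist()
    if dup_genes:
        raise ValidationError(f"duplicated gene id(s): {dup_genes[:5]}")
    dup_samples = expr.columns[expr.columns.duplicated()].unique().tolist()
    if dup_samples:
        raise ValidationError(f"duplicated sample id(s): {dup_samples[:5]}")
    try:
        values = expr.to_numpy(dtype=np.float64)
    except (TypeError, ValueError):
        bad = []
        for j, col in enumerate(expr.columns):
            coerced = pd.to_numeric(expr.iloc[:, j], errors="coerce")
            mask = coerced.isna() & expr.iloc[:, j].notna()
            for gene in expr.index[mask][:3]:
                bad.append(f"(gene {gene!r}, sample {col!r})")
        raise ValidationError(f"non-numeric expression value(s) at {', '.join(bad[:5])}") from None
    if np.isnan(values).any():
        gi, sj = np.argwhere(np.isnan(values))[0]
        raise ValidationError(
            f"missing value at (gene {expr.index[gi]!r}, sample {expr.columns[sj]!r})"
        )
    if not np.isfinite(values).all():
        gi, sj = np.argwhere(~np.isfinite(values))[0]
        raise ValidationError(
            f"non-finite value at (gene {expr.index[gi]!r}, sample {expr.columns[sj]!r})"
        )
    if expr.to_numpy().dtype == np.float64:
        return expr
    return pd.DataFrame(values, index=expr.index, columns=expr.columns)


@dataclass
class ScoreMatrix:
    """Per-gene, per-sample outlier statistics from one method.

    Attributes
    ----------
    values : pd.DataFrame
        Genes x samples statistics (a single column when a target sample was
        requested). od/woda/wodb values are >= 0; zscore/rscore carry sign.
    method : str
        One of ``{"zscore", "rscore", "od", "woda", "wodb"}``.
    params : dict
        Method parameters actually used (``k``, ``degenerate_policy``, ...).
    signs : pd.DataFrame or None
        Optional {-1, 0, +1} direction channel (sign of the difference from
        the per-gene median), set by :func:`odscore.scores.assign_sign`.
    flagged_genes : list of str
        Genes with a degenerate scale (zero sd/MAD) or degenerate weights,
        scored NaN under policy "flag".
    """

    values: pd.DataFrame
    method: str
    params: dict[str, Any] = field(default_factory=dict)
    signs: pd.DataFrame | None = None
    flagged_genes: list[str] = field(default_factory=list)

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    def column(self, sample: str) -> pd.Series:
        """Statistics for one sample (raises KeyError on unknown id)."""
        return self.values[sample]
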