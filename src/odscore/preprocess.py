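"""Known-covariate adjustment and cross-sample rank comparison.

Outlier statistics compare one sample against the cohort, so any covariate
that shifts whole groups of samples (gender being the canonical example:
XIST-like genes are high in females, near-zero in males) masquerades as
outlyingness. ``adjust_covariates`` removes such known effects by fitting,
per gene, an ordinary least-squares model of expression on the covariates
and carrying the residual matrix forward in place of the raw expression.

``shared_outliers`` then supports the applied question of dysregulation
shared between samples with a common phenotype: which genes sit in the
top-N rank list of *every* sample of interest.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .containers import validate_expression
from .errors import ValidationError

__all__ = ["read_design", "adjust_covariates", "shared_outliers"]


def read_design(covars: pd.DataFrame, formula: Sequence[str]) -> pd.DataFrame:
    """Build the OLS design matrix: intercept plus one block per covariate.

    Categorical (non-numeric) covariates use treatment coding with the
    first sorted level as reference; numeric covariates enter as given.
    """
    cols = {"Intercept": np.ones(len(covars))}
    for name in formula:
        if name not in covars.columns:
            raise ValidationError(f"unknown covariate {name!r}")
        col = covars[name]
        if col.isna().any():
            raise ValidationError(f"missing values in covariate {name!r}")
        if pd.api.types.is_numeric_dtype(col):
            cols[name] = col.to_numpy(dtype=float)
        else:
            levels = sorted(col.astype(str).unique())
            for level in levels[1:]:  # first sorted level is the reference
                cols[f"{name}[{level}]"] = (col.astype(str) == level).to_numpy(dtype=float)
    return pd.DataFrame(cols, index=covars.index)


def adjust_covariates(
    expr: pd.DataFrame, covars: pd.DataFrame, formula: Sequence[str]
) -> pd.DataFrame:
    """Replace expression with per-gene OLS residuals on the covariates.

    Parameters
    ----------
    expr
        Genes x samples expression matrix.
    covars
        One row per sample, indexed by sample id; must cover every sample
        of ``expr``.
    formula
        Covariate column names to adjust for. An empty list fits the
        intercept only, i.e. per-gene mean centering.

    Returns
    -------
    A genes x samples residual matrix with the same ids. Residuals are
    exactly invariant to any covariate-explainable offset added to the
    input, and the operation is idempotent.

    Raises
    ------
    ValidationError
        On samples missing from the covariate table, or a rank-deficient
        design (message names the collinear columns).
    """
    expr = validate_expression(expr)
    missing = [s for s in expr.columns if s not in covars.index]
    if missing:
        raise ValidationError(f"sample(s) missing from covariate table: {missing[:5]}")
    design = read_design(covars.loc[expr.columns], formula)
    X = design.to_numpy()
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # name the columns whose removal restores full rank
        collinear = [
            design.columns[c]
            for c in range(X.shape[1])
            if np.linalg.matrix_rank(np.delete(X, c, axis=1)) == rank
        ]
        raise ValidationError(f"rank-deficient design; collinear column(s): {collinear}")
    Y = expr.to_numpy().T  # samples x genes
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ beta
    return pd.DataFrame(resid.T, index=expr.index, columns=expr.columns)


def shared_outliers(rank_tables: Mapping, top: int = 10) -> pd.DataFrame:
    """Genes ranked within the top ``top`` of every supplied sample.

    Parameters
    ----------
    rank_tables
        Mapping of sample id -> rank table as produced by
        :func:`odscore.significance.rank_genes` (needs columns ``gene_id``
        and ``rank``); all tables must cover the same gene universe.
    top
        Rank cutoff applied to each sample.

    Returns
    -------
    DataFrame indexed by gene id with one rank column per sample
    (``rank_<sample>``), sorted by the sum of ranks; empty when no gene is
    shared.
    """
    if len(rank_tables) < 2:
        raise ValidationError("need rank tables for at least 2 samples")
    universes = [frozenset(t["gene_id"]) for t in rank_tables.values()]
    if len(set(universes)) != 1:
        raise ValidationError("rank tables cover different gene universes")
    per_sample = {}
    shared: set | None = None
    for sample, table in rank_tables.items():
        ranks = table.set_index("gene_id")["rank"]
        in_top = set(ranks.index[ranks <= top])
        shared = in_top if shared is None else shared & in_top
        per_sample[sample] = ranks
    shared_genes = sorted(shared)
    out = pd.DataFrame(
        {f"rank_{s}": [int(per_sample[s][g]) for g in shared_genes] for s in rank_tables},
        index=pd.Index(shared_genes, name="gene_id"),
    )
    if not out.empty:
        out = out.loc[out.sum(axis=1).sort_values(kind="stable").index]
    return out
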