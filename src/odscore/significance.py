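"""Empirical gene-rank significance for one evaluated sample.

The null here is *gene-wise, within one sample*: a target gene's absolute
statistic is referred to the empirical distribution of the other genes'
absolute statistics in the same sample's score vector. This differs from the
usual across-sample permutation p-value — the denominator is n - 1 (number
of competitor genes), not a permutation count — and it is exactly uniform
when genes are exchangeable.

The empirical FDR is the fraction of the top-S ranked genes that are not
true positives, with S the size of the known truth set (in the benchmark
simulations S = 100, emulating an activated pathway).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .containers import ScoreMatrix
from .errors import ParameterError, ValidationError

__all__ = ["empirical_pvalue", "empirical_fdr", "rank_order", "rank_genes"]


def _as_abs_stats(T) -> np.ndarray:
    T = np.asarray(T, dtype=float)
    if T.ndim != 1:
        raise ValidationError("statistic vector T must be one-dimensional")
    return T


def empirical_pvalue(T, g1: int) -> float:
    """Empirical rank p-value of gene ``g1`` within one sample's statistics.

    p = [ #{i != g1 : T_i > T_g1} + 1/2 * #{i != g1 : T_i = T_g1} ] / (n - 1)

    where T holds the *absolute* statistics of all n genes for the evaluated
    sample. Ties count half. NaN statistics (flagged degenerate genes) are
    treated as non-exceedances but still count in the denominator.
    """
    T = _as_abs_stats(T)
    n = T.size
    if n < 2:
        raise ParameterError("need at least 2 genes for an empirical p-value")
    if not 0 <= g1 < n:
        raise ParameterError(f"gene index {g1} out of range [0, {n - 1}]")
    t0 = T[g1]
    if np.isnan(t0):
        raise ValidationError("target gene statistic is NaN (degenerate gene)")
    others = np.delete(T, g1)
    with np.errstate(invalid="ignore"):
        greater = np.nansum(others > t0)
        equal = np.nansum(others == t0)
    return float((greater + 0.5 * equal) / (n - 1))


def rank_order(T) -> np.ndarray:
    """Indices ordering T by decreasing statistic, ties broken by gene index
    (stable), NaN last. The deterministic order used everywhere downstream."""
    T = _as_abs_stats(T)
    key = np.where(np.isnan(T), -np.inf, -T)
    return np.argsort(key, kind="stable")


def empirical_fdr(T, true_set) -> float:
    """Top-S empirical false discovery rate.

    Ranks genes by decreasing absolute statistic (deterministic tie order of
    :func:`rank_order`) and returns the fraction of the top S = |true_set|
    genes that are not in the truth set. Values lie on {0, 1/S, ..., 1}.
    """
    T = _as_abs_stats(T)
    true_idx = np.unique(np.asarray(list(true_set), dtype=int))
    S = true_idx.size
    if S == 0:
        raise ParameterError("true-positive set is empty")
    if S > T.size or true_idx.min() < 0 or true_idx.max() >= T.size:
        raise ParameterError("true-positive indices out of range")
    top = rank_order(T)[:S]
    false = np.isin(top, true_idx, invert=True).sum()
    return float(false / S)


def rank_genes(
    scores: ScoreMatrix,
    sample,
    top: int | None = None,
    *,
    expr: pd.DataFrame | None = None,
    direction: str = "absolute",
) -> pd.DataFrame:
    """Rank table for one sample: genes by decreasing absolute statistic.

    Parameters
    ----------
    scores
        A ScoreMatrix from any method (signed or magnitude-only).
    sample
        Sample id to rank (must be a column of ``scores.values``).
    top
        Keep the first ``top`` rows (default: all genes).
    expr
        Optional expression matrix; adds the raw expression column.
    direction
        ``"absolute"`` ranks by |statistic| (two-sided, the default);
        ``"positive"`` restricts to up-regulated genes — positive statistic
        for signed methods, sign +1 where a signs channel is present.

    Returns
    -------
    DataFrame with columns sample_id, gene_id, rank, method, statistic,
    sign, expression — one row per gene, rank starting at 1, NaN-scored
    (flagged) genes ranked last.
    """
    if sample not in scores.values.columns:
        raise ValidationError(f"unknown sample id {sample!r}")
    stat = scores.values[sample].to_numpy(dtype=float)
    genes = scores.values.index
    if scores.signs is not None:
        sign = scores.signs[sample].to_numpy(dtype=float)
    elif scores.method in ("zscore", "rscore"):
        sign = np.sign(stat)
    else:
        sign = np.full(stat.size, np.nan)
    keep = np.arange(stat.size)
    if direction == "positive":
        if scores.signs is not None:
            keep = keep[sign > 0]
        elif scores.method in ("zscore", "rscore"):
            keep = keep[stat > 0]
        else:
            raise ValidationError(
                "direction='positive' needs a signs channel on magnitude-only "
                "scores; apply assign_sign first"
            )
    elif direction != "absolute":
        raise ParameterError(f"direction must be 'absolute' or 'positive', got {direction!r}")
    order = keep[rank_order(np.abs(stat[keep]))]
    if top is not None:
        if top < 0:
            raise ParameterError("top must be >= 0")
        order = order[:top]
    table = pd.DataFrame(
        {
            "sample_id": sample,
            "gene_id": genes[order],
            "rank": np.arange(1, order.size + 1),
            "method": scores.method,
            "statistic": stat[order],
            "sign": sign[order],
        }
    )
    if expr is not None:
        table["expression"] = expr.loc[table["gene_id"], sample].to_numpy()
    else:
        table["expression"] = np.nan
    return table
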