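"""Per-gene, per-sample outlier statistics.

Five statistics quantify, for each gene, how far one sample's expression
lies from the rest of a cohort:

* ``zscore``  -- classical standardization, (x - mean) / sd per gene row;
* ``rscore``  -- robust standardization, (x - median) / MAD per gene row;
* ``outlying_degree`` (OD) -- sum of the k smallest absolute expression
  differences between the target sample and the other cohort members;
* ``woda`` -- weighted mean of the k unweighted-nearest differences, weights
  being the sample-level Euclidean dissimilarities;
* ``wodb`` -- differences are weighted *before* the k nearest are selected,
  then summed (weights normalized by the total off-diagonal weight).

OD-family scores are non-negative magnitudes; direction (up/down relative to
the cohort) is attached separately by :func:`assign_sign`.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
from scipy.spatial.distance import squareform, pdist
from scipy.stats import median_abs_deviation

from .containers import ScoreMatrix, validate_expression
from .errors import DegenerateGeneError, ParameterError, ValidationError

__all__ = [
    "zscore",
    "rscore",
    "outlying_degree",
    "sample_weights",
    "woda",
    "wodb",
    "delta",
    "assign_sign",
    "default_k",
]

MAD_CONSTANT = 1.4826  # consistency factor: MAD * 1.4826 estimates sd under normality


def default_k(n_samples: int) -> int:
    """Default neighbor count: floor(m / 2), adequate for cohorts larger
    than ~10 samples; smaller k tolerates less sample-to-sample variability."""
    return max(1, n_samples // 2)


def _check_k(k: int, m: int) -> int:
    if not isinstance(k, (int, np.integer)):
        raise ParameterError(f"k must be an integer, got {k!r}")
    if not 1 <= k <= m - 1:
        raise ParameterError(f"k={k} outside the valid range [1, {m - 1}] for {m} samples")
    return int(k)


def _degenerate(policy: str, flagged: list[str], what: str):
    if policy == "error":
        raise DegenerateGeneError(f"{what}: {flagged[:10]}")
    if policy != "flag":
        raise ParameterError(f"unknown degenerate policy {policy!r}; use 'flag' or 'error'")


def zscore(expr: pd.DataFrame, *, degenerate_policy: str = "flag") -> ScoreMatrix:
    """Standardize each gene row to mean 0 and (sample, m-1 denominator) sd 1.

    Rows with zero standard deviation (constant genes) are scored NaN and
    listed in ``flagged_genes`` under policy ``"flag"`` (default), or raise
    :class:`DegenerateGeneError` under ``"error"``.
    """
    expr = validate_expression(expr)
    x = expr.to_numpy()
    mu = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, ddof=1, keepdims=True)
    zero = sd[:, 0] == 0.0
    flagged = expr.index[zero].tolist()
    if flagged:
        _degenerate(degenerate_policy, flagged, "zero-sd (constant) gene rows")
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (x - mu) / sd
    z[zero, :] = np.nan
    return ScoreMatrix(
        values=pd.DataFrame(z, index=expr.index, columns=expr.columns),
        method="zscore",
        params={"degenerate_policy": degenerate_policy},
        flagged_genes=flagged,
    )


def rscore(
    expr: pd.DataFrame,
    *,
    mad_constant: float = MAD_CONSTANT,
    degenerate_policy: str = "flag",
) -> ScoreMatrix:
    """Robust standardization: (x - median) / (MAD * mad_constant) per gene.

    The default constant 1.4826 makes the scaled MAD a consistent estimator
    of the standard deviation under normality. Zero-MAD rows are handled by
    ``degenerate_policy`` as in :func:`zscore`.
    """
    expr = validate_expression(expr)
    x = expr.to_numpy()
    med = np.median(x, axis=1, keepdims=True)
    mad = median_abs_deviation(x, axis=1) * mad_constant
    zero = mad == 0.0
    flagged = expr.index[zero].tolist()
    if flagged:
        _degenerate(degenerate_policy, flagged, "zero-MAD gene rows")
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (x - med) / mad[:, None]
    r[zero, :] = np.nan
    return ScoreMatrix(
        values=pd.DataFrame(r, index=expr.index, columns=expr.columns),
        method="rscore",
        params={"mad_constant": mad_constant, "degenerate_policy": degenerate_policy},
        flagged_genes=flagged,
    )


def _sample_index(expr: pd.DataFrame, sample) -> int:
    try:
        return int(expr.columns.get_loc(sample))
    except KeyError:
        raise ValidationError(f"unknown sample id {sample!r}") from None


def _abs_diffs(x: np.ndarray, j: int) -> np.ndarray:
    """n x (m-1) absolute differences between sample j and the others,
    columns ordered by increasing original sample index (j removed)."""
    d = np.abs(x - x[:, [j]])
    return np.delete(d, j, axis=1)


def _od_column(x: np.ndarray, j: int, k: int) -> np.ndarray:
    d = _abs_diffs(x, j)
    if k >= d.shape[1]:
        return d.sum(axis=1)
    part = np.partition(d, k - 1, axis=1)
    return part[:, :k].sum(axis=1)


def outlying_degree(expr: pd.DataFrame, k: int | None = None, sample=None) -> ScoreMatrix:
    """Outlying degree: sum of the k smallest |x_ij - x_ij'| over j' != j.

    With k = 1 this is the gap to the most similar remaining sample; with
    k = m-1 it is the total absolute deviation from the cohort. Larger k
    tolerates more sample-to-sample variability before a value looks
    outlying. ``sample`` restricts computation to one target column.
    """
    expr = validate_expression(expr)
    x = expr.to_numpy()
    m = x.shape[1]
    k = default_k(m) if k is None else _check_k(k, m)
    cols = range(m) if sample is None else [_sample_index(expr, sample)]
    out = np.column_stack([_od_column(x, j, k) for j in cols])
    columns = expr.columns if sample is None else expr.columns[[cols[0]]]
    return ScoreMatrix(
        values=pd.DataFrame(out, index=expr.index, columns=columns),
        method="od",
        params={"k": k},
    )


def sample_weights(expr: pd.DataFrame) -> pd.DataFrame:
    """m x m matrix of pairwise Euclidean distances between sample columns,
    computed over all genes of the matrix as given. Symmetric, zero diagonal."""
    expr = validate_expression(expr)
    w = squareform(pdist(expr.to_numpy().T, metric="euclidean"))
    return pd.DataFrame(w, index=expr.columns, columns=expr.columns)


def _check_weights(expr: pd.DataFrame, weights: pd.DataFrame | None) -> np.ndarray:
    if weights is None:
        return sample_weights(expr).to_numpy()
    if list(weights.index) != list(expr.columns) or list(weights.columns) != list(expr.columns):
        raise ValidationError("weight matrix ids do not match the expression sample ids")
    w = weights.to_numpy(dtype=float)
    if w.shape[0] != w.shape[1]:
        raise ValidationError("weight matrix must be square")
    if not np.allclose(w, w.T):
        raise ValidationError("weight matrix must be symmetric")
    if (w < 0).any():
        raise ValidationError("weight matrix entries must be >= 0")
    return w


def _woda_column(
    x: np.ndarray, w: np.ndarray, j: int, k: int, flagged: set[int]
) -> np.ndarray:
    d = _abs_diffs(x, j)
    wj = np.delete(w[j], j)  # weights to the other samples, original index order
    # neighbors by the *unweighted* distance order; stable sort keeps
    # sample-index order on ties so results are platform-independent
    order = np.argsort(d, axis=1, kind="stable")[:, :k]
    dk = np.take_along_axis(d, order, axis=1)
    wk = wj[order]
    den = wk.sum(axis=1)
    num = (wk * dk).sum(axis=1)
    zero = den == 0.0
    out = np.empty(d.shape[0])
    with np.errstate(divide="ignore", invalid="ignore"):
        out = num / den
    if zero.any():
        # zero weight-sum over the selected neighbors: fall back to the
        # unweighted mean of the k distances (the equal-weights limit)
        out[zero] = dk[zero].mean(axis=1)
        flagged.update(np.nonzero(zero)[0].tolist())
    return out


def woda(
    expr: pd.DataFrame,
    k: int | None = None,
    weights: pd.DataFrame | None = None,
    sample=None,
) -> ScoreMatrix:
    """Weighted outlying degree, variant (a): weighting *after* neighbor choice.

    The k nearest absolute differences are chosen exactly as in
    :func:`outlying_degree`; the score is then their weighted mean, with
    weights the Euclidean sample dissimilarities w_jj'. With k = 1 or with
    constant weights this reduces to OD (up to the factor 1/k).

    Genes whose k selected neighbors all carry zero weight are scored with
    the unweighted mean of the k distances and listed in ``flagged_genes``.
    """
    expr = validate_expression(expr)
    x = expr.to_numpy()
    m = x.shape[1]
    k = default_k(m) if k is None else _check_k(k, m)
    w = _check_weights(expr, weights)
    cols = list(range(m)) if sample is None else [_sample_index(expr, sample)]
    flagged_rows: set[int] = set()
    out = np.column_stack([_woda_column(x, w, j, k, flagged_rows) for j in cols])
    columns = expr.columns if sample is None else expr.columns[[cols[0]]]
    return ScoreMatrix(
        values=pd.DataFrame(out, index=expr.index, columns=columns),
        method="woda",
        params={"k": k},
        flagged_genes=expr.index[sorted(flagged_rows)].tolist(),
    )


def _wodb_column(x: np.ndarray, w: np.ndarray, j: int, k: int) -> np.ndarray:
    d = _abs_diffs(x, j)
    wj = np.delete(w[j], j)
    wtot = wj.sum()
    if wtot == 0.0:
        raise DegenerateGeneError(
            f"all off-diagonal weights are zero for sample column {j}; "
            "wodb is undefined (every sample pair is identical)"
        )
    wd = d * wj[None, :]
    # ordering by w*d/wtot == ordering by w*d (positive constant per sample);
    # the normalization is applied to the summed values below
    order = np.argsort(wd, axis=1, kind="stable")[:, :k]
    return np.take_along_axis(wd, order, axis=1).sum(axis=1) / wtot


def wodb(
    expr: pd.DataFrame,
    k: int | None = None,
    weights: pd.DataFrame | None = None,
    sample=None,
) -> ScoreMatrix:
    """Weighted outlying degree, variant (b): weighting *before* neighbor choice.

    Each difference d_ij'j is first scaled by w_jj' / sum_{j'' != j} w_jj'';
    the k smallest *weighted* differences are then summed. With constant
    weights this reduces to OD / (m-1), preserving per-gene rankings.
    """
    expr = validate_expression(expr)
    x = expr.to_numpy()
    m = x.shape[1]
    k = default_k(m) if k is None else _check_k(k, m)
    w = _check_weights(expr, weights)
    cols = list(range(m)) if sample is None else [_sample_index(expr, sample)]
    out = np.column_stack([_wodb_column(x, w, j, k) for j in cols])
    columns = expr.columns if sample is None else expr.columns[[cols[0]]]
    return ScoreMatrix(
        values=pd.DataFrame(out, index=expr.index, columns=columns),
        method="wodb",
        params={"k": k},
    )


def delta(expr: pd.DataFrame) -> pd.DataFrame:
    """Per-gene gap between the highest and second-highest sample value.

    Returns a DataFrame indexed by gene with columns ``delta`` (the gap) and
    ``sample`` (the id of the maximal sample). Identical to the outlying
    degree with k = 1 evaluated at the maximal sample, and useful for
    binning genes into effect-size categories before per-sample ranking.
    Ties for the maximum resolve to the lowest sample index (gap 0).
    """
    expr = validate_expression(expr)
    x = expr.to_numpy()
    top2 = -np.partition(-x, 1, axis=1)[:, :2]
    argmax = x.argmax(axis=1)  # first maximal column on ties
    return pd.DataFrame(
        {"delta": top2[:, 0] - top2[:, 1], "sample": expr.columns[argmax]},
        index=expr.index,
    )


def assign_sign(expr: pd.DataFrame, scores: ScoreMatrix) -> ScoreMatrix:
    """Attach a direction channel to magnitude-only (OD-family) scores.

    The sign is sign(x_ij - median(x_i)): +1 for values above the per-gene
    median (up-regulated relative to the cohort), -1 below, 0 at the median.
    Magnitudes are left untouched; zscore/rscore are already signed.
    """
    expr = validate_expression(expr)
    med = np.median(expr.to_numpy(), axis=1, keepdims=True)
    sub = expr[scores.values.columns]
    signs = np.sign(sub.to_numpy() - med)
    return ScoreMatrix(
        values=scores.values,
        method=scores.method,
        params=dict(scores.params),
        signs=pd.DataFrame(signs, index=expr.index, columns=scores.values.columns),
        flagged_genes=list(scores.flagged_genes),
    )
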