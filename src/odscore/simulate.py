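"""Monte-Carlo benchmarking of the outlier statistics.

Synthetic cohorts are drawn i.i.d. per gene and sample from either
Normal(mean 7, sd 1) — the low-variability extreme, resembling quantile-
normalized array data — or a noncentral t (df 15, noncentrality 7), the
high-variability extreme. A single-sample outlier effect (+3, +4 or +5
units) is injected into a set of true-positive genes of one sample, and
optionally a technical factor (a -2 unit shift on a large random gene
subset of one or more samples) emulating a batch/hybridization artifact.

Power is the fraction of iterations in which the designated true gene's
empirical rank p-value falls below alpha; FDR is the mean top-S false
fraction. Each iteration draws from an independent child stream of the
master seed, so results are reproducible bit-for-bit and independent of
any parallel scheduling.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.stats import median_abs_deviation
from statsmodels.stats.proportion import proportion_confint

from .errors import ParameterError, ValidationError
from .scores import MAD_CONSTANT
from .significance import empirical_fdr, empirical_pvalue

__all__ = [
    "TechnicalFactor",
    "SimulationScenario",
    "SimulationResult",
    "simulate_cohort",
    "inject_outlier_effect",
    "inject_technical_factor",
    "run_power",
    "run_fdr",
    "k_sweep",
    "METHODS",
]

METHODS = ("zscore", "rscore", "od", "woda", "wodb")


@dataclass(frozen=True)
class TechnicalFactor:
    """A simulated array-level artifact: ``n_affected_genes`` genes (one
    shared random subset) shifted by ``shift`` units in ``n_affected_samples``
    samples. ``includes_true_outlier`` forces the outlier sample and the
    true genes into the affected sets (the hard case)."""

    n_affected_genes: int = 2500
    n_affected_samples: int = 1
    shift: float = -2.0
    includes_true_outlier: bool = True


@dataclass(frozen=True)
class SimulationScenario:
    """Full parameterization of one benchmark condition.

    Defaults mirror the benchmark design: 10,000 genes x 20 samples,
    S = 100 true-positive genes injected in one sample, k = 9 neighbors,
    alpha = 0.05. ``single_gene_power`` switches power runs to injecting
    only the single designated gene.
    """

    n_genes: int = 10_000
    n_samples: int = 20
    distribution: str = "normal"  # "normal" (mean 7, sd 1) or "t" (df 15, ncp 7)
    effect_size: float = 5.0
    n_true_positives: int = 100
    outlier_sample: int = 0
    technical: TechnicalFactor | None = None
    k: int = 9
    alpha: float = 0.05
    iterations: int = 10_000
    seed: int = 0
    single_gene_power: bool = False

    def __post_init__(self):
        if self.n_genes < 2 or self.n_samples < 2:
            raise ParameterError("need n_genes >= 2 and n_samples >= 2")
        if not 1 <= self.n_true_positives <= self.n_genes:
            raise ParameterError("n_true_positives must be in [1, n_genes]")
        if not 0 <= self.outlier_sample < self.n_samples:
            raise ParameterError("outlier_sample out of range")
        if not 1 <= self.k <= self.n_samples - 1:
            raise ParameterError(f"k={self.k} outside [1, {self.n_samples - 1}]")
        if self.distribution not in ("normal", "t"):
            raise ParameterError(f"unknown distribution {self.distribution!r}")
        if self.iterations < 1:
            raise ParameterError("iterations must be >= 1")
        if not 0 < self.alpha < 1:
            raise ParameterError("alpha must be in (0, 1)")
        if self.technical is not None:
            t = self.technical
            if not 1 <= t.n_affected_genes <= self.n_genes:
                raise ParameterError("technical.n_affected_genes out of range")
            if not 1 <= t.n_affected_samples <= self.n_samples:
                raise ParameterError("technical.n_affected_samples out of range")

    def to_dict(self) -> dict:
        d = asdict(self)
        if self.technical is not None:
            d["technical"] = asdict(self.technical)
        return d


@dataclass
class SimulationResult:
    """Estimates for one scenario: a tidy per-method table with 0.95
    confidence intervals (Wilson for power, normal approximation on the
    mean for FDR)."""

    scenario: SimulationScenario
    metric: str  # "power" or "fdr"
    table: pd.DataFrame  # columns: method, estimate, ci_low, ci_high
    iterations_run: int = 0
    seed: int = 0

    def tidy(self) -> pd.DataFrame:
        """One row per method with the scenario parameters as columns."""
        t = self.table.copy()
        s = self.scenario
        t.insert(0, "metric", self.metric)
        for name, val in (
            ("distribution", s.distribution),
            ("effect_size", s.effect_size),
            ("n_genes", s.n_genes),
            ("n_samples", s.n_samples),
            ("k", s.k),
            ("s_true", s.n_true_positives),
            ("iterations", self.iterations_run),
            ("seed", self.seed),
        ):
            t[name] = val
        return t


# ---------------------------------------------------------------- cohorts


def _draw_values(scenario: SimulationScenario, rng: np.random.Generator) -> np.ndarray:
    shape = (scenario.n_genes, scenario.n_samples)
    if scenario.distribution == "normal":
        return rng.normal(loc=7.0, scale=1.0, size=shape)
    # noncentral t, df=15, ncp=7: N(ncp, 1) / sqrt(chi2_df / df)
    z = rng.normal(loc=7.0, scale=1.0, size=shape)
    chi2 = rng.chisquare(15, size=shape)
    return z / np.sqrt(chi2 / 15.0)


def simulate_cohort(scenario: SimulationScenario, rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Draw one clean cohort (no injected effects) as a genes x samples
    DataFrame with ids ``g0001..`` / ``s01..``. Deterministic given
    ``scenario.seed`` when no generator is supplied."""
    if rng is None:
        rng = np.random.default_rng(scenario.seed)
    x = _draw_values(scenario, rng)
    gw = len(str(scenario.n_genes))
    sw = len(str(scenario.n_samples))
    return pd.DataFrame(
        x,
        index=[f"g{i + 1:0{gw}d}" for i in range(scenario.n_genes)],
        columns=[f"s{j + 1:0{sw}d}" for j in range(scenario.n_samples)],
    )


def inject_outlier_effect(expr: pd.DataFrame, sample, gene_set: Iterable, effect_size: float) -> pd.DataFrame:
    """Return a copy with ``effect_size`` added to the listed genes of one
    sample — the planted single-sample outlier truth."""
    genes = list(gene_set)
    if not genes:
        raise ParameterError("gene_set must be nonempty")
    if sample not in expr.columns:
        raise ValidationError(f"unknown sample id {sample!r}")
    missing = [g for g in genes if g not in expr.index]
    if missing:
        raise ValidationError(f"unknown gene id(s): {missing[:5]}")
    out = expr.copy()
    out.loc[genes, sample] += effect_size
    return out


def inject_technical_factor(
    expr: pd.DataFrame,
    samples: Sequence,
    gene_count: int,
    shift: float,
    rng: np.random.Generator,
    force_genes: Iterable | None = None,
) -> tuple[pd.DataFrame, list]:
    """Shift one shared random subset of ``gene_count`` genes by ``shift``
    units in every listed sample (an array-batch artifact hits the same
    probes). ``force_genes`` are guaranteed members of the subset. Returns
    the modified copy and the affected gene list."""
    if not 1 <= gene_count <= expr.shape[0]:
        raise ParameterError("gene_count out of range")
    unknown = [s for s in samples if s not in expr.columns]
    if unknown:
        raise ValidationError(f"unknown sample id(s): {unknown[:5]}")
    forced = [] if force_genes is None else list(force_genes)
    if len(forced) > gene_count:
        raise ParameterError("more forced genes than gene_count")
    pool = expr.index.difference(pd.Index(forced))
    extra = rng.choice(pool.size, size=gene_count - len(forced), replace=False)
    genes = forced + pool[np.sort(extra)].tolist()
    out = expr.copy()
    out.loc[genes, list(samples)] += shift
    return out, genes


# ------------------------------------------------------- fast score paths
# Hot loop works on raw arrays; only the target sample's column is scored.


def _score_column(x: np.ndarray, j: int, k: int, method: str) -> np.ndarray:
    """Absolute statistic of every gene for sample column j."""
    if method == "zscore":
        sd = x.std(axis=1, ddof=1)
        return np.abs(x[:, j] - x.mean(axis=1)) / sd
    if method == "rscore":
        mad = median_abs_deviation(x, axis=1) * MAD_CONSTANT
        return np.abs(x[:, j] - np.median(x, axis=1)) / mad
    d = np.abs(np.delete(x - x[:, [j]], j, axis=1))
    if method == "od":
        if k >= d.shape[1]:
            return d.sum(axis=1)
        return np.partition(d, k - 1, axis=1)[:, :k].sum(axis=1)
    w = squareform(pdist(x.T))
    wj = np.delete(w[j], j)
    if method == "woda":
        order = np.argsort(d, axis=1, kind="stable")[:, :k]
        wk = wj[order]
        return (wk * np.take_along_axis(d, order, axis=1)).sum(axis=1) / wk.sum(axis=1)
    if method == "wodb":
        wd = d * wj[None, :]
        if k >= wd.shape[1]:
            return wd.sum(axis=1) / wj.sum()
        return np.partition(wd, k - 1, axis=1)[:, :k].sum(axis=1) / wj.sum()
    raise ParameterError(f"unknown method {method!r}")


def _iterate(scenario: SimulationScenario, methods: Sequence[str], metric: str):
    """Yield per-iteration dict {method: statistic-of-interest}.

    For metric 'power' the value is the empirical rank p-value of the
    designated gene; for 'fdr' the top-S false fraction.
    """
    for m in methods:
        if m not in METHODS:
            raise ParameterError(f"unknown method {m!r}; choose from {METHODS}")
    S = scenario.n_true_positives
    j = scenario.outlier_sample
    children = np.random.SeedSequence(scenario.seed).spawn(scenario.iterations)
    for child in children:
        rng = np.random.default_rng(child)
        x = _draw_values(scenario, rng)
        truth = rng.choice(scenario.n_genes, size=S, replace=False)
        if metric == "power" and scenario.single_gene_power:
            truth = truth[:1]
        x[truth, j] += scenario.effect_size
        if scenario.technical is not None:
            t = scenario.technical
            if t.includes_true_outlier:
                aff_samples = np.concatenate(
                    [[j], rng.choice(np.delete(np.arange(scenario.n_samples), j),
                                     size=t.n_affected_samples - 1, replace=False)]
                ).astype(int)
                forced = truth
            else:
                aff_samples = rng.choice(scenario.n_samples, size=t.n_affected_samples, replace=False)
                forced = np.empty(0, dtype=int)
            pool = np.setdiff1d(np.arange(scenario.n_genes), forced)
            extra = rng.choice(pool.size, size=t.n_affected_genes - forced.size, replace=False)
            aff_genes = np.concatenate([forced, pool[extra]])
            x[np.ix_(aff_genes, aff_samples)] += t.shift
        out = {}
        for method in methods:
            T = _score_column(x, j, scenario.k, method)
            if metric == "power":
                out[method] = empirical_pvalue(T, int(truth[0]))
            else:
                out[method] = empirical_fdr(T, truth)
        yield out


def run_power(scenario: SimulationScenario, methods: Sequence[str] = ("od",)) -> SimulationResult:
    """Estimate power: the fraction of iterations whose designated true
    gene reaches an empirical rank p-value below ``scenario.alpha``.
    CI: 0.95 Wilson score interval."""
    hits = {m: 0 for m in methods}
    n_it = scenario.iterations
    for res in _iterate(scenario, methods, "power"):
        for m, p in res.items():
            hits[m] += p < scenario.alpha
    rows = []
    for m in methods:
        lo, hi = proportion_confint(hits[m], n_it, alpha=0.05, method="wilson")
        rows.append({"method": m, "estimate": hits[m] / n_it, "ci_low": lo, "ci_high": hi})
    return SimulationResult(scenario, "power", pd.DataFrame(rows), n_it, scenario.seed)


def run_fdr(scenario: SimulationScenario, methods: Sequence[str] = ("od",)) -> SimulationResult:
    """Estimate the mean top-S empirical FDR over iterations.
    CI: 0.95 normal approximation on the mean."""
    vals = {m: [] for m in methods}
    for res in _iterate(scenario, methods, "fdr"):
        for m, f in res.items():
            vals[m].append(f)
    rows = []
    for m in methods:
        v = np.asarray(vals[m])
        mean = v.mean()
        half = 1.959963984540054 * v.std(ddof=1) / np.sqrt(v.size) if v.size > 1 else np.nan
        rows.append(
            {
                "method": m,
                "estimate": mean,
                "ci_low": max(0.0, mean - half) if np.isfinite(half) else np.nan,
                "ci_high": min(1.0, mean + half) if np.isfinite(half) else np.nan,
            }
        )
    return SimulationResult(scenario, "fdr", pd.DataFrame(rows), scenario.iterations, scenario.seed)


def k_sweep(
    scenario: SimulationScenario,
    k_values: Sequence[int],
    methods: Sequence[str] = ("od",),
    metric: str = "power",
) -> pd.DataFrame:
    """Re-run power or FDR across neighbor counts k.

    Every k re-uses the same master seed, hence identical per-iteration
    cohorts and injections — the curves differ only through k and are
    directly comparable. Returns the concatenated tidy tables."""
    if metric not in ("power", "fdr"):
        raise ParameterError("metric must be 'power' or 'fdr'")
    runner = run_power if metric == "power" else run_fdr
    tables = []
    for k in k_values:
        res = runner(replace(scenario, k=int(k)), methods)
        tables.append(res.tidy())
    return pd.concat(tables, ignore_index=True)
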