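"""Unit and property tests for the five outlier statistics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import odscore as od
from odscore.errors import DegenerateGeneError, ParameterError, ValidationError

from .conftest import random_expr
from .oracles import od_brute, weights_brute, woda_brute, wodb_brute


def frame(rows, samples=None):
    rows = np.atleast_2d(np.asarray(rows, dtype=float))
    return pd.DataFrame(
        rows,
        index=[f"g{i}" for i in range(rows.shape[0])],
        columns=samples or [f"s{j}" for j in range(rows.shape[1])],
    )


class TestZscore:
    def test_hand_values(self):
        z = od.zscore(frame([[1, 2, 3]])).values
        assert z.loc["g0", "s1"] == pytest.approx(0.0)
        assert z.loc["g0", "s2"] == pytest.approx(1.0)  # sd with m-1 denominator

    def test_standardization_identity(self, small_expr):
        z = od.zscore(small_expr).values.to_numpy()
        assert np.allclose(z.mean(axis=1), 0.0, atol=1e-12)
        assert np.allclose(z.std(axis=1, ddof=1), 1.0, atol=1e-12)

    def test_constant_row_policies(self):
        expr = frame([[2, 2, 2], [1, 2, 3]])
        res = od.zscore(expr)  # default: flag
        assert res.flagged_genes == ["g0"]
        assert res.values.loc["g0"].isna().all()
        assert not res.values.loc["g1"].isna().any()
        with pytest.raises(DegenerateGeneError):
            od.zscore(expr, degenerate_policy="error")

    def test_single_sample_rejected(self):
        with pytest.raises(ValidationError):
            od.zscore(frame([[1.0]]))


class TestRscore:
    def test_hand_values(self):
        r = od.rscore(frame([[1, 2, 3, 4, 100]])).values
        assert r.loc["g0", "s4"] == pytest.approx(97 / 1.4826)
        assert od.rscore(frame([[1, 2, 3]])).values.loc["g0", "s1"] == pytest.approx(0.0)

    def test_zero_mad_flagged(self):
        res = od.rscore(frame([[0, 0, 0, 0, 10]]))
        assert res.flagged_genes == ["g0"]
        assert res.values.loc["g0"].isna().all()
        with pytest.raises(DegenerateGeneError):
            od.rscore(frame([[0, 0, 0, 0, 10]]), degenerate_policy="error")

    def test_mad_constant_parameter(self):
        raw = od.rscore(frame([[1, 2, 3, 4, 100]]), mad_constant=1.0).values
        assert raw.loc["g0", "s4"] == pytest.approx(97.0)


class TestOutlyingDegree:
    def test_hand_values(self):
        expr = frame([[7.0, 7.1, 12.0]])
        assert od.outlying_degree(expr, k=1).values.loc["g0", "s2"] == pytest.approx(4.9)
        assert od.outlying_degree(expr, k=2).values.loc["g0", "s2"] == pytest.approx(9.9)

    def test_constant_gene_scores_zero(self):
        vals = od.outlying_degree(frame([[5, 5, 5, 5]]), k=2).values
        assert (vals.to_numpy() == 0).all()

    @pytest.mark.parametrize("k", [1, 2, 3, 5])
    def test_brute_force_oracle(self, rng, k):
        x = random_expr(rng, 10, 6)
        got = od.outlying_degree(x, k=k).values.to_numpy()
        for j in range(6):
            assert np.allclose(got[:, j], od_brute(x.to_numpy(), j, k), atol=1e-12)

    def test_monotone_in_k_and_full_sum(self, small_expr):
        m = small_expr.shape[1]
        prev = None
        for k in range(1, m):
            cur = od.outlying_degree(small_expr, k=k).values.to_numpy()
            if prev is not None:
                assert (cur >= prev - 1e-12).all()
            prev = cur
        x = small_expr.to_numpy()
        full = np.stack(
            [np.abs(np.delete(x - x[:, [j]], j, axis=1)).sum(axis=1) for j in range(m)],
            axis=1,
        )
        assert np.allclose(prev, full, atol=0)

    def test_k_validation(self, small_expr):
        for bad in (0, small_expr.shape[1], -1):
            with pytest.raises(ParameterError):
                od.outlying_degree(small_expr, k=bad)

    def test_single_sample_column(self, small_expr):
        one = od.outlying_degree(small_expr, k=2, sample="s2")
        both = od.outlying_degree(small_expr, k=2)
        assert list(one.values.columns) == ["s2"]
        assert np.allclose(one.values["s2"], both.values["s2"])
        with pytest.raises(ValidationError):
            od.outlying_degree(small_expr, k=2, sample="nope")

    def test_default_k_is_half_cohort(self, cohort_expr):
        assert od.outlying_degree(cohort_expr).params["k"] == 6


class TestSampleWeights:
    def test_against_brute_force(self, small_expr):
        w = od.sample_weights(small_expr)
        assert np.allclose(w.to_numpy(), weights_brute(small_expr.to_numpy()), atol=1e-10)

    def test_structure(self, small_expr):
        w = od.sample_weights(small_expr).to_numpy()
        assert np.allclose(w, w.T)
        assert np.allclose(np.diag(w), 0.0)
        assert (w >= 0).all()

    def test_single_gene_difference(self):
        expr = frame([[1.0, 4.0], [2.0, 2.0]])
        assert od.sample_weights(expr).iloc[0, 1] == pytest.approx(3.0)

    def test_duplicate_columns_zero_distance(self, small_expr):
        dup = small_expr.copy()
        dup["s1"] = dup["s0"]
        assert od.sample_weights(dup).loc["s0", "s1"] == pytest.approx(0.0)


class TestWeightedVariants:
    def test_k1_woda_equals_nearest_distance(self, small_expr):
        w = od.sample_weights(small_expr)
        a = od.woda(small_expr, k=1, weights=w).values.to_numpy()
        base = od.outlying_degree(small_expr, k=1).values.to_numpy()
        assert np.allclose(a, base, atol=1e-12)

    def test_constant_weight_reductions(self, small_expr):
        m = small_expr.shape[1]
        const = pd.DataFrame(
            np.ones((m, m)) - np.eye(m), index=small_expr.columns, columns=small_expr.columns
        )
        for k in (1, 2, 3):
            base = od.outlying_degree(small_expr, k=k).values.to_numpy()
            a = od.woda(small_expr, k=k, weights=const).values.to_numpy()
            b = od.wodb(small_expr, k=k, weights=const).values.to_numpy()
            assert np.allclose(a, base / k, atol=1e-12)
            assert np.allclose(b, base / (m - 1), atol=1e-12)

    @pytest.mark.parametrize("k", [1, 2, 3])
    def test_brute_force_oracles(self, rng, k):
        x = random_expr(rng, 8, 4)
        w = od.sample_weights(x)
        a = od.woda(x, k=k, weights=w).values.to_numpy()
        b = od.wodb(x, k=k, weights=w).values.to_numpy()
        for j in range(4):
            assert np.allclose(a[:, j], woda_brute(x.to_numpy(), w.to_numpy(), j, k), atol=1e-12)
            assert np.allclose(b[:, j], wodb_brute(x.to_numpy(), w.to_numpy(), j, k), atol=1e-12)

    def test_wodb_two_samples(self):
        expr = frame([[1.0, 4.0]])
        w = od.sample_weights(expr)
        assert od.wodb(expr, k=1, weights=w).values.loc["g0", "s0"] == pytest.approx(3.0)

    def test_woda_zero_weight_fallback(self):
        # identical columns -> all weights zero -> unweighted mean + flag
        expr = frame([[1.0, 1.0, 1.0], [2.0, 2.0, 2.0]])
        res = od.woda(expr, k=2)
        assert (res.values.to_numpy() == 0).all()
        assert res.flagged_genes == ["g0", "g1"]
        with pytest.raises(DegenerateGeneError):
            od.wodb(expr, k=2)

    def test_weight_id_mismatch_rejected(self, small_expr):
        w = od.sample_weights(small_expr)
        w.index = [f"x{j}" for j in range(len(w))]
        with pytest.raises(ValidationError):
            od.woda(small_expr, k=1, weights=w)


class TestDelta:
    def test_hand_values(self):
        d = od.delta(frame([[3, 8, 5]]))
        assert d.loc["g0", "delta"] == pytest.approx(3.0)
        assert d.loc["g0", "sample"] == "s1"
        assert od.delta(frame([[4, 4, 4]])).loc["g0", "delta"] == 0.0

    def test_equals_od_k1_at_argmax(self, cohort_expr):
        d = od.delta(cohort_expr)
        od1 = od.outlying_degree(cohort_expr, k=1).values
        for gene in cohort_expr.index:
            assert d.loc[gene, "delta"] == pytest.approx(
                od1.loc[gene, d.loc[gene, "sample"]], abs=1e-12
            )


class TestSignsAndInvariances:
    def test_assign_sign_median_rule(self):
        expr = frame([[1, 5, 9, 9]])
        scores = od.assign_sign(expr, od.outlying_degree(expr, k=1))
        # median 7: below -> -1, above -> +1; magnitudes untouched
        assert scores.signs.loc["g0"].tolist() == [-1.0, -1.0, 1.0, 1.0]
        expr2 = frame([[1, 5, 9]])
        s2 = od.assign_sign(expr2, od.outlying_degree(expr2, k=1))
        assert s2.signs.loc["g0"].tolist() == [-1.0, 0.0, 1.0]

    @pytest.mark.parametrize("method", ["zscore", "rscore", "od", "woda", "wodb"])
    def test_permutation_equivariance(self, rng, method):
        expr = random_expr(rng, 8, 5)
        perm = ["s3", "s0", "s4", "s1", "s2"]
        base = _score(method, expr).values
        permuted = _score(method, expr[perm]).values
        assert np.allclose(base[perm].to_numpy(), permuted.to_numpy(), atol=1e-12)

    @pytest.mark.parametrize("method", ["zscore", "rscore", "od", "woda", "wodb"])
    def test_shift_invariance(self, rng, method):
        expr = random_expr(rng, 8, 5)
        shifted = expr + 11.25
        assert np.allclose(
            _score(method, expr).values.to_numpy(),
            _score(method, shifted).values.to_numpy(),
            atol=1e-9,
        )

    @settings(deadline=None, derandomize=True, max_examples=25)
    @given(
        data=st.lists(
            st.lists(st.floats(-50, 50), min_size=4, max_size=4), min_size=2, max_size=6
        ),
        k=st.integers(1, 3),
    )
    def test_od_nonnegative_and_matches_oracle(self, data, k):
        x = np.asarray(data, dtype=float)
        expr = frame(x)
        got = od.outlying_degree(expr, k=k).values.to_numpy()
        assert (got >= 0).all()
        for j in range(x.shape[1]):
            assert np.allclose(got[:, j], od_brute(x, j, k), atol=1e-9)


def _score(method, expr):
    if method == "zscore":
        return od.zscore(expr)
    if method == "rscore":
        return od.rscore(expr)
    if method == "od":
        return od.outlying_degree(expr, k=2)
    w = od.sample_weights(expr)
    fn = od.woda if method == "woda" else od.wodb
    return fn(expr, k=2, weights=w)
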