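"""Standardization, partition algebra and SS-decomposition correctness."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ckm import (
    DataMatrix,
    ckm_loss,
    partition_from_labels,
    read_matrix,
    ss_decompose,
    standardize,
    write_matrix,
)


class TestStandardize:
    def test_unit_variance_column(self):
        out = standardize(np.array([1.0, 2.0, 3.0]))
        np.testing.assert_allclose(out.values[:, 0], [-1.0, 0.0, 1.0])

    def test_constant_column_rejected(self):
        X = np.column_stack([np.arange(4.0), np.full(4, 5.0)])
        with pytest.raises(ValueError, match="constant column.*x2"):
            standardize(X)

    def test_missing_value_position_reported(self):
        X = np.arange(12.0).reshape(4, 3)
        X[2, 1] = np.nan
        with pytest.raises(ValueError, match="row 2, column 1"):
            standardize(X)

    @pytest.mark.parametrize("mode,check", [
        ("unit-variance", lambda X: X.var(axis=0, ddof=1)),
        ("unit-sum-of-squares", lambda X: (X**2).sum(axis=0)),
    ])
    def test_column_moments(self, rng, mode, check):
        out = standardize(rng.normal(size=(10, 4)) * 7 + 3, mode=mode)
        np.testing.assert_allclose(out.values.mean(axis=0), 0.0, atol=1e-12)
        np.testing.assert_allclose(check(out.values), 1.0, atol=1e-10)
        out.validate()


class TestPartition:
    def test_small_examples(self):
        p = partition_from_labels(["a", "a", "b", "b"])
        assert p.K == 2 and list(p.sizes) == [2, 2]
        H = p.indicator()
        np.testing.assert_allclose(H[H > 0], 1 / np.sqrt(2))

        p1 = partition_from_labels([1, 1, 1])
        np.testing.assert_allclose(p1.indicator()[:, 0], 1 / np.sqrt(3))

    @given(st.lists(st.integers(0, 2), min_size=3, max_size=30).filter(
        lambda ls: len(set(ls)) >= 1))
    @settings(deadline=None, max_examples=50)
    def test_indicator_orthonormal(self, labels):
        p = partition_from_labels(labels)
        H = p.indicator()
        np.testing.assert_allclose(H.T @ H, np.eye(p.K), atol=1e-12)

    def test_trace_identity_matches_within_ss(self, rng):
        # for fixed c, within-SS = ||X||_F^2 - Tr(H'XX'H)
        X = rng.normal(size=(20, 5))
        X -= X.mean(axis=0)
        p = partition_from_labels(rng.integers(0, 3, size=20))
        H = p.indicator()
        dec = ss_decompose(X, p)
        trace = np.trace(H.T @ X @ X.T @ H)
        np.testing.assert_allclose(dec.within, (X**2).sum() - trace, atol=1e-8)


def _loop_ss(X, assign):
    """Independent loop-based recomputation of the SS decomposition."""
    J = X.shape[1]
    tot = np.zeros(J)
    btw = np.zeros(J)
    wth = np.zeros(J)
    for j in range(J):
        col = X[:, j]
        for k in np.unique(assign):
            sub = col[assign == k]
            m = sub.mean()
            btw[j] += len(sub) * m**2
            wth[j] += ((sub - m) ** 2).sum()
        tot[j] = (col**2).sum()
    return tot, btw, wth


class TestSsDecompose:
    def test_perfect_separation_and_none(self):
        p = partition_from_labels([1, 1, 2, 2])
        d1 = ss_decompose(np.array([[-1.0], [-1.0], [1.0], [1.0]]), p)
        assert d1.per_var_total[0] == pytest.approx(4.0)
        assert d1.per_var_between[0] == pytest.approx(4.0)
        assert d1.per_var_within[0] == pytest.approx(0.0)

        d2 = ss_decompose(np.array([[-1.0], [1.0], [-1.0], [1.0]]), p)
        assert d2.per_var_between[0] == pytest.approx(0.0)
        assert d2.per_var_within[0] == pytest.approx(4.0)

    def test_identity_vs_loop_oracle(self, rng):
        X = rng.normal(size=(20, 5))
        X -= X.mean(axis=0)
        assign = rng.integers(1, 4, size=20)
        dec = ss_decompose(X, partition_from_labels(assign))
        tot, btw, wth = _loop_ss(X, assign)
        np.testing.assert_allclose(dec.per_var_total, tot, atol=1e-9)
        np.testing.assert_allclose(dec.per_var_between, btw, atol=1e-9)
        np.testing.assert_allclose(dec.per_var_within, wth, atol=1e-9)
        np.testing.assert_allclose(
            dec.per_var_total, dec.per_var_between + dec.per_var_within, atol=1e-9)


class TestCkmLoss:
    def test_reduces_to_km_within_ss(self, rng):
        X = rng.normal(size=(12, 4))
        X -= X.mean(axis=0)
        p = partition_from_labels(rng.integers(0, 2, size=12))
        assert ckm_loss(X, p, []) == pytest.approx(ss_decompose(X, p).within)

    def test_brute_force_equivalence(self, rng):
        X = rng.normal(size=(8, 4))
        X -= X.mean(axis=0)
        assign = rng.integers(1, 3, size=8)
        p = partition_from_labels(assign)
        g = [0, 2]
        # exhaustive term-by-term evaluation of the objective
        expected = (X[:, g] ** 2).sum()
        for j in (1, 3):
            for k in (1, 2):
                sub = X[assign == k][:, j]
                expected += ((sub - sub.mean()) ** 2).sum()
        assert ckm_loss(X, p, g) == pytest.approx(expected, abs=1e-9)

    def test_invariances(self, rng):
        X = rng.normal(size=(15, 5))
        X -= X.mean(axis=0)
        assign = rng.integers(1, 4, size=15)
        p = partition_from_labels(assign)
        relabeled = partition_from_labels(4 - assign)
        g = [1, 4]
        base = ckm_loss(X, p, g)
        assert ckm_loss(X, relabeled, g) == pytest.approx(base)
        perm = rng.permutation(5)
        g_perm = [int(np.where(perm == j)[0][0]) for j in g]
        assert ckm_loss(X[:, perm], p, g_perm) == pytest.approx(base)

    def test_too_many_irrelevant_rejected(self, rng):
        X = rng.normal(size=(6, 4))
        p = partition_from_labels([1, 1, 1, 2, 2, 2])
        with pytest.raises(ValueError, match="two signaling"):
            ckm_loss(X, p, [0, 1, 2])


class TestMatrixIO:
    @pytest.mark.parametrize("ext,delim", [("csv", ","), ("tsv", "\t")])
    def test_round_trip(self, tmp_path, rng, ext, delim):
        X = standardize(rng.normal(size=(6, 4)))
        path = tmp_path / f"m.{ext}"
        write_matrix(X, path)
        back = read_matrix(path)
        np.testing.assert_allclose(back.values, X.values)
        assert back.var_ids == X.var_ids
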