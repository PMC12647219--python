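"""Imputation and Spearman correlation engine, checked against independent
oracles (closed form on tie-free vectors; scipy's pairwise implementation)."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import spearmanr

import gbacorr as g
from gbacorr.io import ValidationError


def closed_form_no_ties(x, y):
    """1 − 6Σd²/(n(n²−1)); valid only when each vector is tie-free."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    rx = np.argsort(np.argsort(x)) + 1
    ry = np.argsort(np.argsort(y)) + 1
    n = x.size
    return 1.0 - 6.0 * np.sum((rx - ry) ** 2) / (n * (n**2 - 1))


class TestImputeZeros:
    def test_missing_becomes_exact_zero(self):
        frame = pd.DataFrame([[1.0, np.nan], [np.nan, 4.0]],
                             index=["A", "B"], columns=["S1", "S2"])
        out = g.impute_zeros(g.AbundanceMatrix(frame))
        assert out.data.to_numpy().tolist() == [[1.0, 0.0], [0.0, 4.0]]

    def test_identity_without_missing(self, seeded_matrix):
        complete = g.AbundanceMatrix(seeded_matrix.data.fillna(1.0))
        out = g.impute_zeros(complete)
        pd.testing.assert_frame_equal(out.data, complete.data)

    def test_counting_oracle(self):
        rng = np.random.default_rng(0)
        values = rng.uniform(1.0, 10.0, size=(100, 50))
        mask = rng.random(size=values.shape) < 0.2
        values[mask] = np.nan
        m = g.AbundanceMatrix(pd.DataFrame(
            values, index=[f"P{i}" for i in range(100)],
            columns=[f"S{j}" for j in range(50)]))
        n_missing = m.n_missing
        out = g.impute_zeros(m)
        assert out.n_missing == 0
        assert int((out.data.to_numpy() == 0.0).sum()) == n_missing


class TestSpearman:
    def test_worked_value(self):
        rho, undefined = g.spearman((1, 2, 3, 4), (2, 1, 4, 3))
        assert not undefined
        assert rho == pytest.approx(0.6, abs=1e-12)

    def test_identity(self):
        rho, undefined = g.spearman((5, 1, 9), (5, 1, 9))
        assert rho == 1.0 and not undefined

    def test_constant_vector_flagged_undefined(self):
        rho, undefined = g.spearman((1, 2, 3), (0, 0, 0))
        assert rho == 0.0 and undefined

    @pytest.mark.parametrize("x,y", [((1, 2), (1,)), ((1,), (1,))])
    def test_bad_lengths(self, x, y):
        with pytest.raises(ValidationError):
            g.spearman(x, y)

    def test_missing_rejected(self):
        with pytest.raises(ValidationError, match="impute"):
            g.spearman((1.0, np.nan, 3.0), (1.0, 2.0, 3.0))

    def test_matches_closed_form_on_tie_free_vectors(self):
        rng = np.random.default_rng(8)
        for _ in range(25):
            x = rng.permutation(12).astype(float)
            y = rng.normal(size=12)
            rho, _ = g.spearman(x, y)
            assert rho == pytest.approx(closed_form_no_ties(x, y), abs=1e-12)

    def test_matches_scipy_with_ties(self):
        rng = np.random.default_rng(9)
        for _ in range(25):
            x = rng.integers(0, 4, size=15).astype(float)
            y = rng.integers(0, 4, size=15).astype(float)
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                continue
            rho, undefined = g.spearman(x, y)
            assert not undefined
            assert rho == pytest.approx(spearmanr(x, y).statistic, abs=1e-12)


class TestCorrelationMatrix:
    def test_identical_rows_give_offdiag_one(self):
        frame = pd.DataFrame([[1.0, 2.0, 3.0], [10.0, 20.0, 30.0]],
                             index=["A", "B"], columns=list("xyz"))
        c = g.correlation_matrix(g.AbundanceMatrix(frame))
        assert c.value("A", "B") == 1.0

    def test_matches_pairwise_scipy_oracle(self, seeded_matrix):
        c = g.correlation_matrix(seeded_matrix)
        imputed = g.impute_zeros(seeded_matrix).data.to_numpy()
        ids = seeded_matrix.protein_ids
        for i in range(len(ids)):
            for j in range(i + 1, len(ids)):
                expected = spearmanr(imputed[i], imputed[j]).statistic
                assert c.value(ids[i], ids[j]) == pytest.approx(
                    expected, abs=1e-10)

    def test_constant_row_zeroed_and_masked(self):
        frame = pd.DataFrame(
            [[1.0, 2.0, 3.0], [5.0, 5.0, 5.0], [3.0, 1.0, 2.0]],
            index=["A", "CONST", "B"], columns=list("xyz"))
        c = g.correlation_matrix(g.AbundanceMatrix(frame))
        assert c.constant_ids == frozenset({"CONST"})
        assert c.value("A", "CONST") == 0.0
        assert c.value("CONST", "B") == 0.0
        assert c.value("CONST", "CONST") == 1.0
        mask = c.undefined_mask()
        assert bool(mask.at["A", "CONST"]) and bool(mask.at["CONST", "B"])
        assert not bool(mask.at["CONST", "CONST"])
        assert not bool(mask.at["A", "B"])

    def test_all_missing_row_is_constant_after_imputation(self):
        frame = pd.DataFrame(
            [[1.0, 2.0, 3.0], [np.nan, np.nan, np.nan]],
            index=["A", "GONE"], columns=list("xyz"))
        c = g.correlation_matrix(g.AbundanceMatrix(frame))
        assert "GONE" in c.constant_ids
        assert c.value("A", "GONE") == 0.0

    def test_invariants(self, seeded_matrix):
        c = g.correlation_matrix(seeded_matrix)
        rho = c.rho.to_numpy()
        assert np.array_equal(rho, rho.T)  # exact symmetry by mirroring
        assert np.all(np.diag(rho) == 1.0)
        assert rho.min() >= -1.0 and rho.max() <= 1.0

    def test_fewer_than_two_samples_rejected(self):
        frame = pd.DataFrame([[1.0], [2.0]], index=["A", "B"], columns=["S1"])
        with pytest.raises(ValidationError, match="2 samples"):
            g.correlation_matrix(g.AbundanceMatrix(frame))

    def test_permutation_equivariance(self, seeded_matrix):
        c = g.correlation_matrix(seeded_matrix)
        rng = np.random.default_rng(2)
        sample_perm = rng.permutation(seeded_matrix.sample_ids)
        shuffled = g.AbundanceMatrix(seeded_matrix.data[sample_perm])
        c2 = g.correlation_matrix(shuffled)
        pd.testing.assert_frame_equal(c.rho, c2.rho)

        protein_perm = rng.permutation(seeded_matrix.protein_ids)
        reordered = g.AbundanceMatrix(seeded_matrix.data.loc[protein_perm])
        c3 = g.correlation_matrix(reordered)
        pd.testing.assert_frame_equal(
            c3.rho, c.rho.loc[protein_perm, protein_perm])

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_monotone_invariance(self, seed):
        """A strictly increasing transform of one row leaves all its defined
        correlations unchanged (rank correlation sees only order)."""
        rng = np.random.default_rng(seed)
        values = rng.normal(size=(5, 12))
        ids = [f"P{i}" for i in range(5)]
        cols = [f"S{j}" for j in range(12)]
        base = g.AbundanceMatrix(pd.DataFrame(values, index=ids, columns=cols))
        transformed = values.copy()
        transformed[0] = np.exp(0.5 * transformed[0]) + 3.0  # strictly increasing
        other = g.AbundanceMatrix(
            pd.DataFrame(transformed, index=ids, columns=cols))
        c1 = g.correlation_matrix(base)
        c2 = g.correlation_matrix(other)
        np.testing.assert_allclose(
            c1.rho.to_numpy(), c2.rho.to_numpy(), atol=1e-10)

    def test_fast_path_equals_per_pair(self, seeded_matrix):
        c = g.correlation_matrix(seeded_matrix)
        imputed = g.impute_zeros(seeded_matrix).data.to_numpy()
        ids = seeded_matrix.protein_ids
        rng = np.random.default_rng(4)
        for _ in range(50):
            i, j = rng.integers(0, len(ids), size=2)
            rho, undefined = g.spearman(imputed[i], imputed[j])
            if i == j:
                assert c.value(ids[i], ids[j]) == 1.0
            elif not undefined:
                assert c.value(ids[i], ids[j]) == pytest.approx(rho, abs=1e-10)


class TestPersistence:
    def test_round_trip_with_mask(self, tmp_path):
        frame = pd.DataFrame(
            [[1.0, 2.0, 3.0], [5.0, 5.0, 5.0], [3.0, 1.0, 2.0]],
            index=["A", "CONST", "B"], columns=list("xyz"))
        c = g.correlation_matrix(g.AbundanceMatrix(frame))
        path = tmp_path / "corr.tsv"
        g.write_correlation_matrix(c, path, full_precision=True)
        assert (tmp_path / "corr.tsv.mask.tsv").exists()
        back = g.read_correlation_matrix(path)
        pd.testing.assert_frame_equal(back.rho, c.rho)
        assert back.constant_ids == c.constant_ids

    def test_round_trip_without_mask(self, tmp_path, seeded_matrix):
        c = g.correlation_matrix(seeded_matrix)
        path = tmp_path / "corr.tsv"
        g.write_correlation_matrix(c, path, full_precision=True)
        assert not (tmp_path / "corr.tsv.mask.tsv").exists()
        back = g.read_correlation_matrix(path)
        pd.testing.assert_frame_equal(back.rho, c.rho)
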