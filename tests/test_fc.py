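"""Dependence measures: Pearson, grid MI, MIC (vs brute-force oracle), eMIC."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fconn.cohort import RoiTimeSeries
from fconn.errors import DegenerateInputError, ValidationError
from fconn.fc import (
    FCMatrix,
    GridPartition,
    all_fc_matrices,
    emic,
    exhaustive_mic_oracle,
    fc_matrix,
    grid_bound,
    grid_mutual_information,
    mic,
    mi_from_counts,
    pearson,
)


class TestPearson:
    @pytest.mark.parametrize(
        "a, b, expected",
        [
            ([1, 2, 3], [2, 4, 6], 1.0),
            ([1, 2, 3], [3, 2, 1], -1.0),
            ([1, 2, 3, 4], [1, 3, 2, 4], 0.8),
        ],
    )
    def test_closed_forms(self, a, b, expected):
        assert pearson(a, b) == pytest.approx(expected, abs=1e-12)

    def test_zero_variance_is_error_not_zero(self):
        with pytest.raises(DegenerateInputError):
            pearson([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    def test_matches_numpy_convention(self, rng):
        a = rng.standard_normal(50)
        b = rng.standard_normal(50)
        assert pearson(a, b) == pytest.approx(np.corrcoef(a, b)[0, 1], abs=1e-12)


class TestGridMutualInformation:
    def test_independent_uniform_counts_zero(self):
        assert mi_from_counts([[1, 1], [1, 1]]) == pytest.approx(0.0, abs=1e-12)

    def test_diagonal_counts_one_bit(self):
        assert mi_from_counts([[2, 0], [0, 2]]) == pytest.approx(1.0, abs=1e-12)

    def test_hand_computed_table(self):
        # counts [[2,1],[0,1]]: H(row)+H(col)-H(joint)
        h_row = -(0.75 * math.log2(0.75) + 0.25 * math.log2(0.25))
        expected = h_row + 1.0 - 1.5
        assert mi_from_counts([[2, 1], [0, 1]]) == pytest.approx(expected, abs=1e-12)

    def test_from_points_over_explicit_grid(self):
        grid = GridPartition((-0.5, 0.5, 1.5), (-0.5, 0.5, 1.5))
        a = [0, 0, 0, 1]
        b = [0, 0, 1, 1]
        h_row = -(0.75 * math.log2(0.75) + 0.25 * math.log2(0.25))
        assert grid_mutual_information(a, b, grid) == pytest.approx(
            h_row + 1.0 - 1.5, abs=1e-12
        )

    def test_grid_validation(self):
        with pytest.raises(ValidationError):
            GridPartition((0.0, 1.0), (0.0, 1.0))  # single bin
        with pytest.raises(ValidationError):
            GridPartition((0.0, 1.0, 0.5), (0.0, 0.5, 1.0))  # not increasing


class TestMic:
    def test_noiseless_functional_relation(self, rng):
        a = rng.random(100)
        assert mic(a, a).value >= 0.99
        assert mic(a, np.exp(a)).value >= 0.99

    def test_symmetry(self, rng):
        for _ in range(20):
            a = rng.standard_normal(60)
            b = rng.standard_normal(60)
            assert mic(a, b).value == pytest.approx(mic(b, a).value, abs=1e-12)

    def test_bounds(self, rng):
        for n in (10, 50, 200):
            a = rng.standard_normal(n)
            b = rng.standard_normal(n)
            assert 0.0 <= mic(a, b).value <= 1.0

    def test_monotone_transform_invariance(self, rng):
        a = rng.standard_normal(200)
        b = a + 0.5 * rng.standard_normal(200)
        base = mic(a, b).value
        # rank-based gridding makes strictly monotone maps exact no-ops
        assert mic(np.exp(a), b).value == pytest.approx(base, abs=1e-12)
        assert mic(a, b**3).value == pytest.approx(base, abs=1e-12)
        assert abs(mic(2 * a + 7, -b).value - base) < 0.05

    def test_constant_series_rejected(self):
        with pytest.raises(DegenerateInputError):
            mic(np.ones(20), np.arange(20.0))

    def test_permutation_null_for_independent_series(self):
        rng = np.random.default_rng(7)
        a = rng.random(200)
        b = rng.random(200)
        observed = mic(a, b).value
        null = []
        for _ in range(200):
            null.append(mic(a, rng.permutation(b)).value)
        assert observed < np.quantile(null, 0.95)

    def test_grid_bound_floor(self):
        assert grid_bound(8) == 5  # 2x2 grid stays admissible at tiny n
        assert grid_bound(100) == 16

    def test_best_grid_reported_within_bound(self, rng):
        a = rng.standard_normal(100)
        res = mic(a, a + rng.standard_normal(100))
        assert res.best_grid.nA * res.best_grid.nB < grid_bound(100)
        assert res.best_grid.m_value == res.value


class TestMicOracle:
    def test_heuristic_never_exceeds_oracle(self, rng):
        for trial in range(20):
            n = int(rng.integers(4, 13))
            a = rng.random(n)
            b = rng.random(n)
            assert mic(a, b).value <= exhaustive_mic_oracle(a, b) + 1e-12

    def test_exhaustive_mode_matches_oracle(self, rng):
        for trial in range(10):
            n = int(rng.integers(4, 13))
            a = rng.random(n)
            b = rng.random(n)
            assert mic(a, b, method="exhaustive").value == pytest.approx(
                exhaustive_mic_oracle(a, b), abs=1e-9
            )

    def test_monotone_small_n(self):
        a = np.arange(8.0)
        b = a**3
        o = exhaustive_mic_oracle(a, b)
        h = mic(a, b).value
        assert h <= o + 1e-12
        assert o == pytest.approx(1.0, abs=1e-12)

    def test_oracle_refuses_large_n(self, rng):
        with pytest.raises(ValidationError, match="blow-up"):
            exhaustive_mic_oracle(rng.random(50), rng.random(50))


class TestEmic:
    def test_identity_on_random_pairs(self, rng):
        for _ in range(100):
            a = rng.standard_normal(30)
            b = rng.standard_normal(30)
            assert emic(a, b) == pytest.approx(
                mic(a, b).value - pearson(a, b) ** 2, abs=0.0
            )

    def test_linear_relation_near_zero(self, rng):
        a = rng.random(100)
        assert abs(emic(a, a)) < 0.02

    def test_quadratic_relation_passes_through(self, rng):
        a = rng.standard_normal(500)
        b = a**2
        rho = pearson(a, b)
        assert rho**2 < 0.05
        assert emic(a, b) == pytest.approx(mic(a, b).value, abs=0.05)

    def test_independent_series_near_zero_sign_free(self, rng):
        vals = [emic(rng.standard_normal(200), rng.standard_normal(200))
                for _ in range(5)]
        assert all(abs(v) < 0.35 for v in vals)


class TestFCMatrix:
    def _subject(self, data):
        return RoiTimeSeries(subject_id="s0", data=data,
                             roi_labels=[f"R{i}" for i in range(data.shape[1])],
                             tr_seconds=3.0)

    def test_duplicate_column_gives_unit_pcc(self, rng):
        x = rng.standard_normal((50, 3))
        x[:, 2] = x[:, 1]
        fc = fc_matrix(self._subject(x), "PCC")
        assert fc.values[1, 2] == pytest.approx(1.0, abs=1e-12)

    def test_pcc_matrix_equals_corrcoef(self, rng):
        x = rng.standard_normal((80, 6))
        fc = fc_matrix(self._subject(x), "PCC")
        np.testing.assert_allclose(fc.values, np.corrcoef(x.T), atol=1e-12)

    def test_symmetry_and_diagonal_conventions(self, rng):
        x = rng.standard_normal((60, 4))
        subj = self._subject(x)
        for measure, diag in (("PCC", 1.0), ("MIC", 1.0), ("eMIC", 0.0)):
            fc = fc_matrix(subj, measure)
            np.testing.assert_array_equal(fc.values, fc.values.T)
            np.testing.assert_allclose(np.diag(fc.values), diag, atol=1e-12)

    def test_mic_matrix_consistent_with_scalar_calls(self, rng):
        x = rng.standard_normal((40, 5))
        subj = self._subject(x)
        fc = fc_matrix(subj, "MIC")
        for i in range(5):
            for j in range(i + 1, 5):
                assert fc.values[i, j] == pytest.approx(
                    mic(x[:, i], x[:, j]).value, abs=1e-12
                )

    def test_all_measures_shared_computation_consistent(self, rng):
        x = rng.standard_normal((40, 4))
        subj = self._subject(x)
        mats = all_fc_matrices(subj)
        np.testing.assert_allclose(
            mats["eMIC"].values + mats["PCC"].values ** 2,
            np.where(np.eye(4, dtype=bool), mats["eMIC"].values + 1.0,
                     mats["MIC"].values),
            atol=1e-12,
        )

    def test_constant_column_names_roi(self, rng):
        x = rng.standard_normal((30, 3))
        x[:, 1] = 2.5
        with pytest.raises((DegenerateInputError, ValidationError), match="R1"):
            fc_matrix(self._subject(x), "PCC")

    def test_asymmetric_matrix_rejected(self):
        with pytest.raises(ValidationError, match="symmetric"):
            FCMatrix(np.array([[1.0, 0.5], [0.2, 1.0]]), "PCC", ["a", "b"], "s")


@settings(max_examples=25, deadline=None, derandomize=True)
@given(st.integers(min_value=0, max_value=10_000))
def test_mic_bounds_property(seed):
    """MIC stays in [0, 1] for arbitrary continuous pairs."""
    r = np.random.default_rng(seed)
    n = int(r.integers(4, 80))
    v = mic(r.standard_normal(n), r.standard_normal(n)).value
    assert 0.0 <= v <= 1.0
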