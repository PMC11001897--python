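"""Moment computations against brute-force and exact-rational oracles."""

import math
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from rna6ma import (
    MOMENT_ORDER,
    HahnParams,
    central_moments,
    centroid,
    hahn_basis,
    hahn_moments,
    hahn_polynomial,
    moment_set,
    raw_moments,
)
from rna6ma.moments import DegenerateMatrixError, hahn_weight, pad_square


def brute_raw(m, j, k):
    """Double loop over 1-based coordinates."""
    total = 0.0
    for c in range(m.shape[0]):
        for d in range(m.shape[1]):
            total += (c + 1) ** j * (d + 1) ** k * m[c, d]
    return total


def brute_central(m, i, j):
    e00 = brute_raw(m, 0, 0)
    xbar = brute_raw(m, 1, 0) / e00
    ybar = brute_raw(m, 0, 1) / e00
    total = 0.0
    for b in range(m.shape[0]):
        for q in range(m.shape[1]):
            total += (b + 1 - xbar) ** i * (q + 1 - ybar) ** j * m[b, q]
    return total


small_matrices = arrays(
    float,
    st.tuples(st.integers(1, 8), st.integers(1, 8)),
    elements=st.floats(-5, 5, allow_nan=False, width=32),
).filter(lambda m: abs(m.sum()) > 1e-6)


class TestRawMoments:
    def test_worked_example(self):
        m = np.array([[1.0, 2.0], [3.0, 4.0]])
        vals = dict(zip(MOMENT_ORDER, raw_moments(m)))
        assert vals[(0, 0)] == 10
        assert vals[(1, 0)] == 17
        assert vals[(1, 1)] == 27

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(small_matrices)
    def test_matches_brute_force(self, m):
        vals = raw_moments(m)
        for idx, (j, k) in enumerate(MOMENT_ORDER):
            assert vals[idx] == pytest.approx(brute_raw(m, j, k), rel=1e-9,
                                              abs=1e-7)

    def test_nonfinite_entries_rejected(self):
        with pytest.raises(ValueError, match="finite"):
            raw_moments(np.array([[1.0, np.nan]]))


class TestCentroid:
    def test_worked_example(self):
        assert centroid(np.array([[1.0, 2.0], [3.0, 4.0]])) == (
            pytest.approx(1.7), pytest.approx(1.6))

    def test_uniform_matrix_center(self):
        for n in (1, 3, 6):
            assert centroid(np.ones((n, n))) == (
                pytest.approx((n + 1) / 2), pytest.approx((n + 1) / 2))

    def test_point_mass(self):
        m = np.zeros((5, 4))
        m[2, 3] = 7.0
        assert centroid(m) == (3.0, 4.0)  # 1-based

    def test_zero_mass_is_degenerate(self):
        with pytest.raises(DegenerateMatrixError, match="degenerate"):
            centroid(np.zeros((3, 3)))


class TestCentralMoments:
    def test_worked_example(self):
        m = np.array([[1.0, 2.0], [3.0, 4.0]])
        vals = dict(zip(MOMENT_ORDER, central_moments(m)))
        assert vals[(0, 0)] == pytest.approx(10)
        assert vals[(2, 0)] == pytest.approx(2.1)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(small_matrices)
    def test_matches_brute_force_and_first_orders_vanish(self, m):
        vals = central_moments(m)
        tol = 1e-9 * max(1.0, abs(m.sum()))
        by_idx = dict(zip(MOMENT_ORDER, vals))
        assert abs(by_idx[(1, 0)]) < tol
        assert abs(by_idx[(0, 1)]) < tol
        for idx, (i, j) in enumerate(MOMENT_ORDER):
            assert vals[idx] == pytest.approx(brute_central(m, i, j),
                                              rel=1e-7, abs=1e-5)


# ---------------------------------------------------------------------------
# classical Hahn oracle: exact rational 3F2 with the binomial-product weight


def _binom(a: Fraction, k: int) -> Fraction:
    num = Fraction(1)
    for i in range(k):
        num *= a - i
    return num / math.factorial(k)


def classical_hahn(n, x, alpha, beta, M):
    """Q_n(x; alpha, beta, M) = 3F2(-n, n+a+b+1, -x; a+1, -M; 1), exact."""
    total = Fraction(0)
    for k in range(n + 1):
        num = Fraction(1)
        for i in range(k):
            num *= Fraction(-n + i) * Fraction(n + alpha + beta + 1 + i) \
                * Fraction(-x + i)
        den = Fraction(1)
        for i in range(k):
            den *= Fraction(alpha + 1 + i) * Fraction(-M + i)
        total += num / den / math.factorial(k)
    return total


def classical_weight(x, alpha, beta, M):
    return _binom(Fraction(alpha + x), x) * _binom(Fraction(beta + M - x),
                                                   M - x)


class TestHahnPolynomial:
    def test_degree_zero_is_one(self):
        for r in range(6):
            for params in (HahnParams(), HahnParams(0.5, 1.5)):
                assert hahn_polynomial(0, r, 6, params) == 1.0

    def test_first_order_value(self):
        assert hahn_polynomial(1, 0, 4) == pytest.approx(9.0)

    def test_out_of_support_rejected(self):
        with pytest.raises(ValueError):
            hahn_polynomial(4, 0, 4)
        with pytest.raises(ValueError):
            hahn_polynomial(0, 4, 4)

    def test_spans_polynomial_degrees(self):
        # family {h_0..h_n} spans {x^0..x^n}: Vandermonde-like full rank
        N = 6
        V = np.array([[hahn_polynomial(n, r, N) for r in range(N)]
                      for n in range(N)])
        assert np.linalg.matrix_rank(V) == N


class TestHahnBasis:
    @pytest.mark.parametrize("N", [4, 6, 8])
    def test_weighted_orthonormality(self, N):
        """sum_r rho(r) h_m(r) h_n(r) = delta_mn for the norm-scaled basis."""
        params = HahnParams()
        Q = hahn_basis(N, params)
        rho = hahn_weight(N, params)
        scaled = Q / np.sqrt(rho)[None, :]  # the norm-scaled polynomials
        gram = (scaled * rho[None, :]) @ scaled.T
        assert np.allclose(gram, np.eye(N), atol=1e-10)

    @pytest.mark.parametrize("N,u,v", [(5, 0.0, 0.0), (6, 1.0, 2.0),
                                       (8, 0.5, 0.5)])
    def test_matches_exact_classical_hahn_oracle(self, N, u, v):
        """Each basis row is proportional to the exact classical polynomial.

        Oracle: rational-arithmetic Q_n(x; v, u, N-1) with the exact
        binomial-product weight, normalized; agreement up to sign.
        """
        Q = hahn_basis(N, HahnParams(u, v))
        M = N - 1
        for n in range(N):
            vals = np.array(
                [float(classical_hahn(n, x, u, v, M)) for x in range(N)]
            )
            w = np.array(
                [float(classical_weight(x, u, v, M)) for x in range(N)]
            )
            ref = vals * np.sqrt(w)
            ref = ref / np.linalg.norm(ref)
            assert (np.allclose(Q[n], ref, atol=1e-8)
                    or np.allclose(Q[n], -ref, atol=1e-8))


class TestHahnMoments:
    def test_zero_matrix_gives_zero_moments(self):
        assert np.all(hahn_moments(np.zeros((5, 5))) == 0)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(
        arrays(float, (4, 4), elements=st.floats(-3, 3, width=32)),
        arrays(float, (4, 4), elements=st.floats(-3, 3, width=32)),
    )
    def test_linearity(self, a, b):
        assert np.allclose(
            hahn_moments(a + b), hahn_moments(a) + hahn_moments(b),
            atol=1e-9,
        )

    def test_full_order_transform_reconstructs(self):
        rng = np.random.default_rng(17)
        m = rng.integers(0, 9, size=(4, 4)).astype(float)
        Q = hahn_basis(4)
        moments = Q @ m @ Q.T
        back = Q.T @ moments @ Q
        assert np.abs(back - m).max() < 1e-6

    def test_rectangular_input_padded(self):
        m = np.array([[1.0, 2.0, 3.0]])
        assert np.allclose(hahn_moments(m), hahn_moments(pad_square(m)))


@settings(deadline=None, max_examples=40, derandomize=True)
@given(small_matrices)
def test_moment_family_invariants(m):
    ms = moment_set(m)
    # conservation: raw(0,0) == central(0,0) == matrix sum
    assert ms.raw[0] == pytest.approx(m.sum(), rel=1e-9, abs=1e-7)
    assert ms.central[0] == pytest.approx(m.sum(), rel=1e-9, abs=1e-6)
    assert ms.concat().shape == (30,)
    assert np.all(np.isfinite(ms.concat()))


@settings(deadline=None, max_examples=20, derandomize=True)
@given(
    arrays(float, (5, 5), elements=st.floats(-3, 3, width=32)),
    arrays(float, (5, 5), elements=st.floats(-3, 3, width=32)),
)
def test_raw_and_hahn_are_linear(a, b):
    assert np.allclose(raw_moments(a + b), raw_moments(a) + raw_moments(b),
                       atol=1e-8)
    assert np.allclose(hahn_moments(a + b),
                       hahn_moments(a) + hahn_moments(b), atol=1e-8)
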