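"""Raw, central, and Hahn moments of 2D numeric matrices.

Every incidence matrix and reshaped sequence matrix in the encoder is
reduced to thirty scalars: ten raw moments, ten central moments, and ten
discrete Hahn moments, all orders (j, k) with j + k <= 3.

Conventions
-----------
Raw and central moments use 1-based row/column coordinates, so the
zeroth moment is the matrix sum and the centroid of a uniform N x N
matrix is ((N+1)/2, (N+1)/2). Hahn moments live on the 0-based support
{0, ..., N-1} of the discrete polynomials.

The Hahn polynomial evaluator follows the three-parameter 3F2 form
common in the orthogonal-moments literature, with Pochhammer symbols
read as rising factorials and shape parameters (u, v) defaulting to 0
(uniform weight). As printed, that family is *not* numerically
orthogonal; the moment transform therefore uses the orthonormal basis
obtained by weighted Gram-Schmidt of the family in degree order, which
coincides (up to sign) with the classical discrete orthonormal Hahn
basis and makes the full-order transform exactly invertible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache

import numpy as np

#: fixed output order for every 10-value moment family
MOMENT_ORDER: tuple[tuple[int, int], ...] = (
    (0, 0), (0, 1), (1, 0), (1, 1), (0, 2),
    (2, 0), (1, 2), (2, 1), (0, 3), (3, 0),
)

MAX_ORDER = 3


class DegenerateMatrixError(ValueError):
    """The matrix has zero total mass, so the centroid is undefined."""


@dataclass(frozen=True)
class HahnParams:
    """Shape parameters of the discrete Hahn polynomials.

    ``u`` and ``v`` deform the weight toward either end of the support;
    ``u = v = 0`` gives the uniform weight (discrete Chebyshev limit).
    """

    u: float = 0.0
    v: float = 0.0

    def __post_init__(self) -> None:
        if self.u <= -1 or self.v <= -1:
            raise ValueError("Hahn parameters must satisfy u, v > -1")


@dataclass(frozen=True)
class MomentSet:
    """The 30 moment coefficients of one matrix, in :data:`MOMENT_ORDER`."""

    raw: np.ndarray
    central: np.ndarray
    hahn: np.ndarray

    def concat(self) -> np.ndarray:
        return np.concatenate([self.raw, self.central, self.hahn])


def _validate(matrix: np.ndarray) -> np.ndarray:
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2 or m.size == 0:
        raise ValueError("matrix must be 2D and non-empty")
    if not np.all(np.isfinite(m)):
        raise ValueError("matrix entries must be finite")
    return m


def raw_moments(matrix: np.ndarray) -> np.ndarray:
    """E_jk = sum_c sum_d c^j d^k beta_cd with 1-based (c, d)."""
    m = _validate(matrix)
    rows = np.arange(1, m.shape[0] + 1, dtype=float)
    cols = np.arange(1, m.shape[1] + 1, dtype=float)
    rp = rows[:, None] ** np.arange(MAX_ORDER + 1)[None, :]  # (R, 4)
    cp = cols[:, None] ** np.arange(MAX_ORDER + 1)[None, :]  # (C, 4)
    table = rp.T @ m @ cp  # table[j, k] = E_jk
    return np.array([table[j, k] for j, k in MOMENT_ORDER])


def centroid(matrix: np.ndarray) -> tuple[float, float]:
    """Mass centroid (x̄, ȳ) = (E10/E00, E01/E00) in 1-based coordinates."""
    m = _validate(matrix)
    total = m.sum()
    if total == 0.0:
        raise DegenerateMatrixError("degenerate matrix: zero total mass")
    rows = np.arange(1, m.shape[0] + 1, dtype=float)
    cols = np.arange(1, m.shape[1] + 1, dtype=float)
    xbar = float(rows @ m.sum(axis=1)) / total
    ybar = float(cols @ m.sum(axis=0)) / total
    return xbar, ybar


def central_moments(matrix: np.ndarray) -> np.ndarray:
    """n_ij about the centroid; first-order values vanish by construction."""
    m = _validate(matrix)
    xbar, ybar = centroid(m)
    dr = np.arange(1, m.shape[0] + 1, dtype=float) - xbar
    dc = np.arange(1, m.shape[1] + 1, dtype=float) - ybar
    rp = dr[:, None] ** np.arange(MAX_ORDER + 1)[None, :]
    cp = dc[:, None] ** np.arange(MAX_ORDER + 1)[None, :]
    table = rp.T @ m @ cp
    return np.array([table[i, j] for i, j in MOMENT_ORDER])


def _rising(x: float, n: int) -> float:
    out = 1.0
    for i in range(n):
        out *= x + i
    return out


def hahn_polynomial(
    n: int, r: int, N: int, params: HahnParams = HahnParams()
) -> float:
    """Evaluate the (unnormalized) Hahn polynomial h_n^{u,v}(r, N).

    Direct term-by-term evaluation of the 3F2 sum with rising-factorial
    Pochhammer symbols; adequate up to the cubic orders used here.
    """
    if not 0 <= n <= N - 1:
        raise ValueError(f"order n={n} outside support 0..{N - 1}")
    if not 0 <= r <= N - 1:
        raise ValueError(f"point r={r} outside support 0..{N - 1}")
    u, v = params.u, params.v
    pref = _rising(N + v - 1, n) * _rising(N - 1, n)
    total = 0.0
    for k in range(n + 1):
        num = _rising(-n, k) * _rising(-r, k) * _rising(2 * N + u + v - n - 1, k)
        den = _rising(N + v - 1, k) * _rising(N - 1, k) * math.factorial(k)
        total += (-1) ** k * num / den
    return pref * total


def hahn_weight(N: int, params: HahnParams = HahnParams()) -> np.ndarray:
    """Hahn orthogonality weight rho(x) on {0..N-1}; all ones at u=v=0."""
    u, v = params.u, params.v
    x = np.arange(N)
    return np.exp(
        [
            math.lgamma(u + xi + 1)
            + math.lgamma(v + N - xi)
            - math.lgamma(xi + 1)
            - math.lgamma(N - xi)
            for xi in x
        ]
    )


@lru_cache(maxsize=None)
def _hahn_basis_cached(N: int, u: float, v: float, order: int) -> np.ndarray:
    params = HahnParams(u, v)
    rho = hahn_weight(N, params)
    V = np.array(
        [
            [hahn_polynomial(n, r, N, params) for r in range(N)]
            for n in range(order + 1)
        ]
    )
    # weighted Gram-Schmidt in degree order: rows of A get orthonormalized,
    # giving the classical orthonormal Hahn functions scaled by sqrt(rho)
    A = V * np.sqrt(rho)[None, :]
    A = A / np.linalg.norm(A, axis=1, keepdims=True)  # conditioning
    Q = np.zeros_like(A)
    for i in range(A.shape[0]):
        q = A[i].copy()
        for j in range(i):
            q -= (Q[j] @ q) * Q[j]
        norm = np.linalg.norm(q)
        if norm == 0.0:
            raise ValueError("degenerate Hahn basis (linearly dependent)")
        q /= norm
        # sign convention: positive weighted mean for degree 0, positive
        # leading difference otherwise
        if (q[-1] - q[0] < 0 if i > 0 else q.sum() < 0):
            q = -q
        Q[i] = q
    Q.setflags(write=False)
    return Q


def hahn_basis(
    N: int, params: HahnParams = HahnParams(), order: int | None = None
) -> np.ndarray:
    """Orthonormal Hahn transform rows Q[n, x], n = 0..order, x = 0..N-1.

    Rows satisfy Q Q^T = I; equivalently the norm-scaled polynomials
    Q[n] / sqrt(rho) are orthonormal under the Hahn weight rho.
    """
    if order is None:
        order = N - 1
    if not 0 <= order <= N - 1:
        raise ValueError(f"order must lie in 0..{N - 1}")
    return _hahn_basis_cached(N, float(params.u), float(params.v), order)


def pad_square(matrix: np.ndarray) -> np.ndarray:
    """Zero-pad a rectangular matrix at the bottom/right to a square."""
    m = _validate(matrix)
    n = max(m.shape)
    if m.shape == (n, n):
        return m
    out = np.zeros((n, n))
    out[: m.shape[0], : m.shape[1]] = m
    return out


def hahn_moments(
    matrix: np.ndarray, params: HahnParams = HahnParams()
) -> np.ndarray:
    """H_ij = sum_q sum_p beta_qp h_i(q) h_j(p) over :data:`MOMENT_ORDER`."""
    m = pad_square(matrix)
    N = m.shape[0]
    order = min(MAX_ORDER, N - 1)
    Q = hahn_basis(N, params, order=order)
    table = Q @ m @ Q.T
    out = np.zeros(len(MOMENT_ORDER))
    for idx, (i, j) in enumerate(MOMENT_ORDER):
        if i <= order and j <= order:
            out[idx] = table[i, j]
    return out


def moment_set(
    matrix: np.ndarray, params: HahnParams = HahnParams()
) -> MomentSet:
    """All three 10-value moment families of one matrix."""
    return MomentSet(
        raw=raw_moments(matrix),
        central=central_moments(matrix),
        hahn=hahn_moments(matrix, params),
    )
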