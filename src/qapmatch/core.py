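"""Pure numerical kernels for quadratic assignment / graph matching.

The Koopmans-Beckmann quadratic assignment problem (QAP) asks for the
permutation ``pi`` minimizing ``sum_{u,v} a_uv * b_{pi(u)pi(v)}``, i.e. in
matrix form ``trace(A P B^T P^T)`` over permutation matrices ``P``.  Graph
matching -- minimizing the number of edge disagreements
``||A P - P B||_F^2`` -- is the same problem with the sign of the objective
flipped, because

    ||A P - P B||_F^2 = trace(A^T A) + trace(B B^T) - 2 trace(A P B^T P^T).

Everything in this module is stateless: objective values, gradients, and the
exact line search used by the Frank-Wolfe solver.  The permutation-matrix
convention is fixed once and used everywhere: ``P[u, pi(u)] = 1``, so that
``trace(A P B^T P^T) = sum_{u,v} A[u, v] * B[pi(u), pi(v)]``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Union

import numpy as np

__all__ = [
    "Direction",
    "Permutation",
    "QAPProblem",
    "as_square",
    "check_doubly_stochastic",
    "kb_objective",
    "gm_distance",
    "faq_gradient",
    "exact_line_search",
    "convex_objective_gradient",
]

#: entries of a doubly stochastic matrix may dip this far below zero (round-off)
NEG_TOL = 1e-12
#: row/column sums of a doubly stochastic matrix must be within this of 1
SUM_TOL = 1e-8


class Direction(str, Enum):
    """Sense of the trace objective.

    ``MINIMIZE`` is the Koopmans-Beckmann cost; ``MAXIMIZE`` is graph-matching
    overlap, handled internally as minimizing the negated objective.
    """

    MINIMIZE = "minimize"
    MAXIMIZE = "maximize"

    @property
    def sign(self) -> float:
        """+1 for minimize, -1 for maximize (internal minimization sense)."""
        return 1.0 if self is Direction.MINIMIZE else -1.0


def as_square(M, name: str = "matrix") -> np.ndarray:
    """Validate and return ``M`` as a finite square 2-D float array."""
    M = np.asarray(M, dtype=float)
    if M.ndim != 2 or M.shape[0] != M.shape[1]:
        raise ValueError(f"{name} must be square 2-D, got shape {M.shape}")
    if not np.all(np.isfinite(M)):
        raise ValueError(f"{name} contains non-finite entries")
    return M


def _common_n(*mats: np.ndarray) -> int:
    n = mats[0].shape[0]
    for M in mats[1:]:
        if M.shape[0] != n:
            raise ValueError(
                f"dimension mismatch: {n} vs {M.shape[0]} (all matrices must share n)"
            )
    return n


def check_doubly_stochastic(D, *, name: str = "D") -> np.ndarray:
    """Validate membership in the Birkhoff polytope (up to round-off)."""
    D = as_square(D, name)
    if D.min() < -NEG_TOL:
        raise ValueError(f"{name} has entry {D.min():.3e} below -{NEG_TOL}")
    rows = D.sum(axis=1)
    cols = D.sum(axis=0)
    err = max(np.abs(rows - 1.0).max(), np.abs(cols - 1.0).max())
    if err > SUM_TOL:
        raise ValueError(f"{name} row/column sums deviate from 1 by {err:.3e}")
    return D


@dataclass(frozen=True)
class Permutation:
    """A bijection ``pi`` of ``{0, ..., n-1}`` with its 0/1 matrix view.

    The matrix view ``P`` satisfies ``P[u, pi[u]] = 1`` and 0 elsewhere.
    """

    pi: np.ndarray

    def __post_init__(self):
        pi = np.asarray(self.pi, dtype=np.intp)
        if pi.ndim != 1:
            raise ValueError("permutation must be a 1-D integer array")
        n = pi.shape[0]
        if not np.array_equal(np.sort(pi), np.arange(n)):
            raise ValueError("permutation is not a bijection of 0..n-1")
        object.__setattr__(self, "pi", pi)

    @property
    def n(self) -> int:
        return self.pi.shape[0]

    def as_matrix(self) -> np.ndarray:
        P = np.zeros((self.n, self.n))
        P[np.arange(self.n), self.pi] = 1.0
        return P

    def inverse(self) -> "Permutation":
        return Permutation(np.argsort(self.pi))

    @classmethod
    def from_matrix(cls, P) -> "Permutation":
        P = as_square(P, "P")
        pi = np.argmax(P, axis=1)
        Q = cls(pi)
        if not np.allclose(P, Q.as_matrix()):
            raise ValueError("matrix is not a permutation matrix")
        return Q

    @classmethod
    def identity(cls, n: int) -> "Permutation":
        return cls(np.arange(n))

    def __eq__(self, other) -> bool:
        return isinstance(other, Permutation) and np.array_equal(self.pi, other.pi)

    def __hash__(self):
        return hash(self.pi.tobytes())


PermLike = Union[Permutation, np.ndarray]


def _as_matrix_operand(P, n: int) -> np.ndarray:
    """Accept a Permutation, a length-n permutation vector, or an n-by-n matrix."""
    if isinstance(P, Permutation):
        return P.as_matrix()
    P = np.asarray(P, dtype=float)
    if P.ndim == 1:
        return Permutation(P.astype(np.intp)).as_matrix()
    return as_square(P, "P")


@dataclass(frozen=True)
class QAPProblem:
    """A matched pair of square matrices and an objective sense.

    ``direction='minimize'`` is the Koopmans-Beckmann cost; ``'maximize'``
    is graph-matching overlap (minimize the negation).
    """

    A: np.ndarray
    B: np.ndarray
    direction: Direction = Direction.MINIMIZE

    def __post_init__(self):
        A = as_square(self.A, "A")
        B = as_square(self.B, "B")
        _common_n(A, B)
        object.__setattr__(self, "A", A)
        object.__setattr__(self, "B", B)
        object.__setattr__(self, "direction", Direction(self.direction))

    @property
    def n(self) -> int:
        return self.A.shape[0]

    @property
    def maximize(self) -> bool:
        return self.direction is Direction.MAXIMIZE


def kb_objective(A, B, P) -> float:
    """Koopmans-Beckmann trace objective ``trace(A P B^T P^T)``.

    With the convention ``P[u, pi(u)] = 1`` this equals
    ``sum_{u,v} A[u, v] * B[pi(u), pi(v)]``.  ``P`` may be a
    :class:`Permutation`, a permutation vector, or any square matrix
    (typically doubly stochastic).
    """
    A = as_square(A, "A")
    B = as_square(B, "B")
    n = _common_n(A, B)
    if isinstance(P, Permutation) or (np.ndim(P) == 1):
        pi = P.pi if isinstance(P, Permutation) else np.asarray(P, dtype=np.intp)
        if pi.shape[0] != n:
            raise ValueError("permutation size does not match matrices")
        return float(np.sum(A * B[np.ix_(pi, pi)]))
    P = _as_matrix_operand(P, n)
    _common_n(A, P)
    # trace(A P B^T P^T) = <A P B^T, P>
    return float(np.sum((A @ P @ B.T) * P))


def gm_distance(A, B, P) -> float:
    """Edge-disagreement distance ``||A P - P B||_F``.

    Satisfies ``gm_distance**2 = trace(A^T A) + trace(B B^T)
    - 2 * kb_objective(A, B, P)`` for any permutation matrix ``P``.
    """
    A = as_square(A, "A")
    B = as_square(B, "B")
    n = _common_n(A, B)
    P = _as_matrix_operand(P, n)
    _common_n(A, P)
    return float(np.linalg.norm(A @ P - P @ B, "fro"))


def faq_gradient(A, B, D, direction=Direction.MAXIMIZE) -> np.ndarray:
    """Gradient of the relaxed objective at a doubly stochastic ``D``.

    For ``direction='maximize'`` the objective being *minimized* is
    ``f(D) = -trace(A D B^T D^T)``, whose gradient is
    ``-A D B^T - A^T D B``; for ``'minimize'`` the sign flips.
    """
    A = as_square(A, "A")
    B = as_square(B, "B")
    D = as_square(D, "D")
    _common_n(A, B, D)
    base = A @ D @ B.T + A.T @ D @ B
    return -base if Direction(direction) is Direction.MAXIMIZE else base


def _segment_coeffs_trace(A, B, P, R, sign: float) -> tuple[float, float]:
    """Linear/quadratic coefficients of ``sign*trace(A(P+aR)B^T(P+aR)^T)`` in a."""
    ABtP = A @ P @ B.T
    ABtR = A @ R @ B.T
    c1 = sign * (np.sum(ABtR * P) + np.sum(ABtP * R))
    c2 = sign * np.sum(ABtR * R)
    return float(c1), float(c2)


def _argmin_quadratic_on_unit_interval(c1: float, c2: float) -> float:
    """Minimize ``c1*a + c2*a^2`` over [0, 1]; exact ties take the larger a.

    The interior critical point is a candidate only when the parabola opens
    upward (c2 > 0) and the vertex lies strictly inside the interval.
    """
    candidates = [(0.0, 0.0), (c1 + c2, 1.0)]
    if c2 > 0.0:
        a_star = -c1 / (2.0 * c2)
        if 0.0 < a_star < 1.0:
            candidates.append((c1 * a_star + c2 * a_star * a_star, a_star))
    # min objective; among exact ties prefer the larger step (toward the vertex)
    best_val = min(v for v, _ in candidates)
    return max(a for v, a in candidates if v == best_val)


def exact_line_search(A, B, P, Q, direction=Direction.MAXIMIZE) -> tuple[float, float]:
    """Exact minimizer of the trace objective along the segment P -> Q.

    Along ``P + alpha*(Q - P)`` the (signed, internal-minimization-sense)
    objective is an exact quadratic ``g(alpha) = c0 + c1*alpha + c2*alpha**2``.
    Returns ``(alpha, g(alpha))`` with ``alpha`` in [0, 1]: the interior
    critical point when ``c2 > 0`` and it lies in (0, 1), otherwise the better
    endpoint.  A zero direction (``Q == P``) returns ``alpha = 0``.
    """
    A = as_square(A, "A")
    B = as_square(B, "B")
    P = as_square(P, "P")
    Q = as_square(Q, "Q")
    _common_n(A, B, P, Q)
    sign = Direction(direction).sign
    R = Q - P
    c0 = sign * float(np.sum((A @ P @ B.T) * P))
    if not np.any(R):
        return 0.0, c0
    c1, c2 = _segment_coeffs_trace(A, B, P, R, sign)
    alpha = _argmin_quadratic_on_unit_interval(c1, c2)
    return alpha, c0 + c1 * alpha + c2 * alpha * alpha


def convex_objective_gradient(A, B, D) -> tuple[float, np.ndarray]:
    """Value and gradient of the convex relaxation ``||A D - D B||_F^2``.

    This is the objective the QCV-style comparator minimizes over the
    Birkhoff polytope.  ``grad = 2 A^T (AD - DB) - 2 (AD - DB) B^T``.
    """
    A = as_square(A, "A")
    B = as_square(B, "B")
    D = as_square(D, "D")
    _common_n(A, B, D)
    M = A @ D - D @ B
    value = float(np.sum(M * M))
    grad = 2.0 * (A.T @ M) - 2.0 * (M @ B.T)
    return value, grad
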