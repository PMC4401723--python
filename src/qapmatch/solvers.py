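"""Frank-Wolfe solvers for the relaxed quadratic assignment problem.

The main entry point is :func:`faq`: conditional-gradient (Frank-Wolfe)
iteration on the *indefinite* relaxation of the trace objective over the
Birkhoff polytope, with the linearized subproblem solved exactly as a linear
assignment problem, an exact quadratic line search, and a final projection of
the doubly stochastic iterate onto the permutation matrices (again a LAP).
:func:`qcv_solve` runs the identical machinery on the *convex* relaxation
``||AD - DB||_F^2`` and is provided as a comparator only — for asymmetric
graphs the indefinite relaxation has the isomorphism as its unique minimizer
while the convex one generally does not (regular graphs being the simplest
counterexample, where the barycenter already attains 0).

``brute_force_qap`` exhaustively enumerates permutations for small n and is
the test oracle.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import permutations as _iter_permutations
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import linear_sum_assignment

from .core import (
    Direction,
    Permutation,
    QAPProblem,
    as_square,
    check_doubly_stochastic,
    kb_objective,
    _argmin_quadratic_on_unit_interval,
    _segment_coeffs_trace,
)

__all__ = [
    "SolverConfig",
    "MatchResult",
    "solve_lap",
    "barycenter_init",
    "sinkhorn_balance",
    "random_init",
    "frank_wolfe",
    "project_to_permutation",
    "faq",
    "qcv_solve",
    "brute_force_qap",
]

_MAX_BRUTE_FORCE_N = 9
_SEED_MOD = 2**31


@dataclass(frozen=True)
class SolverConfig:
    """Knobs of the Frank-Wolfe driver.

    Parameters
    ----------
    max_iter : iteration cap per restart (default 100).
    tol : stop when ``||P_i - P_{i-1}||_F < tol`` (default 1e-6).
    init : 'barycenter' starts restart 0 at the flat matrix J = 11^T/n;
        'randomized' starts every restart at a Sinkhorn-randomized point.
        Restarts beyond the first are always randomized.
    n_restarts : independent runs; the best projected permutation wins.
    sinkhorn_iters : balancing passes when drawing a random start (default 10).
    seed : base RNG seed; restart r uses sub-seed ``(seed + r) % 2**31``.
    grad_tol : optional extra stop on ``||grad||_F``; off by default (FW
        stalls are already caught by the zero-step and step-norm rules).
    """

    max_iter: int = 100
    tol: float = 1e-6
    init: str = "barycenter"
    n_restarts: int = 1
    sinkhorn_iters: int = 10
    seed: Optional[int] = None
    grad_tol: Optional[float] = None

    def __post_init__(self):
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        if self.tol <= 0:
            raise ValueError("tol must be > 0")
        if self.n_restarts < 1:
            raise ValueError("n_restarts must be >= 1")
        if self.sinkhorn_iters < 1:
            raise ValueError("sinkhorn_iters must be >= 1")
        if self.init not in ("barycenter", "randomized"):
            raise ValueError("init must be 'barycenter' or 'randomized'")


@dataclass(frozen=True)
class MatchResult:
    """Outcome of a (possibly multi-restart) matching run.

    ``objective`` is ``trace(A P B^T P^T)`` recomputed exactly at the returned
    permutation, on the problem's native direction (the best restart:
    smallest for minimize, largest for maximize).  ``relaxed_objective`` is
    the relaxed objective at the winning restart's final doubly stochastic
    iterate, before projection.
    """

    permutation: Permutation
    objective: float
    relaxed_objective: float
    n_iterations: tuple
    converged: tuple
    restart_objectives: tuple
    direction: Direction
    config: SolverConfig

    @property
    def n(self) -> int:
        return self.permutation.n


def solve_lap(cost, maximize: bool = False) -> Permutation:
    """Exact linear assignment: the permutation optimizing ``sum cost[u, pi(u)]``."""
    cost = np.asarray(cost, dtype=float)
    if cost.ndim != 2 or cost.shape[0] != cost.shape[1]:
        raise ValueError(f"cost must be square, got shape {cost.shape}")
    if not np.all(np.isfinite(cost)):
        raise ValueError("cost matrix contains non-finite entries")
    _, col = linear_sum_assignment(cost, maximize=maximize)
    return Permutation(col)


def barycenter_init(n: int) -> np.ndarray:
    """The flat doubly stochastic matrix J = 11^T/n, center of the polytope."""
    if n < 1:
        raise ValueError("n must be >= 1")
    return np.full((n, n), 1.0 / n)


def sinkhorn_balance(M, iters: int = 10) -> np.ndarray:
    """Drive a strictly positive matrix toward double stochasticity.

    Each of the ``iters`` passes normalizes rows then columns.  The result has
    row/column sums near (not exactly) 1, which is all the randomized
    initialization needs.
    """
    M = as_square(M, "M")
    if iters < 1:
        raise ValueError("iters must be >= 1")
    if M.min() <= 0:
        raise ValueError("Sinkhorn balancing requires strictly positive entries")
    K = M.copy()
    for _ in range(iters):
        K /= K.sum(axis=1, keepdims=True)
        K /= K.sum(axis=0, keepdims=True)
    return K


def random_init(n: int, rng) -> np.ndarray:
    """A random interior point of the Birkhoff polytope, near the barycenter.

    Draws an i.i.d. uniform(0,1) matrix, applies 10 passes of Sinkhorn
    balancing to get ``K``, and returns ``(J + K) / 2``.  Ten passes leave
    row/column sums off by up to ~1e-7, so the average is renormalized (extra
    balancing passes, initialization only — iterates are never renormalized)
    until it is feasible well within the 1e-8 doubly stochastic tolerance.
    """
    rng = np.random.default_rng(rng)
    K = sinkhorn_balance(rng.uniform(size=(n, n)) + np.finfo(float).tiny, 10)
    P0 = 0.5 * (barycenter_init(n) + K)
    for _ in range(1000):
        rows = P0.sum(axis=1, keepdims=True)
        cols = P0.sum(axis=0, keepdims=True)
        if max(np.abs(rows - 1.0).max(), np.abs(cols - 1.0).max()) <= 1e-10:
            break
        P0 = P0 / rows
        P0 = P0 / P0.sum(axis=0, keepdims=True)
    return P0


class _TraceObjective:
    """Internal-minimization view of ``sign * trace(A D B^T D^T)``."""

    def __init__(self, A, B, direction):
        self.A, self.B = A, B
        self.sign = Direction(direction).sign

    def value(self, D):
        return self.sign * float(np.sum((self.A @ D @ self.B.T) * D))

    def gradient(self, D):
        return self.sign * (self.A @ D @ self.B.T + self.A.T @ D @ self.B)

    def segment_coeffs(self, P, R):
        return _segment_coeffs_trace(self.A, self.B, P, R, self.sign)


class _ConvexObjective:
    """The convex relaxation ``||A D - D B||_F^2`` (QCV-style comparator)."""

    def __init__(self, A, B):
        self.A, self.B = A, B

    def value(self, D):
        M = self.A @ D - D @ self.B
        return float(np.sum(M * M))

    def gradient(self, D):
        M = self.A @ D - D @ self.B
        return 2.0 * (self.A.T @ M) - 2.0 * (M @ self.B.T)

    def segment_coeffs(self, P, R):
        M = self.A @ P - P @ self.B
        N = self.A @ R - R @ self.B
        return 2.0 * float(np.sum(M * N)), float(np.sum(N * N))


def _frank_wolfe_loop(objective, P0, config: SolverConfig, debug: bool = False,
                      history: Optional[list] = None):
    """Run FW on a generic quadratic objective over the Birkhoff polytope.

    Each iteration: linearize at P, solve the LAP for the vertex Q minimizing
    the linearization, take the exact-line-search step along P -> Q.  Iterates
    stay feasible because every update is a convex combination of feasible
    points.  Stops on a zero step (alpha = 0), a small move
    (``||P_new - P||_F < tol``), optionally a small gradient, or max_iter.
    If ``history`` is a list, the relaxed objective (minimization sense) is
    appended at the start and after every accepted step.
    """
    P = check_doubly_stochastic(P0, name="P0").copy()
    converged = False
    n_iter = 0
    if history is not None:
        history.append(objective.value(P))
    for _ in range(config.max_iter):
        G = objective.gradient(P)
        if config.grad_tol is not None and np.linalg.norm(G) < config.grad_tol:
            converged = True
            break
        Q = solve_lap(G, maximize=False).as_matrix()
        R = Q - P
        if not np.any(R):
            converged = True
            break
        c1, c2 = objective.segment_coeffs(P, R)
        alpha = _argmin_quadratic_on_unit_interval(c1, c2)
        if alpha == 0.0:
            converged = True
            break
        step = alpha * R
        P = P + step
        n_iter += 1
        if debug:
            check_doubly_stochastic(P, name=f"P (iteration {n_iter})")
        if history is not None:
            history.append(objective.value(P))
        if np.linalg.norm(step) < config.tol:
            converged = True
            break
    return P, n_iter, converged


def frank_wolfe(problem: QAPProblem, P0, config: Optional[SolverConfig] = None,
                debug: bool = False, history_out: Optional[list] = None):
    """Single Frank-Wolfe solve of the indefinite relaxation from ``P0``.

    Returns ``(P_final, n_iter, converged)`` with ``P_final`` doubly
    stochastic.  The relaxed objective (minimization sense) is non-increasing
    across iterations by construction of the exact line search; pass a list
    as ``history_out`` to capture it.  ``debug=True`` validates feasibility
    of every iterate.
    """
    config = config or SolverConfig()
    objective = _TraceObjective(problem.A, problem.B, problem.direction)
    return _frank_wolfe_loop(objective, P0, config, debug=debug, history=history_out)


def project_to_permutation(D) -> Permutation:
    """Nearest permutation: argmax of ``trace(D P^T)`` over permutations (a LAP)."""
    D = check_doubly_stochastic(D, name="D")
    return solve_lap(D, maximize=True)


def _restart_inits(n: int, config: SolverConfig):
    """Yield the initial point for each restart.

    Restart 0 is the deterministic barycenter (unless ``init='randomized'``);
    later restarts draw Sinkhorn-randomized points with sub-seeds
    ``seed + r`` so a k-restart run is reproducible and nested in a
    (k+1)-restart run.
    """
    for r in range(config.n_restarts):
        if r == 0 and config.init == "barycenter":
            yield barycenter_init(n)
        else:
            seed = None if config.seed is None else (config.seed + r) % _SEED_MOD
            yield random_init(n, np.random.default_rng(seed))


def _multi_restart(problem: QAPProblem, config: SolverConfig, objective_factory):
    A, B = problem.A, problem.B
    best = None  # (native objective, perm, relaxed, index)
    iters, flags, natives = [], [], []
    for P0 in _restart_inits(problem.n, config):
        objective = objective_factory()
        P_final, n_iter, converged = _frank_wolfe_loop(objective, P0, config)
        perm = project_to_permutation(P_final)
        native = kb_objective(A, B, perm)
        iters.append(n_iter)
        flags.append(converged)
        natives.append(native)
        better = (
            best is None
            or (problem.maximize and native > best[0])
            or (not problem.maximize and native < best[0])
        )
        if better:
            best = (native, perm, objective.value(P_final))
    native, perm, relaxed = best
    return MatchResult(
        permutation=perm,
        objective=native,
        relaxed_objective=relaxed,
        n_iterations=tuple(iters),
        converged=tuple(flags),
        restart_objectives=tuple(natives),
        direction=problem.direction,
        config=config,
    )


def faq(problem: QAPProblem, config: Optional[SolverConfig] = None) -> MatchResult:
    """Fast approximate QAP: multi-restart FW on the indefinite relaxation.

    Runs ``config.n_restarts`` independent Frank-Wolfe solves (restart 0 from
    the barycenter by default, the rest from Sinkhorn-randomized starts),
    projects each final iterate to a permutation, recomputes the exact trace
    objective there, and returns the best.  Deterministic given
    ``(problem, config)`` including the seed.
    """
    config = config or SolverConfig()
    A, B, d = problem.A, problem.B, problem.direction
    return _multi_restart(problem, config, lambda: _TraceObjective(A, B, d))


def qcv_solve(problem: QAPProblem, config: Optional[SolverConfig] = None) -> MatchResult:
    """Comparator: identical FW machinery on the convex relaxation.

    Minimizes ``||AD - DB||_F^2`` over the Birkhoff polytope and projects onto
    the permutations.  The reported ``objective`` is still the trace objective
    at the projected permutation (native direction), so results are directly
    comparable with :func:`faq`; ``relaxed_objective`` is the convex value at
    the final iterate.
    """
    config = config or SolverConfig()
    A, B = problem.A, problem.B
    return _multi_restart(problem, config, lambda: _ConvexObjective(A, B))


def brute_force_qap(problem: QAPProblem) -> tuple[Permutation, float]:
    """Exhaustive global optimum over all n! permutations (test oracle, n <= 9)."""
    n = problem.n
    if n > _MAX_BRUTE_FORCE_N:
        raise ValueError(
            f"brute force refused for n = {n} > {_MAX_BRUTE_FORCE_N} "
            "(factorial blow-up)"
        )
    A, B = problem.A, problem.B
    better = max if problem.maximize else min
    best_pi, best_val = None, None
    for pi in _iter_permutations(range(n)):
        pi = np.asarray(pi, dtype=np.intp)
        val = float(np.sum(A * B[np.ix_(pi, pi)]))
        if best_val is None or better(val, best_val) != best_val:
            best_pi, best_val = pi, val
    return Permutation(best_pi), best_val
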