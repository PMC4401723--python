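"""Frank-Wolfe loop, LAP, initializations, restarts, and the brute-force oracle."""

from itertools import permutations

import numpy as np
import pytest

from qapmatch import (
    Direction,
    Permutation,
    QAPProblem,
    SolverConfig,
    barycenter_init,
    brute_force_qap,
    faq,
    frank_wolfe,
    gm_distance,
    kb_objective,
    project_to_permutation,
    qcv_solve,
    random_init,
    sinkhorn_balance,
    solve_lap,
)
from qapmatch.core import check_doubly_stochastic
from qapmatch.solvers import _TraceObjective, _frank_wolfe_loop
from qapmatch.synthetic import er_graph, known_optimum_instance, shuffle_graph

from conftest import random_instance


def exhaustive_lap(cost, maximize=False):
    best = None
    pick = max if maximize else min
    for pi in permutations(range(cost.shape[0])):
        val = sum(cost[u, pi[u]] for u in range(cost.shape[0]))
        if best is None or pick(val, best) != best:
            best = val
    return best


class TestSolveLAP:
    def test_diagonal_preference(self):
        cost = np.ones((4, 4)) - np.eye(4)
        assert solve_lap(cost) == Permutation.identity(4)

    def test_trace_maximization_recovers_permutation(self, rng):
        pi = Permutation(rng.permutation(6))
        assert solve_lap(pi.as_matrix(), maximize=True) == pi

    @pytest.mark.parametrize("seed", range(5))
    @pytest.mark.parametrize("maximize", [False, True])
    def test_optimal_value_matches_exhaustive(self, seed, maximize):
        rng = np.random.default_rng(seed)
        cost = rng.integers(0, 50, (5, 5)).astype(float)
        pi = solve_lap(cost, maximize=maximize)
        value = cost[np.arange(5), pi.pi].sum()
        assert value == exhaustive_lap(cost, maximize=maximize)

    def test_non_finite_rejected(self):
        cost = np.zeros((3, 3))
        cost[1, 1] = np.nan
        with pytest.raises(ValueError):
            solve_lap(cost)


class TestInitializations:
    def test_barycenter_entries(self):
        assert np.all(barycenter_init(1) == 1.0)
        assert np.all(barycenter_init(4) == 0.25)
        check_doubly_stochastic(barycenter_init(17))

    def test_barycenter_rejects_bad_n(self):
        with pytest.raises(ValueError):
            barycenter_init(0)

    def test_sinkhorn_fixed_point(self):
        D = barycenter_init(6)
        assert np.allclose(sinkhorn_balance(D, 3), D, atol=1e-12)

    def test_sinkhorn_scalar_multiple_of_flat(self):
        J = barycenter_init(5)
        assert np.allclose(sinkhorn_balance(7.3 * J, 1), J)

    def test_sinkhorn_monotone_balancing(self):
        rng = np.random.default_rng(3)
        M = rng.uniform(size=(10, 10))

        def residual(K):
            return max(np.abs(K.sum(0) - 1).max(), np.abs(K.sum(1) - 1).max())

        assert residual(sinkhorn_balance(M, 10)) < residual(sinkhorn_balance(M, 1))

    def test_sinkhorn_rejects_nonpositive(self):
        M = np.ones((3, 3))
        M[0, 0] = 0.0
        with pytest.raises(ValueError):
            sinkhorn_balance(M)

    @pytest.mark.parametrize("n", [2, 8, 30])
    def test_random_init_feasible_and_interior(self, n):
        P0 = random_init(n, np.random.default_rng(0))
        check_doubly_stochastic(P0)
        # the barycenter contributes 1/(2n) to every entry
        assert P0.min() >= 1.0 / (2 * n) - 1e-8

    def test_random_init_reproducible(self):
        a = random_init(6, np.random.default_rng(42))
        b = random_init(6, np.random.default_rng(42))
        c = random_init(6, np.random.default_rng(43))
        assert np.array_equal(a, b)
        assert not np.array_equal(a, c)


class TestFrankWolfe:
    def test_n1_converges_immediately(self):
        problem = QAPProblem(np.array([[2.0]]), np.array([[3.0]]))
        P, n_iter, converged = frank_wolfe(problem, barycenter_init(1))
        assert converged and np.allclose(P, [[1.0]])

    def test_asymmetric_self_match_reaches_identity(self):
        # directed ER graph, maximize, barycenter start: relaxed optimum is
        # the identity with value trace(AA^T) = number of edges
        A = er_graph(20, seed=1, directed=True)
        problem = QAPProblem(A, A, Direction.MAXIMIZE)
        P, _, converged = frank_wolfe(problem, barycenter_init(20))
        assert converged
        assert np.allclose(P, np.eye(20), atol=1e-8)
        assert -_TraceObjective(A, A, Direction.MAXIMIZE).value(P) == pytest.approx(
            float((A * A).sum())
        )

    @pytest.mark.parametrize("seed", range(20))
    def test_relaxed_objective_monotone_nonincreasing(self, seed):
        A, B = random_instance(seed, n=6)
        problem = QAPProblem(A, B)
        history = []
        P, _, _ = frank_wolfe(problem, barycenter_init(6), history_out=history)
        assert all(b <= a + 1e-9 for a, b in zip(history, history[1:]))

    @pytest.mark.parametrize("seed", range(5))
    def test_iterates_stay_feasible_in_debug_mode(self, seed):
        A, B = random_instance(seed, n=8)
        frank_wolfe(QAPProblem(A, B), barycenter_init(8), debug=True)

    def test_infeasible_start_rejected(self):
        A, B = random_instance(0, n=4)
        with pytest.raises(ValueError):
            frank_wolfe(QAPProblem(A, B), np.eye(4) * 2)


class TestProjection:
    def test_permutation_matrix_is_its_own_projection(self, rng):
        pi = Permutation(rng.permutation(7))
        assert project_to_permutation(pi.as_matrix()) == pi

    def test_flat_matrix_projects_to_some_permutation(self):
        perm = project_to_permutation(barycenter_init(5))
        assert np.array_equal(np.sort(perm.pi), np.arange(5))

    @pytest.mark.parametrize("seed", range(5))
    def test_projection_attains_exhaustive_trace_maximum(self, seed):
        D = random_init(5, np.random.default_rng(seed))
        perm = project_to_permutation(D)
        attained = D[np.arange(5), perm.pi].sum()
        best = max(
            sum(D[u, pi[u]] for u in range(5)) for pi in permutations(range(5))
        )
        assert attained == pytest.approx(best)


class TestFAQ:
    def test_objective_is_recomputed_at_permutation(self):
        A, B = random_instance(3, n=7)
        result = faq(QAPProblem(A, B), SolverConfig(n_restarts=3, seed=0))
        assert result.objective == kb_objective(A, B, result.permutation)
        assert result.objective == min(result.restart_objectives)

    def test_shuffled_self_match_recovers_exactly(self):
        pair = shuffle_graph(er_graph(20, seed=2, directed=True), seed=5)
        result = faq(QAPProblem(pair.A, pair.B, Direction.MAXIMIZE))
        assert gm_distance(pair.A, pair.B, result.permutation) == 0.0
        assert result.permutation == pair.unshuffle

    @pytest.mark.parametrize("seed", range(25))
    def test_never_beats_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 8))
        A = rng.integers(0, 10, (n, n)).astype(float)
        B = rng.integers(0, 10, (n, n)).astype(float)
        problem = QAPProblem(A, B)
        _, best = brute_force_qap(problem)
        result = faq(problem, SolverConfig(n_restarts=3, seed=seed))
        assert result.objective >= best - 1e-9

    @pytest.mark.parametrize("seed", range(5))
    def test_self_match_attains_brute_force_optimum(self, seed):
        # A = B directed ER: barycenter start reaches the global optimum
        A = er_graph(7, seed=seed, directed=True)
        problem = QAPProblem(A, A, Direction.MAXIMIZE)
        _, best = brute_force_qap(problem)
        assert faq(problem).objective == best

    def test_restart_dominance(self):
        A, B = random_instance(11, n=10)
        problem = QAPProblem(A, B)
        objs = [
            faq(problem, SolverConfig(n_restarts=k, seed=7)).objective
            for k in (1, 2, 4, 8)
        ]
        assert all(b <= a for a, b in zip(objs, objs[1:]))

    def test_deterministic_given_config(self):
        A, B = random_instance(5, n=12)
        cfg = SolverConfig(n_restarts=4, seed=99)
        r1 = faq(QAPProblem(A, B), cfg)
        r2 = faq(QAPProblem(A, B), cfg)
        assert r1.permutation == r2.permutation
        assert r1.objective == r2.objective
        assert r1.restart_objectives == r2.restart_objectives

    def test_matches_reference_implementation(self):
        # scipy's quadratic_assignment(method='faq') is the independent
        # reference; with a barycenter start and no input shuffling both
        # implementations run the same deterministic iteration.
        from scipy.optimize import quadratic_assignment

        for seed in range(8):
            rng = np.random.default_rng(seed)
            n = int(rng.integers(5, 12))
            A = rng.integers(0, 10, (n, n)).astype(float)
            B = rng.integers(0, 10, (n, n)).astype(float)
            ref = quadratic_assignment(
                A, B,
                options={"P0": "barycenter", "shuffle_input": False,
                         "tol": 1e-6, "maxiter": 100},
            )
            assert faq(QAPProblem(A, B)).objective == ref.fun

    def test_known_optimum_instances_solved_single_start(self):
        for n, seed in [(20, 0), (30, 1)]:
            problem, optimum = known_optimum_instance(n, seed=seed)
            assert faq(problem).objective == optimum


class TestQCV:
    @pytest.mark.parametrize("seed", range(10))
    def test_relaxed_objective_monotone(self, seed):
        from qapmatch.solvers import _ConvexObjective

        A, B = random_instance(seed, n=6)
        history = []
        _frank_wolfe_loop(
            _ConvexObjective(A, B), barycenter_init(6), SolverConfig(),
            history=history,
        )
        assert all(b <= a + 1e-9 for a, b in zip(history, history[1:]))

    def test_regular_graph_relaxation_bottoms_out_at_barycenter(self):
        import networkx as nx

        A = nx.to_numpy_array(nx.random_regular_graph(4, 14, seed=2))
        from qapmatch import convex_objective_gradient

        value, _ = convex_objective_gradient(A, A, barycenter_init(14))
        assert value == pytest.approx(0.0, abs=1e-18)

    def test_reports_trace_objective_of_projection(self):
        A, B = random_instance(2, n=8)
        result = qcv_solve(QAPProblem(A, B), SolverConfig(seed=0))
        assert result.objective == kb_objective(A, B, result.permutation)


class TestBruteForce:
    def test_n1_trivial(self):
        perm, val = brute_force_qap(QAPProblem(np.array([[5.0]]), np.array([[2.0]])))
        assert perm == Permutation.identity(1) and val == 10.0

    def test_refuses_large_n(self):
        A = np.zeros((10, 10))
        with pytest.raises(ValueError):
            brute_force_qap(QAPProblem(A, A))

    def test_asymmetric_self_match_identity_unique(self):
        A = er_graph(7, seed=3, directed=True)
        perm, val = brute_force_qap(QAPProblem(A, A, Direction.MAXIMIZE))
        assert val == float((A * A).sum())
        assert perm == Permutation.identity(7)

    @pytest.mark.parametrize("seed", range(3))
    def test_degenerates_to_lap_for_diagonal_b(self, seed):
        # B = diag(d): sum a_uv d_pi(u) [u==v] -> assignment of diagonal of A to d
        rng = np.random.default_rng(seed)
        A = rng.integers(0, 9, (5, 5)).astype(float)
        d = rng.integers(1, 9, 5).astype(float)
        B = np.diag(d)
        _, val = brute_force_qap(QAPProblem(A, B))
        cost = np.outer(np.diag(A), d)
        lap_pi = solve_lap(cost)
        assert val == cost[np.arange(5), lap_pi.pi].sum()
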