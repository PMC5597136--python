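"""Constrained solver: projections, oracles, feasibility, weight iteration."""

import numpy as np
import pytest

from stablevar import (
    GershgorinWeights,
    InvalidInputError,
    LaggedData,
    SolverConfig,
    infer_network,
    solve_fixed_weights,
)
from stablevar.solver import (
    project_feasible,
    project_gershgorin_cone,
    project_l1_ball,
)

from conftest import brute_force_objective_2x2, clipped_ols_1d


# ---------------------------------------------------------------------------
# projections

def test_l1_projection_inside_is_identity():
    X = np.array([[0.2, -0.1], [0.0, 0.3]])
    np.testing.assert_array_equal(project_l1_ball(X, 1.0), X)


def test_l1_projection_known_value():
    # project (3, 1) onto the l1 ball of radius 2: soft-threshold at 1
    X = np.array([[3.0, 1.0]])
    np.testing.assert_allclose(project_l1_ball(X, 2.0), [[2.0, 0.0]])


def test_l1_projection_is_projection(rng):
    """Result is feasible and no feasible point is closer (spot-checked)."""
    for _ in range(20):
        X = rng.normal(size=(3, 3))
        r = rng.uniform(0.1, 2.0)
        P = project_l1_ball(X, r)
        assert np.abs(P).sum() <= r + 1e-10
        for _ in range(20):
            Q = project_l1_ball(X + 0.5 * rng.normal(size=(3, 3)), r)
            assert np.linalg.norm(X - P) <= np.linalg.norm(X - Q) + 1e-10


def test_gershgorin_projection_feasible_is_identity():
    A = np.array([[-1.0, 0.5], [0.2, -0.5]])
    v = np.array([1.0, 1.0])
    np.testing.assert_array_equal(project_gershgorin_cone(A, v), A)


def test_gershgorin_projection_output_feasible(rng):
    from stablevar import stability_margins

    for _ in range(100):
        n = rng.integers(2, 6)
        A = rng.normal(size=(n, n))
        v = rng.uniform(0.2, 1.8, size=n)
        P = project_gershgorin_cone(A, v)
        g = stability_margins(P, GershgorinWeights(v=v))
        assert np.all(g <= 1e-9)


def test_gershgorin_projection_optimality(rng):
    """No nearby feasible point is closer than the projection."""
    from stablevar import stability_margins

    for _ in range(20):
        A = rng.normal(size=(3, 3))
        v = rng.uniform(0.3, 1.7, size=3)
        P = project_gershgorin_cone(A, v)
        d0 = np.linalg.norm(A - P)
        w = GershgorinWeights(v=v)
        for _ in range(40):
            C = P + 0.1 * rng.normal(size=(3, 3))
            C = project_gershgorin_cone(C, v)
            assert np.all(stability_margins(C, w) <= 1e-9)
            assert d0 <= np.linalg.norm(A - C) + 1e-8


def test_project_feasible_both_constraints(rng):
    from stablevar import stability_margins

    for _ in range(30):
        A = rng.normal(size=(4, 4))
        v = rng.uniform(0.3, 1.7, size=4)
        lam = rng.uniform(0.1, 3.0)
        P = project_feasible(A, lam, v)
        assert np.abs(P).sum() <= lam + 1e-10
        assert np.all(stability_margins(P, GershgorinWeights(v=v)) <= 1e-9)


# ---------------------------------------------------------------------------
# fixed-weight solves against independent oracles

def test_lambda_zero_gives_zero_matrix(rng):
    Y, Z = rng.normal(size=(2, 8)), rng.normal(size=(2, 8))
    sol = solve_fixed_weights(LaggedData(Y=Y, Z=Z), 0.0, GershgorinWeights.unit(2))
    np.testing.assert_array_equal(sol.A, np.zeros((2, 2)))
    assert sol.objective == pytest.approx(0.5 * np.linalg.norm(Y, "fro") ** 2)


def test_scalar_case_matches_clipped_ols(rng):
    for _ in range(20):
        z = rng.normal(size=12)
        y = rng.uniform(-0.8, 0.8) * z + 0.1 * rng.normal(size=12)
        lam = rng.uniform(0.05, 1.0)
        sol = solve_fixed_weights(
            LaggedData(Y=y[None, :], Z=z[None, :]), lam, GershgorinWeights.unit(1)
        )
        a_ref = clipped_ols_1d(y, z, lam)
        obj_ref = 0.5 * float(np.sum((y - a_ref * z) ** 2))
        assert sol.A[0, 0] == pytest.approx(a_ref, abs=1e-5)
        assert sol.objective == pytest.approx(obj_ref, abs=1e-6)


def test_two_gene_case_matches_brute_force(rng):
    for _ in range(5):
        Y = rng.normal(size=(2, 15))
        Z = rng.normal(size=(2, 15))
        lam = rng.uniform(0.2, 1.5)
        v = rng.uniform(0.4, 1.6, size=2)
        sol = solve_fixed_weights(LaggedData(Y=Y, Z=Z), lam, GershgorinWeights(v=v))
        obj_ref = brute_force_objective_2x2(Y, Z, lam, v)
        assert abs(sol.objective - obj_ref) <= 1e-3


def test_solution_feasibility_invariants(rng):
    from stablevar import stability_margins

    for _ in range(15):
        n = rng.integers(2, 5)
        Y = rng.normal(size=(n, 20))
        Z = rng.normal(size=(n, 20))
        lam = rng.uniform(0.1, 2.0)
        v = rng.uniform(0.3, 1.7, size=n)
        w = GershgorinWeights(v=v)
        sol = solve_fixed_weights(LaggedData(Y=Y, Z=Z), lam, w)
        assert np.abs(sol.A).sum() <= lam + 1e-9
        assert np.all(stability_margins(sol.A, w) <= 1e-9)
        assert np.all(np.diag(sol.A) <= 1e-9)
        assert np.max(np.linalg.eigvals(sol.A).real) <= 1e-9


def test_objective_nonincreasing_in_budget(rng):
    Y = rng.normal(size=(3, 25))
    Z = rng.normal(size=(3, 25))
    w = GershgorinWeights.unit(3)
    objs = [
        solve_fixed_weights(LaggedData(Y=Y, Z=Z), lam, w).objective
        for lam in np.linspace(0.0, 2.0, 9)
    ]
    diffs = np.diff(objs)
    assert np.all(diffs <= 1e-8)


def test_warm_start_does_not_change_answer(rng):
    Y = rng.normal(size=(3, 20))
    Z = rng.normal(size=(3, 20))
    w = GershgorinWeights.unit(3)
    data = LaggedData(Y=Y, Z=Z)
    cold = solve_fixed_weights(data, 0.8, w)
    near = solve_fixed_weights(data, 0.7, w)
    warm = solve_fixed_weights(data, 0.8, w, warm=near.state)
    assert warm.objective == pytest.approx(cold.objective, abs=1e-6)


def test_mismatched_weights_raise(rng):
    data = LaggedData(Y=rng.normal(size=(2, 8)), Z=rng.normal(size=(2, 8)))
    with pytest.raises(InvalidInputError, match="weights"):
        solve_fixed_weights(data, 1.0, GershgorinWeights.unit(3))


def test_negative_lambda_raises(rng):
    data = LaggedData(Y=rng.normal(size=(2, 8)), Z=rng.normal(size=(2, 8)))
    with pytest.raises(InvalidInputError, match="lam"):
        solve_fixed_weights(data, -0.1, GershgorinWeights.unit(2))


# ---------------------------------------------------------------------------
# full inference

def test_infer_network_deterministic(small_expr):
    a = infer_network(small_expr, SolverConfig(lam=0.5))
    b = infer_network(small_expr, SolverConfig(lam=0.5))
    np.testing.assert_array_equal(a.A_hat, b.A_hat)
    np.testing.assert_array_equal(a.weights.v, b.weights.v)


def test_infer_network_result_feasible(small_expr):
    res = infer_network(small_expr, SolverConfig(lam=0.8))
    assert res.l1_norm <= 0.8 + 1e-9
    assert np.all(res.margins <= 1e-9)
    assert np.all(np.diag(res.A_hat) <= 1e-9)
    assert np.max(res.eigenvalues.real) <= 1e-9


def test_infer_network_records_config_and_labels(small_expr):
    cfg = SolverConfig(lam=0.4, delta=0.7)
    res = infer_network(small_expr, cfg)
    assert res.config == cfg
    assert res.gene_ids == small_expr.gene_ids
    np.testing.assert_allclose(res.row_means, small_expr.row_means())


def test_solver_config_validation():
    with pytest.raises(InvalidInputError):
        SolverConfig(lam=-1.0)
    with pytest.raises(InvalidInputError):
        SolverConfig(delta=1.5)
    with pytest.raises(InvalidInputError):
        SolverConfig(solver_tol=0.0)
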