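"""Shared fixtures and helpers for the test suite."""

import numpy as np
import pytest

from stablevar import (
    ExpressionMatrix,
    GeneratorSpec,
    VARModel,
    generate_dataset,
    random_stable_sparse_model,
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_expr():
    """A deterministic 3-gene, 12-observation expression matrix."""
    model = VARModel(
        A=np.array([[-0.5, 0.2, 0.0], [0.0, -0.6, 0.3], [0.1, 0.0, -0.4]]),
        noise_cov=0.05**2 * np.eye(3),
    )
    from stablevar import simulate_var

    return simulate_var(model, 12, seed=7, burn_in=10)


@pytest.fixture
def synthetic_pair():
    """(model, truth, expression) for a default 6-gene instance."""
    spec = GeneratorSpec(seed=42)
    model, truth = random_stable_sparse_model(spec)
    expr = generate_dataset(model, 60, noise_sd=spec.noise_sd, seed=43)
    return model, truth, expr


def _row_qp_min(zd, zo, y, w, s):
    """Exact minimum of one row's 2-variable constrained least squares.

    minimise 1/2 || y - a zd - b zo ||^2
    subject to a + w |b| <= 0  and  |a| + |b| <= s

    (a is the diagonal coefficient on its own lagged series zd, b the
    off-diagonal one on zo).  The first constraint forces a <= 0, so with
    the sign of b fixed every constraint is linear; for each sign the
    strictly convex 2-D QP is solved exactly by enumerating active sets
    (interior optimum, each single constraint, each constraint pair).
    Shares no code with the production solver.
    """
    H = np.array([[zd @ zd, zd @ zo], [zd @ zo, zo @ zo]])
    c = np.array([y @ zd, y @ zo])
    const = 0.5 * float(y @ y)

    def f(x):
        return 0.5 * float(x @ H @ x) - float(c @ x) + const

    best = f(np.zeros(2))  # the origin is always feasible
    for sigma in (1.0, -1.0):
        # constraints  A_in x <= b_in  on the half-plane sigma * b >= 0
        A_in = np.array([[1.0, w * sigma], [-1.0, sigma], [0.0, -sigma]])
        b_in = np.array([0.0, s, 0.0])
        cands = []
        try:
            cands.append(np.linalg.solve(H, c))
        except np.linalg.LinAlgError:
            pass
        for i in range(3):
            K = np.block([[H, A_in[i][:, None]], [A_in[i][None, :], np.zeros((1, 1))]])
            try:
                sol = np.linalg.solve(K, np.append(c, b_in[i]))
                cands.append(sol[:2])
            except np.linalg.LinAlgError:
                pass
        for i in range(3):
            for j in range(i + 1, 3):
                M = A_in[[i, j]]
                if abs(np.linalg.det(M)) > 1e-12:
                    cands.append(np.linalg.solve(M, b_in[[i, j]]))
        for x in cands:
            if np.all(A_in @ x <= b_in + 1e-9):
                best = min(best, f(x))
    return best


def brute_force_objective_2x2(Y, Z, lam, v):
    """Independent exact minimiser of the constrained 2x2 problem.

    The objective separates by rows; only the L1 budget couples them.  For
    a budget split s (row 1) / lam - s (row 2) each row is an exactly
    solvable 2-variable QP (see _row_qp_min); the total as a function of s
    is convex, so a bounded scalar search plus the endpoints finds the
    joint optimum.
    """
    from scipy.optimize import minimize_scalar

    w12 = v[1] / v[0]
    w21 = v[0] / v[1]

    def h(s):
        r1 = _row_qp_min(Z[0], Z[1], Y[0], w12, s)
        r2 = _row_qp_min(Z[1], Z[0], Y[1], w21, lam - s)
        return r1 + r2

    res = minimize_scalar(h, bounds=(0.0, lam), method="bounded",
                          options={"xatol": 1e-10})
    return min(h(0.0), h(lam), float(res.fun))


def clipped_ols_1d(y, z, lam):
    """Closed-form solution of the 1-gene constrained problem.

    min 1/2 ||y - a z||^2 subject to |a| <= lam and a <= 0 (the 1x1
    Gershgorin margin is just the diagonal entry).  The quadratic is
    minimised at the OLS value and monotone away from it, so the
    constrained solution clips OLS to the interval [-lam, 0].
    """
    a_ols = float(y @ z) / float(z @ z)
    return float(np.clip(a_ols, -lam, 0.0))


def toy_expression(values, gene_ids=None):
    arr = np.atleast_2d(np.asarray(values, dtype=float))
    return ExpressionMatrix.from_array(arr, gene_ids=gene_ids)
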