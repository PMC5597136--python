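"""VAR(1) representation, lag construction, OLS estimation and simulation.

The model is y_t = v + A y_{t-1} + u_t with A an N x N coefficient matrix.
Orientation convention used everywhere in this package: A[i, j] != 0 means a
directed regulatory edge gene_j -> gene_i (the state of gene j at time t-1
affects gene i at time t, i.e. lagged predictors define Granger-style edge
direction).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .expression import ExpressionMatrix, InvalidInputError

__all__ = [
    "VARModel",
    "LaggedData",
    "StabilityReport",
    "build_lagged_matrices",
    "ols_estimate",
    "ols_standard_errors",
    "is_stable",
    "simulate_var",
]


class SingularDesignError(np.linalg.LinAlgError):
    """Raised when the lag covariate Gram matrix Z Z' is rank deficient."""


@dataclass(frozen=True)
class VARModel:
    """First-order VAR: y_t = v + A y_{t-1} + u_t.

    A is N x N; ``intercept`` defaults to zero; ``noise_cov`` is the
    innovation covariance (defaults to ``sigma**2 * I`` when simulating).
    """

    A: np.ndarray
    intercept: "np.ndarray | None" = None
    noise_cov: "np.ndarray | None" = None

    def __post_init__(self) -> None:
        A = np.asarray(self.A, dtype=float)
        if A.ndim != 2 or A.shape[0] != A.shape[1]:
            raise InvalidInputError("coefficient matrix A must be square")
        object.__setattr__(self, "A", A)
        n = A.shape[0]
        if self.intercept is not None:
            v = np.asarray(self.intercept, dtype=float).reshape(-1)
            if v.shape != (n,):
                raise InvalidInputError("intercept must be an N-vector")
            object.__setattr__(self, "intercept", v)
        if self.noise_cov is not None:
            S = np.asarray(self.noise_cov, dtype=float)
            if S.shape != (n, n):
                raise InvalidInputError("noise_cov must be N x N")
            if not np.allclose(S, S.T, atol=1e-10):
                raise InvalidInputError("noise_cov must be symmetric")
            w = np.linalg.eigvalsh(S)
            if w.min() < -1e-10 * max(1.0, w.max()):
                raise InvalidInputError("noise_cov must be positive semidefinite")
            object.__setattr__(self, "noise_cov", S)

    @property
    def n_genes(self) -> int:
        return self.A.shape[0]


@dataclass(frozen=True)
class LaggedData:
    """One-lag aligned response/covariate pair.

    Column k of ``Z`` is observation k of the input series and column k of
    ``Y`` is observation k+1, so Y ~ A Z is the one-step regression.
    """

    Y: np.ndarray
    Z: np.ndarray

    def __post_init__(self) -> None:
        Y = np.asarray(self.Y, dtype=float)
        Z = np.asarray(self.Z, dtype=float)
        if Y.shape != Z.shape:
            raise InvalidInputError("Y and Z must have identical shape")
        object.__setattr__(self, "Y", Y)
        object.__setattr__(self, "Z", Z)


@dataclass(frozen=True)
class StabilityReport:
    stable: bool
    eigenvalues: np.ndarray = field(repr=False)
    mode: str = "modulus"
    tol: float = 1e-7

    @property
    def spectral_radius(self) -> float:
        return float(np.max(np.abs(self.eigenvalues)))

    @property
    def max_real_part(self) -> float:
        return float(np.max(self.eigenvalues.real))


def build_lagged_matrices(expr: ExpressionMatrix) -> LaggedData:
    """Align a series of T observations into T-1 lag pairs.

    Uses the single-series convention (no presample): Z = observations
    1..T-1, Y = observations 2..T.
    """
    vals = np.atleast_2d(np.asarray(expr.values if hasattr(expr, "values") else expr,
                                    dtype=float))
    if vals.shape[1] < 3:
        raise InvalidInputError(
            f"need at least 3 observations to form lag pairs, got {vals.shape[1]}"
        )
    return LaggedData(Y=vals[:, 1:].copy(), Z=vals[:, :-1].copy())


def ols_estimate(
    data: LaggedData, intercept: bool = False
) -> "tuple[VARModel, float]":
    """Unpenalised multivariate least-squares fit of Y ~ A Z.

    Solves min_A ||Y - A Z||_F^2 (plus an intercept column when requested)
    through the normal equations A (Z Z') = Y Z'.  Returns the fitted model
    and the Frobenius norm of the residual.
    """
    Y, Z = data.Y, data.Z
    n = Z.shape[0]
    if intercept:
        Zx = np.vstack([Z, np.ones((1, Z.shape[1]))])
    else:
        Zx = Z
    G = Zx @ Zx.T
    rank = np.linalg.matrix_rank(G)
    if rank < G.shape[0]:
        raise SingularDesignError(
            f"Z Z' is rank deficient (rank {rank} < {G.shape[0]}); "
            "the design does not identify all coefficients"
        )
    coef = np.linalg.solve(G, Zx @ Y.T).T
    if intercept:
        A, v = coef[:, :n], coef[:, n]
        model = VARModel(A=A, intercept=v)
        resid = Y - A @ Z - v[:, None]
    else:
        model = VARModel(A=coef)
        resid = Y - coef @ Z
    return model, float(np.linalg.norm(resid, "fro"))


def ols_standard_errors(data: LaggedData) -> np.ndarray:
    """Classical per-coefficient standard errors of the OLS fit.

    SE[i, j] = sigma_i * sqrt([(Z Z')^{-1}]_jj) with sigma_i the row-i
    residual standard deviation (degrees of freedom T-1-N).  Used to call
    coefficients statistically distinguishable from zero.
    """
    Y, Z = data.Y, data.Z
    n, m = Z.shape
    if m <= n + 1:
        raise InvalidInputError(
            f"need more than N+1 = {n + 1} lag pairs for standard errors, got {m}"
        )
    G = Z @ Z.T
    A = np.linalg.solve(G, Z @ Y.T).T
    resid = Y - A @ Z
    sigma2 = (resid**2).sum(axis=1) / (m - n)
    gjj = np.diag(np.linalg.inv(G))
    return np.sqrt(sigma2[:, None] * gjj[None, :])


def is_stable(A: np.ndarray, mode: str = "modulus", tol: float = 1e-7) -> StabilityReport:
    """Stability check for the coefficient matrix.

    mode "modulus": the VAR(1) stationarity condition, max |tau| < 1 - tol (all
    eigenvalues strictly inside the unit circle).  mode "halfplane": max
    Re[tau] <= tol, which is what the weighted-Gershgorin constraint of the
    inference program certifies.
    """
    A = np.asarray(A, dtype=float)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise InvalidInputError("stability check needs a square matrix")
    if tol <= 0:
        raise InvalidInputError("tol must be positive")
    eig = np.linalg.eigvals(A)
    if mode == "modulus":
        ok = bool(np.max(np.abs(eig)) < 1.0 - tol)
    elif mode == "halfplane":
        ok = bool(np.max(eig.real) <= tol)
    else:
        raise InvalidInputError(f"unknown stability mode {mode!r}")
    return StabilityReport(stable=ok, eigenvalues=eig, mode=mode, tol=tol)


def simulate_var(
    model: VARModel,
    T: int,
    y0="zero",
    seed: "int | None" = 0,
    burn_in: int = 0,
    noise_sd: "float | None" = None,
) -> ExpressionMatrix:
    """Simulate T observations of the VAR(1) recursion.

    Gaussian innovations are drawn from ``model.noise_cov`` when present,
    else from ``noise_sd**2 * I`` (``noise_sd=None`` means noise-free).
    ``burn_in`` extra initial steps are discarded; for burn_in > 0 the model
    should be modulus-stable or the trajectory may diverge (warned, not an
    error).  Same seed, same output.
    """
    if T < 3:
        raise InvalidInputError(f"simulation length must be >= 3, got {T}")
    n = model.n_genes
    if burn_in > 0 and not is_stable(model.A, "modulus").stable:
        warnings.warn(
            "simulating a burn-in with a modulus-unstable A; the trajectory "
            "may diverge",
            RuntimeWarning,
            stacklevel=2,
        )
    rng = np.random.default_rng(seed)
    if isinstance(y0, str) and y0 == "zero":
        y = np.zeros(n)
    else:
        y = np.asarray(y0, dtype=float).reshape(n)
    v = model.intercept if model.intercept is not None else np.zeros(n)
    cov = model.noise_cov
    if cov is None and noise_sd is not None and noise_sd > 0:
        cov = noise_sd**2 * np.eye(n)
    chol = None
    if cov is not None and np.any(cov):
        # eigendecomposition handles PSD (possibly singular) covariances
        w, Q = np.linalg.eigh(cov)
        chol = Q * np.sqrt(np.clip(w, 0.0, None))
    out = np.empty((n, T))
    for t in range(burn_in + T):
        if t > 0:
            y = v + model.A @ y
            if chol is not None:
                y = y + chol @ rng.standard_normal(n)
        elif chol is not None and burn_in > 0:
            # a noise kick at t=0 so burn-in starts off the fixed point
            y = y + chol @ rng.standard_normal(n)
        if t >= burn_in:
            out[:, t - burn_in] = y
    return ExpressionMatrix.from_array(out)
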