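"""Penalty selection by rolling one-step-ahead forecast error.

The observations are split three ways at T1 = floor(T/3) and
T2 = floor(2T/3): the first third initialises the rolling fits, the middle
third scores them, and the final third is reserved for an optional final
forecast evaluation.  For each window end t in {T1, ..., T2-1} the model is
fitted on observations 1..t and the forecast for t+1 is

    yhat_{t+1} = ybar_{1..t} + A_hat (y_t - ybar_{1..t}),

i.e. the fit is on row-centered data and the training-window means are
added back so forecasts live on the data scale.  The score is

    MSFE(lambda) = 1/(T2 - T1 - 1) * sum_{t=T1}^{T2-1} || yhat_{t+1} - y_{t+1} ||^2

(the sum runs over T2 - T1 window ends; the normaliser is kept exactly as
defined).  The budget with the smallest MSFE wins; ties break toward the
smaller (sparser) lambda.  Successive windows and successive grid values
warm-start the weight iteration — an efficiency device only, the converged
answers do not depend on it beyond the weight tolerance.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .expression import ExpressionMatrix, InvalidInputError
from .solver import SolverConfig, SolverError, _fit_centered
from .var import build_lagged_matrices

__all__ = ["LambdaSelection", "split_indices", "msfe", "select_lambda"]

DEFAULT_GRID = tuple(round(0.1 * k, 1) for k in range(11))

# inner-solver and weight-iteration tolerances used for the rolling
# scoring fits only (the final fit keeps the caller's tolerances)
_SCORING_TOL = 1e-6
_SCORING_WEIGHT_TOL = 1e-3


@dataclass(frozen=True)
class LambdaSelection:
    """Grid, per-budget forecast errors and the winning budget."""

    grid: tuple[float, ...]
    msfe: tuple[float, ...]
    best_lambda: float
    T1: int
    T2: int
    final_msfe: "float | None" = None

    def table(self) -> str:
        lines = ["lambda\tMSFE"]
        for lam, err in zip(self.grid, self.msfe):
            lines.append(f"{lam:g}\t{err:.6g}")
        lines.append(f"selected lambda = {self.best_lambda:g}")
        return "\n".join(lines)


def split_indices(T: int) -> "tuple[int, int]":
    """(T1, T2) = (floor(T/3), floor(2T/3)); requires T >= 9."""
    if T < 9:
        raise InvalidInputError(
            f"need at least 9 observations for the three-way split, got {T}"
        )
    return T // 3, (2 * T) // 3


def _rolling_sse(
    values: np.ndarray,
    lam: float,
    config: SolverConfig,
    t_start: int,
    t_stop: int,
    warm_in=None,
):
    """Sum of squared one-step forecast errors for window ends t_start..t_stop-1.

    Fits on observations 0..t-1 (the first t columns) and scores the
    forecast of column t (0-based).  Returns (sse, warm state of the first
    window) so a neighbouring budget can reuse the initialisation.
    """
    # scoring fits use a (relatively) loose inner tolerance: one-step
    # forecasts are insensitive below ~1e-6 and the rolling scan dominates
    # the selection cost; the final fit at the winning budget uses the
    # caller's full tolerance
    cfg = replace(config, lam=lam,
                  solver_tol=max(config.solver_tol, _SCORING_TOL),
                  weight_tol=max(config.weight_tol, _SCORING_WEIGHT_TOL))
    sse = 0.0
    warm = warm_in
    first_warm = None
    for t in range(t_start, t_stop):
        train = values[:, :t]
        means = train.mean(axis=1, keepdims=True)
        centered = train - means
        data = build_lagged_matrices(
            ExpressionMatrix.from_array(centered)
        )
        try:
            A, w, _, _, _, state = _fit_centered(data, cfg, warm=warm)
        except SolverError as exc:
            raise SolverError(f"rolling fit at window t={t} failed: {exc}") from exc
        warm = (state, w.v)
        if first_warm is None:
            first_warm = warm
        yhat = means[:, 0] + A @ (values[:, t - 1] - means[:, 0])
        err = yhat - values[:, t]
        sse += float(err @ err)
    return sse, first_warm


def msfe(expr: ExpressionMatrix, lam: float, config: SolverConfig) -> float:
    """Rolling one-step-ahead mean square forecast error at one budget."""
    T = expr.n_obs
    T1, T2 = split_indices(T)
    sse, _ = _rolling_sse(expr.values, lam, config, T1, T2)
    return sse / (T2 - T1 - 1)


def final_forecast_msfe(
    expr: ExpressionMatrix, lam: float, config: SolverConfig
) -> float:
    """Forecast error over the held-out final third (windows T2..T-1)."""
    T = expr.n_obs
    _, T2 = split_indices(T)
    sse, _ = _rolling_sse(expr.values, lam, config, T2, T)
    return sse / max(T - T2 - 1, 1)


def select_lambda(
    expr: ExpressionMatrix,
    grid=DEFAULT_GRID,
    config: "SolverConfig | None" = None,
    evaluate_final: bool = False,
) -> LambdaSelection:
    """Score every candidate budget and pick the MSFE minimiser.

    Ties break toward the smallest lambda (the sparser model).  The
    previous budget's first-window solution initialises the next budget's
    weight iteration.
    """
    grid = tuple(float(g) for g in grid)
    if len(grid) == 0:
        raise InvalidInputError("lambda grid must be nonempty")
    if any(g < 0 for g in grid):
        raise InvalidInputError("lambda grid values must be >= 0")
    if config is None:
        config = SolverConfig()
    T = expr.n_obs
    T1, T2 = split_indices(T)
    errs = []
    warm = None
    for lam in grid:
        sse, warm = _rolling_sse(expr.values, lam, config, T1, T2, warm_in=warm)
        errs.append(sse / (T2 - T1 - 1))
    best_i = min(range(len(grid)), key=lambda i: (errs[i], grid[i]))
    best = grid[best_i]
    final = None
    if evaluate_final:
        sse, _ = _rolling_sse(expr.values, best, config, T2, T)
        final = sse / max(T - T2 - 1, 1)
    return LambdaSelection(
        grid=grid,
        msfe=tuple(errs),
        best_lambda=best,
        T1=T1,
        T2=T2,
        final_msfe=final,
    )
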