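"""Weighted Gershgorin-disc machinery for the stability constraint.

Every eigenvalue of a square matrix A lies in a disc centred at a diagonal
entry a_ii with radius the deleted absolute row sum R_i(A).  Applying the
theorem to the diagonal similarity V^{-1} A V with V = diag(v_1..v_N),
v_i > 0, gives the bound Re[tau] <= a_ii + sum_{j != i} (v_j/v_i) |a_ij| for
every row; requiring all these row margins to be <= 0 therefore certifies
that every eigenvalue has non-positive real part while staying linear in
|a_ij| — a convex constraint.

The weights follow a fixed heuristic driven by each row's diagonal-dominance
margin m_i = |a_ii| - R_i(A) relative to the matrix-wide average beta:
dominant rows (m_i > beta) get v_i in (1, 2), which shrinks their own radius
contribution; weak rows get v_i in (0, 1].  delta in (0, 1] controls how
fast the weight saturates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .expression import InvalidInputError

__all__ = [
    "GershgorinWeights",
    "deleted_row_sum",
    "compute_beta",
    "compute_weights",
    "stability_margins",
]


@dataclass(frozen=True)
class GershgorinWeights:
    """Positive similarity-transform weights with their parameters."""

    v: np.ndarray = field(repr=False)
    delta: float = 0.5
    beta: float = 0.0

    def __post_init__(self) -> None:
        v = np.asarray(self.v, dtype=float).reshape(-1)
        if not (0.0 < self.delta <= 1.0):
            raise InvalidInputError(f"delta must be in (0, 1], got {self.delta}")
        if v.size == 0 or np.any(v <= 0) or not np.all(np.isfinite(v)):
            raise InvalidInputError("weights must be strictly positive and finite")
        object.__setattr__(self, "v", v)

    @property
    def n(self) -> int:
        return self.v.size

    @classmethod
    def unit(cls, n: int, delta: float = 0.5) -> "GershgorinWeights":
        """The canonical first-iteration state: all weights one."""
        return cls(v=np.ones(n), delta=delta, beta=0.0)


def _check_square(A: np.ndarray) -> np.ndarray:
    A = np.asarray(A, dtype=float)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise InvalidInputError("expected a square matrix")
    return A


def deleted_row_sum(A: np.ndarray, i: int) -> float:
    """R_i(A) = sum_{j != i} |a_ij| (zero for a 1x1 matrix)."""
    A = _check_square(A)
    n = A.shape[0]
    if not (0 <= i < n):
        raise InvalidInputError(f"row index {i} out of range for {n}x{n} matrix")
    return float(np.sum(np.abs(A[i])) - abs(A[i, i]))


def _margins_m(A: np.ndarray) -> np.ndarray:
    """Per-row diagonal-dominance margins m_i = |a_ii| - R_i(A)."""
    absA = np.abs(A)
    d = np.diag(absA)
    return 2.0 * d - absA.sum(axis=1)


def compute_beta(A: np.ndarray) -> float:
    """Average diagonal-dominance margin (may be negative)."""
    A = _check_square(A)
    return float(_margins_m(A).mean())


def compute_weights(A: np.ndarray, delta: float = 0.5) -> GershgorinWeights:
    """Weight schedule v_i(m_i; beta, delta).

    Rows with m_i > beta take v_i = 1 + (m_i - beta)/(delta + (m_i - beta));
    rows with m_i <= beta take v_i = delta/(delta - (m_i - beta)).  Equality
    goes to the second branch, where it gives v_i = 1, so the schedule is
    continuous at the junction.  Outputs lie in (0, 2).
    """
    A = _check_square(A)
    if not (0.0 < delta <= 1.0):
        raise InvalidInputError(f"delta must be in (0, 1], got {delta}")
    m = _margins_m(A)
    beta = float(m.mean())
    e = m - beta
    v = np.where(e > 0, 1.0 + e / (delta + e), delta / (delta - np.minimum(e, 0.0)))
    return GershgorinWeights(v=v, delta=delta, beta=beta)


def stability_margins(A: np.ndarray, weights: GershgorinWeights) -> np.ndarray:
    """Row margins g_i = a_ii + sum_{j != i} (v_j/v_i) |a_ij|.

    All g_i <= 0 certifies max Re[eig(A)] <= 0.
    """
    A = _check_square(A)
    v = weights.v
    if v.size != A.shape[0]:
        raise InvalidInputError(
            f"{v.size} weights for a {A.shape[0]}x{A.shape[0]} matrix"
        )
    absA = np.abs(A)
    W = v[None, :] / v[:, None]
    off = (W * absA).sum(axis=1) - np.diag(absA)  # W diagonal is 1
    return np.diag(A) + off
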