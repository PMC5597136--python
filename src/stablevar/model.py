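"""statsmodels-style front end: a model object fitted to expression data.

``StableLassoVAR`` holds the genes x observations matrix; ``fit`` runs the
constrained, weight-iterated estimation and returns a
``StableVARResults`` carrying the coefficient matrix, the Gershgorin
weights and margins, convergence diagnostics, a ``summary()`` table, and
network/forecast/simulation helpers.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .expression import ExpressionMatrix, InvalidInputError
from .network import SignedNetwork, extract_edges
from .selection import DEFAULT_GRID, LambdaSelection, select_lambda
from .solver import InferenceResult, SolverConfig, infer_network
from .var import StabilityReport, VARModel, is_stable, simulate_var

__all__ = ["StableLassoVAR", "StableVARResults"]


class StableLassoVAR:
    """Sparse stable VAR(1) model of a gene panel.

    Parameters
    ----------
    endog : ExpressionMatrix, DataFrame (genes x observations) or ndarray
        Expression levels in temporal/experimental order.
    gene_ids, obs_ids : optional labels when ``endog`` is a bare array.
    """

    def __init__(self, endog, gene_ids=None, obs_ids=None):
        if isinstance(endog, ExpressionMatrix):
            self.data = endog
        elif isinstance(endog, pd.DataFrame):
            self.data = ExpressionMatrix.from_dataframe(endog)
        else:
            self.data = ExpressionMatrix.from_array(
                np.asarray(endog, dtype=float), gene_ids, obs_ids
            )
        if self.data.n_genes < 2:
            raise InvalidInputError("network inference needs at least 2 genes")

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "StableLassoVAR":
        return cls(df)

    @classmethod
    def from_tsv(cls, path, dialect: str = "tsv") -> "StableLassoVAR":
        from .expression import read_expression

        return cls(read_expression(path, dialect))

    @property
    def gene_ids(self):
        return self.data.gene_ids

    @property
    def n_genes(self) -> int:
        return self.data.n_genes

    @property
    def n_obs(self) -> int:
        return self.data.n_obs

    def fit(self, lam: float = 1.0, delta: float = 0.5, **kwargs) -> "StableVARResults":
        """Fit at a fixed L1 budget; extra kwargs go to SolverConfig."""
        config = SolverConfig(lam=lam, delta=delta, **kwargs)
        return StableVARResults(self, infer_network(self.data, config))

    def fit_select(
        self,
        grid=DEFAULT_GRID,
        delta: float = 0.5,
        evaluate_final: bool = False,
        **kwargs,
    ) -> "StableVARResults":
        """Select the budget by rolling MSFE, then fit at the winner."""
        config = SolverConfig(delta=delta, **kwargs)
        sel = select_lambda(self.data, grid=grid, config=config,
                            evaluate_final=evaluate_final)
        res = self.fit(lam=sel.best_lambda, delta=delta, **kwargs)
        res.selection = sel
        return res


class StableVARResults:
    """Estimates, diagnostics and post-estimation tools of one fit."""

    def __init__(self, model: StableLassoVAR, result: InferenceResult):
        self.model = model
        self._result = result
        self.selection: "LambdaSelection | None" = None

    # estimation outcome -------------------------------------------------
    @property
    def A_hat(self) -> np.ndarray:
        return self._result.A_hat

    @property
    def params(self) -> pd.DataFrame:
        """Coefficients as a DataFrame; entry (i, j) is gene_j -> gene_i."""
        g = list(self.model.gene_ids)
        return pd.DataFrame(self.A_hat.copy(), index=g, columns=g)

    @property
    def weights(self):
        return self._result.weights

    @property
    def margins(self) -> np.ndarray:
        return self._result.margins

    @property
    def objective(self) -> float:
        return self._result.objective

    @property
    def outer_iters(self) -> int:
        return self._result.outer_iters

    @property
    def converged(self) -> bool:
        return self._result.converged

    @property
    def config(self) -> SolverConfig:
        return self._result.config

    @property
    def l1_norm(self) -> float:
        return self._result.l1_norm

    @property
    def eigenvalues(self) -> np.ndarray:
        return self._result.eigenvalues

    # post-estimation ----------------------------------------------------
    def stability(self, mode: str = "modulus") -> StabilityReport:
        return is_stable(self.A_hat, mode=mode)

    def network(self, threshold: "float | None" = None) -> SignedNetwork:
        if threshold is None:
            threshold = self.config.edge_threshold
        return extract_edges(self.A_hat, self.model.gene_ids, threshold)

    def forecast(self, steps: int = 1, y_last=None) -> np.ndarray:
        """One or more steps ahead on the data scale (means added back)."""
        mu = self._result.row_means
        y = self.model.data.values[:, -1] if y_last is None else np.asarray(y_last)
        out = np.empty((len(mu), steps))
        x = y - mu
        for k in range(steps):
            x = self.A_hat @ x
            out[:, k] = mu + x
        return out

    def simulate(self, T: int, seed: int = 0, noise_sd: float = 0.0,
                 burn_in: int = 0) -> ExpressionMatrix:
        fitted = VARModel(A=self.A_hat, intercept=self._result.row_means
                          - self.A_hat @ self._result.row_means)
        return simulate_var(fitted, T, y0=self.model.data.values[:, -1],
                            seed=seed, burn_in=burn_in, noise_sd=noise_sd)

    def summary(self) -> str:
        """Plain-text summary table of the fit."""
        r = self._result
        eig = r.eigenvalues
        net = self.network()
        lines = [
            "Sparse stable VAR(1) fit",
            "=" * 44,
            f"genes:                {self.model.n_genes}",
            f"observations:         {self.model.n_obs}",
            f"lambda (L1 budget):   {r.config.lam:g}",
            f"delta:                {r.config.delta:g}",
            f"objective 1/2||Y-AZ||^2: {r.objective:.6g}",
            f"||A||_1:              {r.l1_norm:.6g}",
            f"outer iterations:     {r.outer_iters}"
            f" ({'converged' if r.converged else 'not converged'})",
            f"max Gershgorin margin: {np.max(r.margins):.3g}",
            f"max |eigenvalue|:     {np.max(np.abs(eig)):.6g}",
            f"max Re eigenvalue:    {np.max(eig.real):.6g}",
            f"edges (|a| > {r.config.edge_threshold:g}): {net.n_edges}",
        ]
        if self.selection is not None:
            lines.append("-" * 44)
            lines.append(self.selection.table())
        return "\n".join(lines)

    def to_report(self) -> dict:
        """JSON-able run record (see io/report for the file form)."""
        r = self._result
        eig = r.eigenvalues
        rep = {
            "lambda": float(r.config.lam),
            "delta": float(r.config.delta),
            "objective": float(r.objective),
            "l1_norm": float(r.l1_norm),
            "outer_iters": int(r.outer_iters),
            "converged": bool(r.converged),
            "weights": [float(x) for x in r.weights.v],
            "beta": float(r.weights.beta),
            "margins": [float(x) for x in r.margins],
            "max_abs_eigenvalue": float(np.max(np.abs(eig))),
            "max_real_eigenvalue": float(np.max(eig.real)),
            "modulus_stable": bool(is_stable(self.A_hat, "modulus").stable),
            "halfplane_stable": bool(is_stable(self.A_hat, "halfplane").stable),
            "gene_ids": list(self.model.gene_ids),
        }
        if self.selection is not None:
            rep["lambda_grid"] = [float(g) for g in self.selection.grid]
            rep["msfe"] = [float(e) for e in self.selection.msfe]
            rep["best_lambda"] = float(self.selection.best_lambda)
            rep["T1"] = self.selection.T1
            rep["T2"] = self.selection.T2
        return rep
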