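"""Gene-expression matrices: the genes x ordered-observations container.

Columns are taken in order as the temporal (or perturbation-experiment)
ordering; rows are genes.  Values are expression levels or log-ratios,
unitless.  The file format is TSV (default) or CSV with the gene identifier
in the first column and observation labels in the header row.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["ExpressionMatrix", "center_rows", "read_expression", "write_expression"]


class InvalidInputError(ValueError):
    """Raised when an input violates a documented precondition."""


@dataclass(frozen=True)
class ExpressionMatrix:
    """N genes x T ordered observations of expression values.

    Parameters
    ----------
    gene_ids : sequence of str
        Unique gene identifiers, one per row.
    obs_ids : sequence of str
        Observation labels, one per column, in temporal/experimental order.
    values : ndarray, shape (N, T)
        Finite expression values.
    """

    gene_ids: tuple[str, ...]
    obs_ids: tuple[str, ...]
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "gene_ids", tuple(str(g) for g in self.gene_ids))
        object.__setattr__(self, "obs_ids", tuple(str(o) for o in self.obs_ids))
        vals = np.asarray(self.values, dtype=float)
        if vals.ndim != 2:
            raise InvalidInputError("expression values must be a 2-D matrix")
        object.__setattr__(self, "values", vals)
        n, t = vals.shape
        if n < 1:
            raise InvalidInputError("expression matrix needs at least one gene")
        if t < 3:
            raise InvalidInputError(
                f"expression matrix needs at least 3 observations, got {t}"
            )
        if len(self.gene_ids) != n:
            raise InvalidInputError(
                f"{len(self.gene_ids)} gene ids for {n} rows"
            )
        if len(self.obs_ids) != t:
            raise InvalidInputError(
                f"{len(self.obs_ids)} observation ids for {t} columns"
            )
        dupes = _duplicates(self.gene_ids)
        if dupes:
            raise InvalidInputError(f"duplicate gene ids: {sorted(dupes)}")
        if not np.all(np.isfinite(vals)):
            i, j = np.argwhere(~np.isfinite(vals))[0]
            raise InvalidInputError(
                f"non-finite value at gene {self.gene_ids[i]!r}, "
                f"observation {self.obs_ids[j]!r}"
            )

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_obs(self) -> int:
        return self.values.shape[1]

    @classmethod
    def from_array(
        cls,
        values: np.ndarray,
        gene_ids: "list[str] | None" = None,
        obs_ids: "list[str] | None" = None,
    ) -> "ExpressionMatrix":
        values = np.asarray(values, dtype=float)
        n, t = values.shape
        if gene_ids is None:
            gene_ids = [f"g{i + 1}" for i in range(n)]
        if obs_ids is None:
            obs_ids = [f"t{j + 1}" for j in range(t)]
        return cls(tuple(gene_ids), tuple(obs_ids), values)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "ExpressionMatrix":
        """Build from a genes-as-index, observations-as-columns DataFrame."""
        return cls(
            tuple(str(i) for i in df.index),
            tuple(str(c) for c in df.columns),
            df.to_numpy(dtype=float),
        )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values.copy(), index=list(self.gene_ids), columns=list(self.obs_ids)
        )

    def row_means(self) -> np.ndarray:
        return self.values.mean(axis=1)


def _duplicates(items) -> set:
    seen: set = set()
    dup: set = set()
    for x in items:
        (dup if x in seen else seen).add(x)
    return dup


def center_rows(expr: ExpressionMatrix) -> ExpressionMatrix:
    """Subtract each gene's mean so every row has mean zero.

    Centering stands in for the intercept term: the constrained fit carries
    no intercept, so each gene's series is centered before the lag
    regression and the mean is added back when forecasting.
    """
    centered = expr.values - expr.values.mean(axis=1, keepdims=True)
    return ExpressionMatrix(expr.gene_ids, expr.obs_ids, centered)


def read_expression(path, dialect: str = "tsv") -> ExpressionMatrix:
    """Read an expression matrix from a TSV/CSV file.

    First column holds gene identifiers, header row holds observation
    labels.  Duplicate gene ids, non-numeric cells and ragged rows are
    rejected with coordinates in the message.
    """
    if dialect not in ("tsv", "csv"):
        raise InvalidInputError(f"unknown dialect {dialect!r} (use 'tsv' or 'csv')")
    sep = "\t" if dialect == "tsv" else ","
    try:
        # round_trip parsing: written matrices must reload bit-identical so
        # constraint checks on re-loaded artifacts still hold
        df = pd.read_csv(path, sep=sep, index_col=0, float_precision="round_trip")
    except pd.errors.EmptyDataError as exc:
        raise InvalidInputError(f"empty expression file: {path}") from exc
    if df.shape[0] == 0 or df.shape[1] == 0:
        raise InvalidInputError(f"empty expression matrix in {path}")
    dupes = _duplicates([str(i) for i in df.index])
    if dupes:
        raise InvalidInputError(
            f"duplicate gene ids in {path}: {sorted(dupes)}"
        )
    bad = df.apply(pd.to_numeric, errors="coerce")
    if bad.isna().to_numpy().any() and not df.isna().to_numpy().any():
        i, j = np.argwhere(bad.isna().to_numpy())[0]
        raise InvalidInputError(
            f"non-numeric cell at gene {df.index[i]!r}, column {df.columns[j]!r}"
        )
    if df.isna().to_numpy().any():
        i, j = np.argwhere(df.isna().to_numpy())[0]
        raise InvalidInputError(
            f"missing value at gene {df.index[i]!r}, column {df.columns[j]!r}"
        )
    return ExpressionMatrix.from_dataframe(bad)


def write_expression(expr: ExpressionMatrix, path, dialect: str = "tsv") -> None:
    """Write with full double precision so a round-trip is exact."""
    if dialect not in ("tsv", "csv"):
        raise InvalidInputError(f"unknown dialect {dialect!r} (use 'tsv' or 'csv')")
    sep = "\t" if dialect == "tsv" else ","
    expr.to_dataframe().to_csv(path, sep=sep, float_format="%.17g")
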