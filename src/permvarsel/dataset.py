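"""Container for a numeric regression sample.

A :class:`Dataset` bundles an ``n x p`` covariate matrix ``X``, a response
vector ``y`` of length ``n`` and the ``p`` covariate names.  It is the single
currency every other module (regression backends, importance, selection,
model choice) trades in.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = ["Dataset", "read_csv", "write_csv"]


@dataclass(frozen=True)
class Dataset:
    """An ``n x p`` covariate matrix with its response vector.

    Parameters
    ----------
    X : ndarray of shape (n, p)
        Covariate matrix; rows are observations.
    y : ndarray of shape (n,)
        Response vector.
    names : sequence of str
        The ``p`` covariate labels, unique.
    """

    X: np.ndarray
    y: np.ndarray
    names: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        X = np.asarray(self.X, dtype=float)
        y = np.asarray(self.y, dtype=float).ravel()
        if X.ndim != 2:
            raise ValueError("X must be a 2-d matrix")
        n, p = X.shape
        if n < 2 or p < 1:
            raise ValueError(f"need n >= 2 and p >= 1, got n={n}, p={p}")
        if y.shape[0] != n:
            raise ValueError(f"y has length {y.shape[0]}, expected {n}")
        if not np.all(np.isfinite(X)):
            raise ValueError("X contains non-finite values")
        if not np.all(np.isfinite(y)):
            raise ValueError("y contains non-finite values")
        names = tuple(self.names) if self.names else tuple(f"X{j + 1}" for j in range(p))
        if len(names) != p:
            raise ValueError(f"{len(names)} names for {p} covariates")
        if len(set(names)) != p:
            raise ValueError("covariate names must be unique")
        object.__setattr__(self, "X", X)
        object.__setattr__(self, "y", y)
        object.__setattr__(self, "names", names)

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def p(self) -> int:
        return self.X.shape[1]

    def subset_rows(self, idx: np.ndarray) -> "Dataset":
        """Dataset restricted to the given row indices (order preserved)."""
        idx = np.asarray(idx)
        return Dataset(self.X[idx], self.y[idx], self.names)

    def subset_columns(self, cols: Sequence[int]) -> "Dataset":
        """Dataset restricted to the given covariate indices."""
        cols = list(cols)
        return Dataset(self.X[:, cols], self.y, tuple(self.names[j] for j in cols))

    def with_permuted_column(self, j: int, perm: np.ndarray) -> "Dataset":
        """Copy of the dataset with the rows of covariate ``j`` permuted."""
        X = self.X.copy()
        X[:, j] = X[perm, j]
        return Dataset(X, self.y, self.names)

    def to_frame(self, response: str = "y") -> pd.DataFrame:
        df = pd.DataFrame(self.X, columns=list(self.names))
        df[response] = self.y
        return df


def read_csv(path: str | Path, response: str = "y") -> Dataset:
    """Load a Dataset from a comma-separated file with a header row.

    Every column except ``response`` is treated as a covariate.  Raises a
    descriptive error when the response column is missing or a cell is not
    numeric.
    """
    df = pd.read_csv(path)
    if response not in df.columns:
        raise ValueError(
            f"response column {response!r} not found in {path}; "
            f"available columns: {list(df.columns)}"
        )
    covs = df.drop(columns=[response])
    bad = covs.columns[covs.apply(lambda c: not np.issubdtype(c.dtype, np.number))]
    if len(bad):
        raise ValueError(f"non-numeric covariate columns in {path}: {list(bad)}")
    if not np.issubdtype(df[response].dtype, np.number):
        raise ValueError(f"response column {response!r} in {path} is not numeric")
    if df.isna().any().any():
        rows = df.index[df.isna().any(axis=1)].tolist()[:5]
        raise ValueError(f"missing values in {path} (first rows: {rows})")
    return Dataset(covs.to_numpy(float), df[response].to_numpy(float), tuple(covs.columns))


def write_csv(data: Dataset, path: str | Path, response: str = "y") -> None:
    data.to_frame(response).to_csv(path, index=False)
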