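"""Regression backends behind one uniform fit/predict contract.

Three estimators of the regression function ``E[Y | X]`` are provided:

``linreg``
    Multiple linear regression fitted by ordinary least squares.
``sir``
    A semiparametric single-index model ``Y = f(X' beta) + eps``: the index
    direction ``beta`` is estimated by sliced inverse regression (SIR) and
    the unknown link ``f`` by Nadaraya-Watson kernel smoothing of the
    responses against the estimated index.
``rf``
    A nonparametric random-forest regression (averaged regression trees),
    delegated to scikit-learn.

Every backend satisfies the :class:`Regressor` contract — ``fit(Dataset)``
then ``predict(X)`` — which is all the importance and model-choice engines
require, so user-defined regressors plug in the same way.
"""

from __future__ import annotations

import copy
import logging
import warnings
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from sklearn.ensemble import RandomForestRegressor

from .dataset import Dataset

__all__ = [
    "Regressor",
    "LinearRegressor",
    "SIRRegressor",
    "ForestRegressor",
    "sir_direction",
    "sir_eigenvalues",
    "kernel_smooth",
    "make_regressor",
    "REGRESSOR_KINDS",
]

logger = logging.getLogger(__name__)


class Regressor:
    """Fit/predict contract shared by all regression backends.

    Subclasses implement ``_fit(data)`` and ``_predict(X)``; ``predict``
    refuses to run before ``fit``.  ``clone()`` returns an unfitted copy
    with the same hyperparameters, which is how the permutation-importance
    loop refits the model on perturbed samples.
    """

    kind: str = "abstract"

    def __init__(self) -> None:
        self._fitted = False

    def fit(self, data: Dataset) -> "Regressor":
        self._fit(data)
        self._fitted = True
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        if not self._fitted:
            raise RuntimeError(f"{self.kind} regressor must be fitted before predict")
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return self._predict(X)

    def clone(self) -> "Regressor":
        new = copy.deepcopy(self)
        new._reset()
        new._fitted = False
        return new

    def _reset(self) -> None:  # drop fitted state; overridden where needed
        pass

    def _fit(self, data: Dataset) -> None:
        raise NotImplementedError

    def _predict(self, X: np.ndarray) -> np.ndarray:
        raise NotImplementedError


# ---------------------------------------------------------------------------
# multiple linear regression


class LinearRegressor(Regressor):
    """Multiple linear regression fitted by ordinary least squares.

    Predictions are ``b0 + X @ b`` with ``(b0, b)`` the least-squares
    solution.  A rank-deficient design falls back to the minimum-norm
    (pseudo-inverse) solution with a logged warning, so degenerate permuted
    resamples inside Monte-Carlo loops never crash the run.
    """

    kind = "linreg"

    def __init__(self) -> None:
        super().__init__()
        self.intercept_: float | None = None
        self.coef_: np.ndarray | None = None

    def _reset(self) -> None:
        self.intercept_ = None
        self.coef_ = None

    def _fit(self, data: Dataset) -> None:
        n, p = data.n, data.p
        if n <= p + 1:
            raise ValueError(
                f"underdetermined: n={n} observations for p={p} covariates "
                "(need n > p + 1)"
            )
        design = np.column_stack([np.ones(n), data.X])
        beta, _, rank, _ = np.linalg.lstsq(design, data.y, rcond=None)
        if rank < p + 1:
            logger.warning(
                "rank-deficient design (rank %d < %d); using minimum-norm solution",
                rank,
                p + 1,
            )
        self.intercept_ = float(beta[0])
        self.coef_ = beta[1:]

    def _predict(self, X: np.ndarray) -> np.ndarray:
        return self.intercept_ + X @ self.coef_


def fit_linreg(data: Dataset) -> LinearRegressor:
    """Convenience wrapper: OLS fit of ``data``."""
    return LinearRegressor().fit(data)


# ---------------------------------------------------------------------------
# sliced inverse regression + kernel link


def _slice_mean_cov(data: Dataset, n_slices: int) -> tuple[np.ndarray, np.ndarray]:
    """Whitened slice-mean covariance matrix and the whitening map.

    Returns ``(M, inv_sqrt)`` where ``M`` is the slice-proportion-weighted
    covariance of the slice means of the whitened covariates and
    ``inv_sqrt`` is the inverse square root of the covariate covariance.
    """
    X, y = data.X, data.y
    n, p = X.shape
    if n_slices < 2:
        raise ValueError("need at least 2 slices")
    if n < 2 * n_slices:
        raise ValueError(f"need n >= 2*n_slices, got n={n}, n_slices={n_slices}")
    mu = X.mean(axis=0)
    Xc = X - mu
    cov = Xc.T @ Xc / n
    evals, evecs = np.linalg.eigh(cov)
    floor = 1e-10 * max(evals.max(), 1.0)
    if evals.min() <= floor:
        logger.warning("near-singular covariate covariance; ridge-regularizing")
        evals = evals + floor
    inv_sqrt = evecs @ np.diag(evals**-0.5) @ evecs.T
    Z = Xc @ inv_sqrt

    # slice by the ranks of y: near-equal slice sizes, never empty, and ties
    # in y simply share a slice (the rank split plays the merge role)
    order = np.argsort(y, kind="stable")
    slices = np.array_split(order, n_slices)
    M = np.zeros((p, p))
    for idx in slices:
        if len(idx) == 0:  # defensive; array_split of n >= 2H cannot yield empties
            continue
        zbar = Z[idx].mean(axis=0)
        M += (len(idx) / n) * np.outer(zbar, zbar)
    return M, inv_sqrt


def sir_eigenvalues(data: Dataset, n_slices: int = 10) -> np.ndarray:
    """Eigenvalues of the whitened slice-mean covariance, ascending.

    Under independence of ``y`` and ``X`` no direction dominates: the top
    eigenvalue stays comparable to the rest, which makes this spectrum a
    useful diagnostic for whether a single-index structure is present.
    """
    M, _ = _slice_mean_cov(data, n_slices)
    return np.linalg.eigvalsh(M)


def sir_direction(data: Dataset, n_slices: int = 10) -> np.ndarray:
    """First sliced-inverse-regression direction of a single-index model.

    The covariates are whitened with the inverse square root of their sample
    covariance, the observations are partitioned into ``n_slices`` slices of
    near-equal size by the ranks of ``y``, and the direction is the top
    eigenvector of the slice-proportion-weighted covariance of the slice
    means of the whitened covariates, mapped back through the whitening.

    Returns a unit vector of length ``p`` whose largest-magnitude coordinate
    is positive (a deterministic sign convention; SIR only identifies the
    direction up to sign).
    """
    if data.p == 1:
        if data.n < 2 * n_slices:
            raise ValueError(
                f"need n >= 2*n_slices, got n={data.n}, n_slices={n_slices}"
            )
        return np.ones(1)
    M, inv_sqrt = _slice_mean_cov(data, n_slices)
    w, v = np.linalg.eigh(M)
    eta = v[:, -1]
    beta = inv_sqrt @ eta
    beta = beta / np.linalg.norm(beta)
    if beta[np.argmax(np.abs(beta))] < 0:
        beta = -beta
    return beta


def kernel_smooth(
    index_train: np.ndarray,
    y_train: np.ndarray,
    index_query: np.ndarray,
    bandwidth: float,
) -> np.ndarray:
    """Nadaraya-Watson estimate with a Gaussian kernel.

    ``yhat(q) = sum_i K((q - t_i)/h) y_i / sum_i K((q - t_i)/h)`` with
    ``K`` the standard normal density.  Kernel weights are normalized in
    log space, so a query far outside the training range degrades smoothly
    to the response of its nearest training point rather than dividing by
    an underflowed mass; a genuinely zero mass (degenerate bandwidth) hits
    an explicit nearest-neighbor fallback.
    """
    t = np.asarray(index_train, dtype=float).ravel()
    y = np.asarray(y_train, dtype=float).ravel()
    q = np.atleast_1d(np.asarray(index_query, dtype=float))
    if t.shape[0] != y.shape[0] or t.shape[0] < 1:
        raise ValueError("index_train and y_train must have equal length >= 1")
    if not bandwidth > 0:
        raise ValueError("bandwidth must be positive")
    if t.shape[0] == 1:
        return np.full(q.shape, y[0])

    logw = -0.5 * ((q[:, None] - t[None, :]) / bandwidth) ** 2
    logw -= logw.max(axis=1, keepdims=True)  # per-query shift: max weight = 1
    w = np.exp(logw)
    mass = w.sum(axis=1)
    out = np.empty(q.shape)
    ok = mass > 0
    out[ok] = (w[ok] @ y) / mass[ok]
    if not ok.all():
        logger.warning(
            "zero kernel mass at %d queries; nearest-neighbor fallback", (~ok).sum()
        )
        nearest = np.abs(q[~ok, None] - t[None, :]).argmin(axis=1)
        out[~ok] = y[nearest]
    return out


def rule_of_thumb_bandwidth(index: np.ndarray) -> float:
    """Silverman-style rule of thumb ``h = 1.06 sd(t) m^(-1/5)``."""
    m = len(index)
    sd = float(np.std(index))
    if sd == 0.0:
        return 1.0  # degenerate index; any bandwidth averages the responses
    return 1.06 * sd * m ** (-1 / 5)


class SIRRegressor(Regressor):
    """Single-index model: SIR direction + Nadaraya-Watson kernel link.

    Parameters
    ----------
    n_slices : int
        Number of SIR slices (default 10 slices of near-equal size).
    bandwidth : float or None
        Gaussian kernel bandwidth for the link estimate; ``None`` applies
        the rule of thumb ``1.06 sd(index) m^(-1/5)`` on the training index.
    """

    kind = "sir"

    def __init__(self, n_slices: int = 10, bandwidth: float | None = None) -> None:
        super().__init__()
        self.n_slices = n_slices
        self.bandwidth = bandwidth
        self.direction_: np.ndarray | None = None
        self.index_train_: np.ndarray | None = None
        self.y_train_: np.ndarray | None = None
        self.bandwidth_: float | None = None

    def _reset(self) -> None:
        self.direction_ = None
        self.index_train_ = None
        self.y_train_ = None
        self.bandwidth_ = None

    def _fit(self, data: Dataset) -> None:
        self.direction_ = sir_direction(data, n_slices=self.n_slices)
        self.index_train_ = data.X @ self.direction_
        self.y_train_ = data.y.copy()
        self.bandwidth_ = (
            self.bandwidth
            if self.bandwidth is not None
            else rule_of_thumb_bandwidth(self.index_train_)
        )

    def _predict(self, X: np.ndarray) -> np.ndarray:
        return kernel_smooth(
            self.index_train_, self.y_train_, X @ self.direction_, self.bandwidth_
        )


def fit_sir(
    data: Dataset, n_slices: int = 10, bandwidth: float | None = None
) -> SIRRegressor:
    """Convenience wrapper: two-step single-index fit (SIR then kernel link)."""
    return SIRRegressor(n_slices=n_slices, bandwidth=bandwidth).fit(data)


# ---------------------------------------------------------------------------
# random forest


class ForestRegressor(Regressor):
    """Random-forest regression behind the common contract.

    Delegates to :class:`sklearn.ensemble.RandomForestRegressor` with
    regression defaults: 500 trees and one third of the covariates tried at
    each split.  The seed makes repeated fits on the same data identical.
    """

    kind = "rf"

    def __init__(self, n_trees: int = 500, seed: int = 0) -> None:
        super().__init__()
        self.n_trees = n_trees
        self.seed = seed
        self.forest_: RandomForestRegressor | None = None

    def _reset(self) -> None:
        self.forest_ = None

    def _fit(self, data: Dataset) -> None:
        if data.n < 5:
            raise ValueError(f"need n >= 5 for a forest, got n={data.n}")
        self.forest_ = RandomForestRegressor(
            n_estimators=self.n_trees,
            max_features=1 / 3,
            random_state=self.seed,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            self.forest_.fit(data.X, data.y)

    def _predict(self, X: np.ndarray) -> np.ndarray:
        return self.forest_.predict(X)


def fit_rf(data: Dataset, n_trees: int = 500, seed: int = 0) -> ForestRegressor:
    """Convenience wrapper: random-forest fit of ``data``."""
    return ForestRegressor(n_trees=n_trees, seed=seed).fit(data)


# ---------------------------------------------------------------------------
# registry

_FACTORIES: dict[str, Callable[..., Regressor]] = {
    "linreg": LinearRegressor,
    "sir": SIRRegressor,
    "rf": ForestRegressor,
}

REGRESSOR_KINDS = tuple(_FACTORIES)


def make_regressor(kind: str, **hyperparams) -> Regressor:
    """Build an unfitted regressor by name (``linreg``, ``sir`` or ``rf``)."""
    try:
        factory = _FACTORIES[kind]
    except KeyError:
        raise ValueError(
            f"unknown regression method {kind!r}; valid methods: {sorted(_FACTORIES)}"
        ) from None
    return factory(**hyperparams)
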