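"""Synthetic regression datasets for the simulation study and smoke tests.

Two study models share one design: ``p = 15`` covariates drawn iid uniform
on ``[0, 0.7]``, standard normal noise, and the coefficient vector
``beta = (4, 4, -3, -3, -2, 0, ..., 0)'`` so that only the first five
covariates carry signal.

* ``M1`` (linear):   ``Y = X' beta + eps``
* ``M2`` (cubic):    ``Y = (X' beta)^3 + eps``

M1 favors multiple linear regression; M2 keeps the single-index structure
but breaks linearity, so a single-index (SIR + kernel) fit should win while
a linear fit misspecifies the link.

A third generator emulates a meat-science application: ``n = 71`` animals,
``p = 21`` protein biomarkers of beef tenderness with moderate exchangeable
correlation (co-regulated protein abundances), 6 active biomarkers with
mixed-sign effects and noise calibrated so the linear signal explains about
40% of the response variance.  The real covariance of those biomarkers is
unpublished, so this fixture is a synthetic stand-in for smoke tests only.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .dataset import Dataset

__all__ = [
    "SimulationConfig",
    "BIOMARKER_NAMES",
    "simulate_m1",
    "simulate_m2",
    "simulate_fixture",
    "default_beta",
]

#: the 21 muscle-protein tenderness biomarkers used as fixture column names
BIOMARKER_NAMES: tuple[str, ...] = (
    "MDH1",
    "ENO3",
    "LDHB",
    "CRYAB",
    "HSP20",
    "HSP27",
    "HSP40",
    "HSP70-1A/B",
    "HSP70-Grp75",
    "HSP70-8",
    "DJ-1",
    "Prdx6",
    "SOD1",
    "alpha-actinin-2",
    "MLC-1F",
    "MyHC-I",
    "MyHC-II",
    "MyHC-IIx",
    "CAPZB",
    "MyBP-H",
    "mu-calpain",
)


def default_beta(p: int = 15) -> np.ndarray:
    """Study coefficients ``(4, 4, -3, -3, -2, 0, ..., 0)`` padded to length p."""
    if p < 5:
        raise ValueError("need p >= 5 for the default coefficient vector")
    beta = np.zeros(p)
    beta[:5] = [4.0, 4.0, -3.0, -3.0, -2.0]
    return beta


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of a simulated regression sample.

    Defaults reproduce the study design: ``n=200``, ``p=15``, covariates
    iid uniform on ``[0, 0.7]``, standard normal noise, coefficients
    ``(4, 4, -3, -3, -2, 0, ..., 0)``.
    """

    model: str = "M1"
    n: int = 200
    p: int = 15
    beta: tuple[float, ...] | None = None
    #: noise standard deviation; None lets the fixture calibrate it to its
    #: R^2 target (M1/M2 treat None as the standard normal default)
    noise_sd: float | None = 1.0
    covariate_range: tuple[float, float] = (0.0, 0.7)
    seed: int = 0

    def resolved_beta(self) -> np.ndarray:
        if self.beta is None:
            return default_beta(self.p)
        beta = np.asarray(self.beta, dtype=float)
        if beta.shape[0] != self.p:
            raise ValueError(f"beta has length {beta.shape[0]}, expected p={self.p}")
        return beta

    def to_manifest(self) -> dict:
        d = asdict(self)
        d["beta"] = self.resolved_beta().tolist()
        return d

    def write_manifest(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_manifest(), indent=2))


def _draw_index(config: SimulationConfig) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    rng = np.random.default_rng(config.seed)
    lo, hi = config.covariate_range
    X = rng.uniform(lo, hi, size=(config.n, config.p))
    sd = 1.0 if config.noise_sd is None else config.noise_sd
    eps = rng.normal(0.0, sd, size=config.n) if sd > 0 else np.zeros(config.n)
    index = X @ config.resolved_beta()
    return X, index, eps


def simulate_m1(config: SimulationConfig | None = None, **overrides) -> Dataset:
    """Linear model ``Y = X' beta + eps``; pure function of (config, seed)."""
    config = _resolve(config, "M1", overrides)
    X, index, eps = _draw_index(config)
    return Dataset(X, index + eps)


def simulate_m2(config: SimulationConfig | None = None, **overrides) -> Dataset:
    """Cubic single-index model ``Y = (X' beta)^3 + eps``."""
    config = _resolve(config, "M2", overrides)
    X, index, eps = _draw_index(config)
    return Dataset(X, index**3 + eps)


#: fixture effect sizes: 6 active biomarkers, mixed signs
_FIXTURE_ACTIVE = {
    "HSP70-1A/B": -1.0,
    "ENO3": 0.8,
    "LDHB": 0.8,
    "SOD1": -0.6,
    "CRYAB": 0.6,
    "HSP20": -0.5,
}
_FIXTURE_RHO = 0.3
_FIXTURE_R2 = 0.4


def simulate_fixture(config: SimulationConfig | None = None, **overrides) -> Dataset:
    """Biomarker-like sample: n=71, p=21, correlated covariates, R^2 ~ 0.4.

    Covariates are multivariate normal with unit variances and exchangeable
    correlation 0.3; six biomarkers act linearly with mixed signs and the
    noise standard deviation solves ``R^2 = var(signal)/(var(signal)+sd^2)``
    for the 0.4 target.  Synthetic by construction — the real biomarker
    covariance is not public.
    """
    if config is None:
        kw = {"model": "fixture", "n": 71, "p": 21, "noise_sd": None}
        kw.update(overrides)
        config = SimulationConfig(**kw)
    elif overrides:
        raise TypeError("pass either a config or keyword overrides, not both")
    if config.p != len(BIOMARKER_NAMES):
        raise ValueError(f"fixture requires p={len(BIOMARKER_NAMES)}")
    rng = np.random.default_rng(config.seed)
    p = config.p
    cov = np.full((p, p), _FIXTURE_RHO)
    np.fill_diagonal(cov, 1.0)
    X = rng.multivariate_normal(np.zeros(p), cov, size=config.n, method="cholesky")
    beta = np.zeros(p)
    for name, b in _FIXTURE_ACTIVE.items():
        beta[BIOMARKER_NAMES.index(name)] = b
    signal_var = float(beta @ cov @ beta)
    noise_sd = config.noise_sd
    if noise_sd is None:  # calibrate to the population R^2 target
        noise_sd = float(np.sqrt(signal_var * (1.0 - _FIXTURE_R2) / _FIXTURE_R2))
    y = X @ beta + (
        rng.normal(0.0, noise_sd, size=config.n) if noise_sd > 0 else 0.0
    )
    return Dataset(X, y, BIOMARKER_NAMES)


def _resolve(
    config: SimulationConfig | None, model: str, overrides: dict
) -> SimulationConfig:
    if config is None:
        config = SimulationConfig(model=model, **overrides)
    elif overrides:
        raise TypeError("pass either a config or keyword overrides, not both")
    return config
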