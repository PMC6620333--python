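"""Repeated train/test comparison of regression methods with selection.

The engine answers "which regression method, including its covariate
selection, predicts best on held-out data?".  For each of ``M`` random
80/20-style splits it

1. computes the permute-and-refit variable importance on the TRAIN rows
   only,
2. selects covariates by the configured rule (change point, baseline MSE
   threshold, or no selection),
3. refits the method on the train rows restricted to the selected
   covariates, and
4. scores the fitted model on the held-out test rows by

       MSE_test = (1/n_test) * sum_{i in test} (y_i - yhat_i)^2 .

Every method sees the SAME ``M`` splits (a paired comparison), and all
randomness descends from one master seed through a counter-based spawning
scheme, so a run is reproducible bit for bit.  The summaries mirror the
standard graphics: MSE_test boxplots per method, model-size distributions,
and per-covariate occurrence frequencies across the ``M`` final models.
"""

from __future__ import annotations

import json
import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .dataset import Dataset
from .importance import variable_importance
from .regressors import Regressor, make_regressor
from .selection import SelectionResult, select_by_baseline, select_by_changepoint

__all__ = ["ChoiceReplicate", "ChoiceSummary", "split_sample", "mse_test", "choicemod"]

logger = logging.getLogger(__name__)

SELECTION_RULES = ("changepoint", "baseline", "none")


def split_sample(
    n: int,
    train_frac: float = 0.8,
    seed: int | np.random.Generator | np.random.SeedSequence = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Uniform random partition of ``1..n`` into train and test indices.

    The test set holds ``round((1 - train_frac) * n)`` observations; train
    and test are disjoint and exhaustive.
    """
    if not 0.0 < train_frac < 1.0:
        raise ValueError("train_frac must be in (0, 1)")
    n_test = int(round((1.0 - train_frac) * n))
    if n_test < 1 or n - n_test < 2:
        raise ValueError(
            f"degenerate split: n={n}, train_frac={train_frac} gives "
            f"{n - n_test} train / {n_test} test observations"
        )
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    return np.sort(perm[n_test:]), np.sort(perm[:n_test])


def mse_test(y_held_out: np.ndarray, predictions: np.ndarray) -> float:
    """Mean squared prediction error on a held-out sample."""
    y = np.asarray(y_held_out, dtype=float).ravel()
    yhat = np.asarray(predictions, dtype=float).ravel()
    if y.shape != yhat.shape or y.size < 1:
        raise ValueError(
            f"length mismatch: {y.size} responses vs {yhat.size} predictions"
        )
    return float(np.mean((y - yhat) ** 2))


@dataclass(frozen=True)
class ChoiceReplicate:
    """One train/test split with each method's selection and test error."""

    split_id: int
    train_idx: np.ndarray
    test_idx: np.ndarray
    #: method name -> record with keys selected, size, mse_test, no_change
    records: dict = field(default_factory=dict)


@dataclass(frozen=True)
class ChoiceSummary:
    """Aggregate of ``M`` train/test replications for several methods."""

    methods: tuple[str, ...]
    names: tuple[str, ...]
    mse_matrix: np.ndarray  # M x n_methods, NaN where a method failed
    replicates: tuple[ChoiceReplicate, ...]
    config: dict

    @property
    def M(self) -> int:
        return self.mse_matrix.shape[0]

    def mse_frame(self) -> pd.DataFrame:
        """M x methods table of held-out MSEs (rows = splits)."""
        return pd.DataFrame(self.mse_matrix, columns=list(self.methods))

    def median_mse(self) -> dict[str, float]:
        """Per-method median MSE_test over the non-missing replicates."""
        return {
            m: float(np.nanmedian(self.mse_matrix[:, k]))
            for k, m in enumerate(self.methods)
        }

    def size_distribution(self) -> dict[str, Counter]:
        """Per method, frequency table of selected-model sizes over M splits."""
        out: dict[str, Counter] = {}
        for m in self.methods:
            out[m] = Counter(
                rep.records[m]["size"] for rep in self.replicates if m in rep.records
            )
        return out

    def occurrence(self) -> pd.DataFrame:
        """Per-covariate selection proportion (rows) for each method (cols)."""
        mat = np.zeros((len(self.names), len(self.methods)))
        for k, m in enumerate(self.methods):
            count = sum(1 for rep in self.replicates if m in rep.records)
            for rep in self.replicates:
                if m in rep.records:
                    for j in rep.records[m]["selected"]:
                        mat[j, k] += 1
            mat[:, k] /= max(count, 1)
        return pd.DataFrame(mat, index=list(self.names), columns=list(self.methods))

    def size_frame(self) -> pd.DataFrame:
        sizes = range(1, len(self.names) + 1)
        dist = self.size_distribution()
        return pd.DataFrame(
            {m: [dist[m].get(s, 0) for s in sizes] for m in self.methods},
            index=list(sizes),
        )

    def write(self, directory: str | Path) -> None:
        """Write the MSE, occurrence and size-distribution CSVs + manifest."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.mse_frame().to_csv(directory / "mse_test.csv", index=False)
        self.occurrence().to_csv(directory / "occurrence.csv", index_label="covariate")
        self.size_frame().to_csv(directory / "size_distribution.csv", index_label="size")
        (directory / "manifest.json").write_text(json.dumps(self.config, indent=2))


def _select(imp, rule: str) -> SelectionResult:
    if rule == "changepoint":
        return select_by_changepoint(imp)
    if rule == "baseline":
        return select_by_baseline(imp)
    raise ValueError(f"unknown selection rule {rule!r}; valid: {SELECTION_RULES}")


def choicemod(
    data: Dataset,
    methods: Sequence[str] | Mapping[str, Regressor] = ("linreg", "sir", "rf"),
    M: int = 50,
    train_frac: float = 0.8,
    selection_rule: str = "changepoint",
    vi_reps: int = 50,
    seed: int = 0,
    predict_on: str = "permuted",
) -> ChoiceSummary:
    """Repeated train/test comparison of regression methods.

    Parameters
    ----------
    methods : sequence of method names, or mapping name -> Regressor
        Names are resolved through :func:`make_regressor` with default
        hyperparameters; pass a mapping to control them.
    M : int
        Number of train/test replications.
    selection_rule : {"changepoint", "baseline", "none"}
        Covariate-selection rule applied to the train-sample importances;
        ``"none"`` fits every method on all covariates (the no-selection
        comparison arm).
    vi_reps : int
        Permutation replications inside each split's importance run.
    seed : int
        Master seed; per-split and per-method streams are spawned from it.
    """
    if M < 1:
        raise ValueError("M must be >= 1")
    if selection_rule not in SELECTION_RULES:
        raise ValueError(
            f"unknown selection rule {selection_rule!r}; valid: {SELECTION_RULES}"
        )
    if isinstance(methods, Mapping):
        specs = dict(methods)
    else:
        specs = {name: make_regressor(name) for name in methods}
    if not specs:
        raise ValueError("need at least one method")

    method_names = tuple(specs)
    mse_matrix = np.full((M, len(specs)), np.nan)
    replicates: list[ChoiceReplicate] = []
    all_cols = tuple(range(data.p))

    for m_rep in range(M):
        split_ss, *vi_ss = np.random.SeedSequence(
            entropy=seed, spawn_key=(m_rep,)
        ).spawn(1 + len(specs))
        train_idx, test_idx = split_sample(data.n, train_frac, seed=split_ss)
        train = data.subset_rows(train_idx)
        test = data.subset_rows(test_idx)
        records: dict = {}
        for k, (name, spec) in enumerate(specs.items()):
            try:
                if selection_rule == "none":
                    selected = all_cols
                    no_change = False
                else:
                    imp = variable_importance(
                        train, spec, n_reps=vi_reps, seed=vi_ss[k], predict_on=predict_on
                    )
                    sel = _select(imp, selection_rule)
                    selected = sel.selected
                    no_change = bool(sel.diagnostics.get("no_change", False))
                    if not selected:  # baseline rule may select nothing
                        selected = all_cols
                        no_change = True
                fitted = spec.clone().fit(train.subset_columns(selected))
                preds = fitted.predict(test.X[:, list(selected)])
                err = mse_test(test.y, preds)
                records[name] = {
                    "selected": tuple(int(j) for j in selected),
                    "size": len(selected),
                    "mse_test": err,
                    "no_change": no_change,
                }
                mse_matrix[m_rep, k] = err
            except Exception as exc:
                logger.warning("method %s failed on split %d: %s", name, m_rep + 1, exc)
        replicates.append(
            ChoiceReplicate(
                split_id=m_rep + 1,
                train_idx=train_idx,
                test_idx=test_idx,
                records=records,
            )
        )

    for k, name in enumerate(method_names):
        if np.all(np.isnan(mse_matrix[:, k])):
            raise RuntimeError(f"method {name!r} failed on every split")

    config = {
        "methods": list(method_names),
        "M": M,
        "train_frac": train_frac,
        "selection_rule": selection_rule,
        "vi_reps": vi_reps,
        "seed": seed,
        "predict_on": predict_on,
        "n": data.n,
        "p": data.p,
    }
    return ChoiceSummary(
        methods=method_names,
        names=data.names,
        mse_matrix=mse_matrix,
        replicates=tuple(replicates),
        config=config,
    )
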