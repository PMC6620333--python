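"""Covariate selection from a variable-importance profile.

Two thresholding rules turn per-covariate mean importances into a selected
subset:

``baseline``
    Keep every covariate whose mean VI strictly exceeds the baseline MSE of
    the unperturbed fit — permuting a useful covariate must cost more than
    fitting the intact sample.

``changepoint``
    Sort the mean importances decreasingly and detect a single change point
    (in mean AND variance) in the sorted sequence; keep the covariates
    before the change.  Acceptance of a change is penalized BIC-style, so a
    flat profile yields no change and, conservatively, the full covariate
    set (flagged) rather than a silently empty model.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .importance import ImportanceResult

__all__ = [
    "SelectionResult",
    "select_by_baseline",
    "detect_change_point",
    "select_by_changepoint",
]

#: extra parameters of the two-segment model: one mean, one variance, one position
_EXTRA_PARAMS = 3

#: variance floor inside segment likelihoods (constant segments)
VAR_FLOOR = 1e-12


@dataclass(frozen=True)
class SelectionResult:
    """Outcome of a covariate-selection rule.

    Attributes
    ----------
    order : ndarray
        Covariate indices sorted by decreasing mean VI.
    selected : tuple of int
        Indices of the selected covariates (in ``order``'s prefix for the
        change-point rule).
    rule : str
        ``"changepoint"``, ``"baseline"`` or ``"none"``.
    threshold_value : float
        Baseline MSE for the baseline rule; the change position (a count of
        covariates) for the change-point rule.
    diagnostics : dict
        Per-rule details (segment statistics or margins above baseline);
        contains ``"no_change": True`` when the fallback fired.
    """

    order: np.ndarray
    selected: tuple[int, ...]
    rule: str
    threshold_value: float
    names: tuple[str, ...]
    diagnostics: dict = field(default_factory=dict)

    @property
    def size(self) -> int:
        return len(self.selected)

    @property
    def selected_names(self) -> tuple[str, ...]:
        return tuple(self.names[j] for j in self.selected)

    def to_dict(self) -> dict:
        return {
            "rule": self.rule,
            "order": [self.names[j] for j in self.order],
            "selected": list(self.selected_names),
            "threshold_value": self.threshold_value,
            "diagnostics": self.diagnostics,
        }

    def write(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))


def _decreasing_order(means: np.ndarray) -> np.ndarray:
    return np.argsort(-means, kind="stable")


def select_by_baseline(imp: ImportanceResult) -> SelectionResult:
    """Select the covariates whose mean VI strictly exceeds the baseline MSE."""
    means = imp.means
    order = _decreasing_order(means)
    selected = tuple(int(j) for j in np.flatnonzero(means > imp.baseline_mse))
    margins = {imp.names[j]: float(means[j] - imp.baseline_mse) for j in range(imp.p)}
    return SelectionResult(
        order=order,
        selected=selected,
        rule="baseline",
        threshold_value=imp.baseline_mse,
        names=imp.names,
        diagnostics={"margin_above_baseline": margins},
    )


def _segment_loglik(x: np.ndarray) -> float:
    """Gaussian log-likelihood of a segment at its MLE mean and variance."""
    m = len(x)
    var = max(float(np.mean((x - x.mean()) ** 2)), VAR_FLOOR)
    return -0.5 * m * (math.log(2.0 * math.pi * var) + 1.0)


def detect_change_point(
    sorted_means: np.ndarray, penalty: float | None = None
) -> int | None:
    """At-most-one change point (mean and variance) in a sorted sequence.

    Every split ``k`` in ``1..p-1`` (minimum segment length 1) is scored by
    the sum of the Gaussian log-likelihoods of the two segments, each with
    its own mean and variance.  The best split is returned if twice the
    log-likelihood gain over the single-segment fit exceeds ``penalty``
    (default ``2*log(p)`` per extra parameter, 3 extra parameters — a
    BIC-like criterion); otherwise ``None``.  Ties go to the smallest
    ``k`` (fewest covariates).
    """
    x = np.asarray(sorted_means, dtype=float).ravel()
    p = len(x)
    if p < 3:
        raise ValueError(f"too few covariates for change-point rule (p={p} < 3)")
    if penalty is None:
        penalty = _EXTRA_PARAMS * 2.0 * math.log(p)
    ll_one = _segment_loglik(x)
    best_k, best_ll = None, -math.inf
    for k in range(1, p):
        ll = _segment_loglik(x[:k]) + _segment_loglik(x[k:])
        if ll > best_ll:  # strict: ties keep the smallest k
            best_k, best_ll = k, ll
    if 2.0 * (best_ll - ll_one) > penalty:
        return best_k
    return None


def select_by_changepoint(
    imp: ImportanceResult, penalty: float | None = None
) -> SelectionResult:
    """Select the covariates before a detected change in the sorted mean VIs.

    Falls back to the full covariate set (flagged ``no_change``) when the
    penalized two-segment fit never beats one segment, so a downstream
    model-choice loop never receives an empty model.
    """
    means = imp.means
    order = _decreasing_order(means)
    sorted_means = means[order]
    k = detect_change_point(sorted_means, penalty=penalty)
    if k is None:
        selected = tuple(int(j) for j in order)
        diagnostics: dict = {"no_change": True}
        threshold = float(imp.p)
    else:
        selected = tuple(int(j) for j in order[:k])
        diagnostics = {
            "no_change": False,
            "segment_means": [float(sorted_means[:k].mean()), float(sorted_means[k:].mean())],
            "segment_vars": [
                float(np.var(sorted_means[:k])),
                float(np.var(sorted_means[k:])),
            ],
        }
        threshold = float(k)
    return SelectionResult(
        order=order,
        selected=selected,
        rule="changepoint",
        threshold_value=threshold,
        names=imp.names,
        diagnostics=diagnostics,
    )
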