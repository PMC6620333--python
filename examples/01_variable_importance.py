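"""Measure covariate importance by permute-and-refit on a linear model.

Simulates the study's linear design (n=200, p=15, five active covariates
with coefficients 4, 4, -3, -3, -2), computes each covariate's variable
importance (VI) — the training MSE after permuting that covariate and
refitting — and selects covariates by the automatic change-point rule and
by the baseline-MSE threshold.
"""

import numpy as np

from permvarsel import (
    LinearRegressor,
    select_by_baseline,
    select_by_changepoint,
    simulate_m1,
    variable_importance,
)

data = simulate_m1(seed=0)
imp = variable_importance(data, LinearRegressor(), n_reps=200, seed=0)

print(f"baseline MSE (unperturbed fit): {imp.baseline_mse:.3f}")
print("mean VI per covariate:")
for name, m in zip(imp.names, imp.means):
    print(f"  {name:>4s}  {m:.3f}")

cp = select_by_changepoint(imp)
bl = select_by_baseline(imp)
print(f"change-point rule keeps {cp.size}: {', '.join(cp.selected_names)}")
print(f"baseline rule keeps   {bl.size}: {', '.join(bl.selected_names)}")

# A mean VI well above the baseline marks a covariate whose permutation
# genuinely hurts the fit; the five active covariates should stand out and
# the change point should fall right after them.
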