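# permvarsel

Method-agnostic covariate selection and regression model choice by
permutation importance.

## The problem

Given a numeric regression sample S = {(xᵢ, yᵢ), i = 1…n} with p covariates
X = (X₁, …, X_p), two questions come up together in applied modelling —
typically in biostatistics, where the covariates are candidate biomarkers
and the response a quality or outcome measurement:

1. **Which covariates actually help predict Y?**
2. **Which regression method — parametric, semiparametric or
   nonparametric — predicts Y best, once each method selects its own
   covariates?**

Most selection procedures are tied to one model class (stepwise or lasso to
the linear model, split-based importances to forests). `permvarsel`
implements a generic wrapper that works identically for *any* regressor
exposing `fit`/`predict`, with no distributional assumptions on the error
term.

## The method

**Variable importance (VI).** For covariate Xⱼ, randomly permute the
observations of column j, **refit** the regression on the permuted sample,
and record

    VIⱼ = (1/n) Σᵢ (yᵢ − ŷᵢ⁽ʲ⁾)²,

where ŷ⁽ʲ⁾ comes from the refitted model f̂⁽ʲ⁾. Permutation destroys any
X_j–Y link, so VIⱼ rises above the baseline MSE — the training error
(1/n) Σ (yᵢ − ŷᵢ)² of the unperturbed fit — exactly when Xⱼ carries signal.
The permutation is replicated N times per covariate and the mean VIs are
compared. Refitting (rather than forest-style predict-only shuffling) is
what makes the measure comparable across model classes.

**Selection.** Sort the p mean VIs decreasingly and either
(a) detect a single change point in mean *and* variance of the sorted
sequence by a penalized two-segment Gaussian fit, keeping the covariates
before the change (automatic rule), or
(b) keep every covariate whose mean VI exceeds the baseline MSE
(threshold rule).

**Model choice.** Randomly split S into 80% train / 20% test, M times. On
each split, each competing method runs the VI + selection step on the train
rows only, refits on its selected covariates, and is scored on the held-out
rows by MSE_test = (1/n_test) Σ (yᵢ − ŷᵢ)². Methods are compared by their M
MSE_test values (boxplots/medians), the distribution of selected-model
sizes, and each covariate's occurrence frequency across the M final models.

Three backends ship behind the common contract:

| name     | model                              | estimation                                  |
|----------|------------------------------------|---------------------------------------------|
| `linreg` | Y = β₀ + Σ βⱼXⱼ + ε                | ordinary least squares                      |
| `sir`    | Y = f(X′β) + ε (single index)      | sliced inverse regression for β, Nadaraya–Watson Gaussian-kernel smoothing for f |
| `rf`     | Y = f(X) + ε (nonparametric)       | random forest (scikit-learn)                |

Any user object with `fit(Dataset)` / `predict(X)` / `clone()` plugs into
the same importance and model-choice engines.

## Worked example

`examples/01_variable_importance.py` simulates the package's linear study
design — n = 200 observations, p = 15 covariates iid uniform on [0, 0.7],
β = (4, 4, −3, −3, −2, 0, …, 0)′, standard normal noise — and screens the
covariates with the linear backend:

```
baseline MSE (unperturbed fit): 1.111
mean VI per covariate:
    X1  1.496
    X2  1.661
    X3  1.486
    X4  1.487
    X5  1.213
    X6  1.112
    X7  1.106
    ...
   X15  1.110
change-point rule keeps 5: X2, X1, X4, X3, X5
baseline rule keeps   6: X1, X2, X3, X4, X5, X6
```

The five active covariates stand clearly above the baseline (permuting them
costs up to 0.55 MSE units) while the ten null covariates hug it within
~0.5%; the change point lands right after the five.

`examples/02_model_choice.py` runs the full comparison on the cubic
single-index model Y = (X′β)³ + ε, where a linear fit misspecifies the link:

```
median MSE_test per method (lower = better):
  linreg    18.913
     sir     6.768
      rf    56.022

selected-model sizes over the 15 splits:
  linreg  {5: 13, 6: 2}
     sir  {5: 15}
      rf  {1: 9, 4: 2, 5: 1, 6: 2, 14: 1}
```

The single-index fit halves the linear fit's held-out error and beats the
forest by an order of magnitude, while both index-based methods stably
recover five-covariate models — the behaviour expected when a
one-dimensional index structure truly generates the data.

`examples/03_biomarker_screen.py` shows the same screen on a synthetic
71 × 21 biomarker panel with correlated covariates (muscle-protein
abundances predicting meat shear force).

A thin CLI mirrors the library:

```bash
permvarsel simulate --model M2 --seed 1 --out m2.csv
permvarsel importance --input m2.csv --method linreg --reps 200 --outdir run/
permvarsel choicemod --input m2.csv --methods linreg,sir,rf -M 25 --outdir run/
permvarsel report --rundir run/
```

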