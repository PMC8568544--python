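# oadcompare

Multi-arm observational comparison of oral antidiabetic therapies in a
real-world type-2-diabetes cohort: efficacy (glycemic control), adverse
events (hypoglycemia), health-related quality of life (EQ-5D), and annual
costs, compared across eight therapy arms — metformin, the Xiaoke Pill
(a traditional Chinese compound of glibenclamide and herbal substances),
other TCMs, gliclazide, acarbose, Xiaoke Pill combination therapy,
glibenclamide, and a pooled "Others" arm.

The package is a tested, reusable pipeline for anyone who needs to compare
many treatment arms in observational data with confounded treatment choice:
pharmacoepidemiologists, health economists, and biostatisticians working
with survey or registry cohorts.

## What it computes

Let `Y` be an outcome, `T ∈ {1, …, 8}` the therapy arm chosen at baseline
(intent-to-treat) or held throughout follow-up (on-treatment), and
`X ∈ {0,1}^35` the baseline indicators (age/education/city/income/insurance
dummies, behaviors, comorbidities, and clinical cutoffs such as
BMI ≥ 24, baseline HbA1c < 6.5 %, SBP ≥ 140 mmHg, TG ≥ 1.7 mmol/L).
Under conditional independence `Y(t) ⊥ T | X`, four estimators of the
per-arm mean potential outcomes `E[Y(t)]` are provided:

1. **Unadjusted subgroup means** with per-arm SEs and a compact letter
   display (arms share a letter iff not significantly different at the 5 %
   level);
2. **OLS predictive margins** (G-computation): fit
   `Y = α + Σ_t τ_t 1{T=t} + β'X + ε`, then average the prediction over the
   sample with every patient's arm fixed at `t`; delta-method SEs. For a
   linear model, `margin(t) − margin(ref) = τ_t` exactly, and with no
   covariates the margins are the subgroup means;
3. **Inverse probability weighting**: multinomial-logit propensities
   `e_t(x) = P(T=t|X=x)`, Hájek-normalized weights `1/e_T(x)`, weighted
   arm means with linearization SEs, and weighted covariate-balance
   diagnostics. Arms too small to support the propensity model (the
   glibenclamide arm has 12 patients) are merged into "Others";
4. **Double-selection adaptive lasso**: over a 69-column candidate pool
   (35 main indicators + 34 interactions with the baseline-control
   indicator), select predictors of the outcome *and* of each arm
   indicator by adaptive lasso (BIC-tuned), refit OLS on the union, and
   report post-selection margins — protecting the treatment effects from
   omitted-confounder bias that a pure prediction lasso would leave in.

Because the original survey data are not publicly deposited, the package
ships a synthetic-cohort generator whose defaults reproduce the study
conditions (n = 1903 across five cities, the published arm mix down to the
12-patient glibenclamide arm, published covariate marginals, confounded
multinomial assignment, and arm margins with known truth), so every
estimator can be validated against a recoverable ground truth.

## Worked example

```python
from oadcompare import (SimulationConfig, simulate_cohort, subgroup_summary,
                        fit_outcome_model, predictive_margins)

cohort = simulate_cohort(SimulationConfig(seed=42))
arms = cohort.arms.reset_index(drop=True)
X = cohort.covariates.reset_index(drop=True)
y = cohort.outcomes["hba1c_control"].reset_index(drop=True)

print(subgroup_summary(y, arms).round(3))
fit = fit_outcome_model(y, arms, covariates=X)
print(predictive_margins(fit, covariates=X).round(3))
print(f"Xiaoke vs metformin adjusted effect: "
      f"{fit.params['XiaokePill']:.3f} (SE {fit.bse['XiaokePill']:.3f})")
```

prints

```
                  n  estimate     se letters
arm
Metformin       181     0.337  0.035      ab
XiaokePill      226     0.487  0.033       c
OtherTCMs       186     0.290  0.033       a
Gliclazide      160     0.494  0.040       c
Acarbose        119     0.420  0.045      bc
XiaokePillPlus  176     0.466  0.038       c
Glibenclamide    15     0.267  0.114     abc
Others          840     0.340  0.016      ab

                margin     se letters
arm
Metformin        0.331  0.033       a
XiaokePill       0.450  0.030       b
OtherTCMs        0.379  0.034      ab
Gliclazide       0.444  0.036       b
Acarbose         0.390  0.041      ab
XiaokePillPlus   0.406  0.034      ab
Glibenclamide    0.262  0.115      ab
Others           0.358  0.015       a

Xiaoke vs metformin adjusted effect: 0.119 (SE 0.045)
```

The unadjusted Xiaoke Pill control rate (0.487) is inflated by confounding
— Xiaoke users are more often glycemically controlled at baseline — while
the adjusted margin (0.450) recovers the generator's configured truth of
0.45 against 0.33 for metformin; the adjusted contrast (+0.119) matches the
configured +0.12. Letters summarize all pairwise comparisons: arms sharing
no letter differ at the 5 % level.

The same pipeline runs from the shell:

```sh
oadcompare simulate --seed 42 --n 1903          # write a cohort CSV pair
oadcompare all --seed 42 --out report/          # every estimator stage
oadcompare dslasso --regime on_treatment --out report_ot/
```

`report/` contains CSV analogues of the study's tables (arm counts,
baseline balance, unadjusted outcomes, adjusted coefficients and margins,
IPW outcomes and weighted balance, selected variables, double-selection
margins) plus a JSON manifest with the seed and config hash; a fixed seed
reproduces the bundle byte for byte.

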