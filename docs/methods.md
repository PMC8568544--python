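# Methods

## Cohort and therapy definitions

One record per patient: baseline covariates, the oral regimen observed at
baseline and at four quarterly follow-ups, and endpoint outcomes. Insulin
users are rejected at classification (they are excluded at screening);
missing baseline or endpoint measures raise an explicit error — the
analysis is complete-case throughout, with no imputation.

Therapy classification is a total function on drug sets: the six named
monotherapies map to their arms; any multi-drug set containing the Xiaoke
Pill maps to the combination arm; everything else — including unknown drug
names, admitted with a warning, since observed plans include agents outside
the 15 monitored ones — pools into "Others". The intent-to-treat arm is
fixed at the baseline regimen. The on-treatment cohort keeps a patient iff
all four follow-up drug sets equal the baseline set. We read "no
discontinuation, switching, or add-on" as strict set equality at every
wave; a patient who drops a drug for one quarter and resumes is excluded.
This is the conservative choice where partial-period adherence is
ambiguous.

Covariate construction dichotomizes the continuous baseline measures at
standard clinical cutoffs (BMI ≥ 24 kg/m², HbA1c < 6.5 %, FBS < 7 mmol/L,
SBP ≥ 140 / DBP ≥ 90 mmHg, TC ≥ 5.2 / TG ≥ 1.7 mmol/L, EQ-5D ≥ 0.9), all
cutoffs inclusive on the stated side, and encodes categorical factors as
dummies with the reference level (age < 50, primary education, Beijing,
lowest income, URBMI insurance, duration < 5 years) all-zero. Derived
outcomes: glycemic control is the strict target endpoint HbA1c < 6.5 %
(6.5 exactly is *not* controlled); hypoglycemia incidence is the sum of
the four follow-up flags (0–4); total cost is the exact sum of the
inpatient, outpatient, and OTC components in 1000-RMB units.

## Synthetic cohort generator

The generator defines the study conditions under which everything is
tested; its defaults are fixed, not tuning knobs.

* n = 1903 patients; 35 indicators drawn at the published pooled marginal
  frequencies, independently across patients and (within the constraint of
  mutually exclusive dummy groups) across covariates. Only marginals are
  published, so independence is the default; an optional latent severity
  factor (`latent_severity > 0`) tilts the health-related flags from a
  shared Gaussian factor for correlation stress tests.
* Assignment: multinomial logit over the eight arms with intercepts equal
  to the log arm-size ratios from the published counts (so the
  intercept-implied mix reproduces the study's arm sizes, down to the
  12-patient glibenclamide arm) plus centered confounding terms
  `c'(x − μ)`. The default confounding signs follow the published baseline
  imbalance (other-TCM users concentrated in Shenyang, gliclazide in
  Nanjing, Xiaoke users more often controlled at baseline, …) with
  moderate magnitudes (0.5–1.5 on the log-odds scale).
* Outcomes: arm margins enter as location parameters and covariate effects
  enter centered, so absent clipping the configured margin is exactly the
  potential-outcome mean. Default margins are the study's adjusted margins
  (control rates 0.33 metformin / 0.45 Xiaoke Pill, …); default covariate
  effects take the study's dominant fitted coefficients (baseline control
  +0.26 on the control probability, Shenyang +0.56 on hypoglycemia
  incidence, …). Glycemic control is a linear-probability Bernoulli
  clipped to [0.01, 0.99] — chosen so OLS margins are exactly the
  configured truth; a logistic option exists for misspecification
  experiments. Hypoglycemia is Binomial(4, p) summed from per-wave flags.
  EQ-5D is Gaussian (sd 0.05) clipped to [0, 1]. Costs are per-component
  Gaussian (sd 1.0 / 0.8 / 0.3 for inpatient / outpatient / OTC) truncated
  at zero; total cost is the exact component sum. A configuration whose
  implied control probability leaves [0, 1] by more than a tolerance
  (default 0.1, computed over the covariate support respecting the dummy
  groups) is rejected.
* Adherence: each patient is fully adherent with probability 0.46 (the
  on-treatment sensitivity cohort retains 878 of 1903 patients, 46.1 %);
  otherwise one random wave gains an add-on drug.
* Reproducibility: one `numpy` generator seeded from `config.seed` drives
  every draw; a fixed seed yields a byte-identical cohort.

**Truth oracle.** Clipping and zero-truncation are part of the mechanism,
so the estimand is the *post-clipping* potential-outcome mean.
`true_potential_margins` computes it by forcing each arm on a large
unconfounded draw (default 300 000 patients) and averaging — independent
of every estimator. For the binary outcome at the default effect sizes
clipping essentially never binds and the oracle agrees with the configured
margins to ~0.01; for costs the zero-truncation raises small-margin arms
(e.g. the glibenclamide inpatient margin) noticeably, which is why the
oracle, not the raw configuration, is the reference in recovery tests.

**What the generator does not emulate:** within-patient covariate
correlation beyond the optional severity factor, lognormal/heavy-tailed
cost noise (the analysis models costs linearly, so the truncated-Gaussian
mechanism matches the estimand actually fit), dropout between waves, and
outcome-dependent adherence. Passing recovery tests therefore certify the
estimators under correct specification and confounding-on-observables;
they say nothing about unmeasured confounding or heavy-tailed costs.

## Descriptive statistics

Subgroup means with SE = SD/√n (binomial √(p(1−p)/n) for 0/1 outcomes,
auto-detected); arms with one patient keep their mean but get an undefined
SE and a warning. Pairwise comparisons are two-sample z-tests from the
per-arm means and SEs, unadjusted for multiplicity — the source tables
state "at the 5 % level" with no correction; a Bonferroni adjustment can
be applied by dividing alpha upstream. Per-arm SEs (not a pooled model
variance) feed the tests. Balance tests are one-way ANOVA F-tests treating
the 0/1 indicator as numeric; degenerate inputs use the conventions p = 1
for a constant covariate and p = 0 for zero within-group variance with
distinct means.

**Compact letter display.** Letters must satisfy: two arms share a letter
iff their pairwise p ≥ alpha. We solve the minimum clique cover of the
non-significance graph exactly — maximal cliques via Bron–Kerbosch, then
the smallest subfamily covering every non-significant pair and every arm —
rather than the common insert-and-absorb heuristic, which does not
guarantee minimality. With at most eight arms the exact search is
microseconds; beyond ~15 arms a heuristic would be needed. Ties break
deterministically by first arm index, and non-transitive significance
patterns yield overlapping letters (never an error).

## Adjusted margins

OLS with classical (homoskedastic) covariance by default — matching the
magnitudes of the source tables' reporting; HC1 robust covariance is an
option. All seven outcomes (binary control, 0–4 count, bounded EQ-5D,
costs) are fit in the same linear framework, exactly as the source
analysis does. Predictive margins are `G β` with
`G = [1, arm pattern, x̄]`; their covariance `G V Gᵀ` treats the covariate
means as fixed (the standard predictive-margins convention) and carries
the full between-margin covariance into the letter display. Rank-deficient
designs are rejected with the names of the collinear columns (QR with
pivoting).

## Inverse probability weighting

Maximum-likelihood multinomial logit (Newton, gradient checked below
1e-8 at the optimum); separation — divergent coefficients or a singular
Hessian — raises an error naming the offending covariate. Arms under 30
patients (configurable) merge into "Others" before fitting, following the
source's handling of the glibenclamide arm. Weights are 1/ê_T(x), Hájek
(within-arm sum-to-one) normalized; optional symmetric percentile
truncation is off by default since no extreme-weight handling is reported.
SEs of the weighted means use the Taylor linearization of the Hájek ratio,
`Σ w²(y − m)² / (Σ w)²` — the source does not state its variance method,
so the linearization is our documented choice; it is invariant to
within-arm weight rescaling. Weighted balance uses a weighted one-way
ANOVA (weights normalized to sum to n, F with (k−1, n−k) df). Note the
weighted F-test inherits the weighting design effect: with *estimated*
weights from a correctly specified model the rejection share calibrates to
~5 % (the fit's score equations enforce in-sample weighted balance), but
weighting by the *true* probabilities leaves O(1/√n) random imbalance that
the test flags more often — diagnostics should use the fitted model's
weights.

## Double selection

Candidate pool: the 35 main indicators plus the interaction of each
remaining indicator with the baseline glycemic-control indicator (a binary
squared with itself is the original column, so squared terms and the
anchor self-interaction are excluded); duplicate and constant columns drop
deterministically, keeping the first occurrence — 69 columns on the full
schema. Interactions are limited to the baseline-control anchor, which is
what the 69-count arithmetic implies; a full pairwise expansion is not the
default.

Adaptive lasso: pilot OLS on the standardized pool (ridge-initialized with
a warning if rank deficient), penalty weights `|β̂_init|^(−γ)` with γ = 1,
path solved by coordinate descent (scikit-learn `lasso_path` on the
rescaled design, tolerance 1e-7) over 80 log-spaced penalties from the
smallest all-zero penalty down four decades. "Empirical BIC" is
implemented as the Gaussian-RSS form `n log(RSS/n) + df log(n)` with df =
number of nonzero coefficients; an extended-BIC variant
(+`df log p`) is available. The response is centered and scaled
internally, making selection invariant to affine response rescaling and to
column order.

Treatment equations use a linear (least-squares) working model for the 0/1
arm indicators — chosen for determinism and speed; an adaptive L1 logistic
option exists. Selection runs once per arm indicator (not jointly on the
arm block), then the union of the outcome and treatment selections feeds
an ordinary OLS with arm dummies, and margins/letters come from the
adjusted-margins machinery. Nesting identities hold exactly: a full-pool
union reproduces the fully adjusted model; an empty union reproduces
subgroup means.

## Recovery study and its metric

`run_recovery_study` replicates confounded cohorts (default 200 × n=1903)
and compares unadjusted means, OLS margins, true-propensity Hájek IPW, and
double-selection margins against the forced-arm oracle. The pre-registered
metric is, per estimator and outcome, the across-arm mean absolute bias
versus twice the across-arm mean combined SE (replication SE and oracle SE
in quadrature). A per-arm two-sigma rule over 8 arms × several estimators
would fail a genuinely unbiased estimator with high probability by
multiplicity alone; the across-arm mean (E|bias| ≈ 0.8 SE under
unbiasedness) keeps the check sharp and stable. The replicated studies use
the binary control outcome and the hypoglycemia count — the two outcomes
whose mechanisms are clip-free at the default effect sizes, so model
misspecification cannot masquerade as estimator bias. At these sizes the
study runs in ~1.5 minutes on one CPU; the observed mean absolute biases
of the adjusted estimators sit at roughly a third of the bound while the
unadjusted means exceed it several-fold.

## Known limitations

* The published-count fixture reproduces arm sizes, city sizes and per-arm
  outcome means, not joint covariate-outcome structure; it validates
  arithmetic (shares, identities, letter logic), not estimator behavior.
* One printed source row violates its own cost identity by a rounding unit
  (components 2.06 + 2.48 + 0.62 = 5.16 against a printed total of 5.15);
  the package always computes totals as exact component sums.
* The weighted-variance choice for IPW SEs and the Gaussian-BIC reading of
  "empirical BIC" are documented choices where the source is silent;
  alternatives are exposed as options, not defaults.
* Cost outcomes are truncated-Gaussian by design; users fitting real
  right-skewed costs should treat the linear-model SEs with the usual
  caution.
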