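"""Synthetic cohorts with the statistical structure the estimators assume.

The generator emulates a multicenter observational diabetes cohort: 35
binary baseline indicators drawn at the published marginal frequencies
(mutually exclusive within dummy groups), confounded multinomial-logit
therapy assignment over eight arms, and binary / count / continuous / cost
outcomes with known arm-specific potential-outcome margins. Because the
assignment model and the outcome models are both known, every estimator in
the package has a recoverable ground truth.

Outcome mechanisms
------------------
* glycemic control: Bernoulli with a linear-probability index clipped to
  [0.01, 0.99] (a logistic option exists for misspecification experiments);
* hypoglycemia incidence: Binomial(4, p) summed from four per-wave flags;
* EQ-5D: Gaussian clipped to [0, 1];
* costs: Gaussian truncated at zero, per component; total = exact sum.

Covariate effects enter centered, ``beta' (x - mu)``, so that with no
clipping the configured margin is exactly the potential-outcome mean.
Clipping and truncation are part of the mechanism; the implied estimand is
exposed by :func:`true_potential_margins`, a forced-arm Monte-Carlo oracle.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .cohort import (ARMS, ARM_METFORMIN, ARM_XIAOKE, ARM_TCMS,
                     ARM_GLICLAZIDE, ARM_ACARBOSE, ARM_XIAOKE_PLUS,
                     ARM_GLIBENCLAMIDE, ARM_OTHERS, CITIES,
                     COVARIATE_COLUMNS, DUMMY_GROUPS, XIAOKE_PILL, TCMS,
                     PatientRecord)

__all__ = [
    "SimulationConfig",
    "SimulatedCohort",
    "ConfigError",
    "simulate_cohort",
    "generate_cohort",
    "true_potential_margins",
    "make_paper_fixture",
    "TABLE2_ARM_COUNTS",
    "CITY_COUNTS",
]


class ConfigError(ValueError):
    """Invalid simulation configuration."""


# Published arm sizes at baseline (working sample n = 1903).
TABLE2_ARM_COUNTS = {
    ARM_METFORMIN: 203, ARM_XIAOKE: 233, ARM_TCMS: 137,
    ARM_GLICLAZIDE: 128, ARM_ACARBOSE: 110, ARM_XIAOKE_PLUS: 177,
    ARM_GLIBENCLAMIDE: 12, ARM_OTHERS: 903,
}

# Working-sample sizes by city.
CITY_COUNTS = {"Shenyang": 440, "Beijing": 314, "Chengdu": 403,
               "Nanjing": 366, "Guangzhou": 380}

# Marginal frequencies of the 35 indicators in the pooled sample
# (the balance table's Total column, as fractions).
DEFAULT_COVARIATE_MARGINALS = dict(zip(COVARIATE_COLUMNS, (
    0.25, 0.33, 0.27,           # age bands (reference < 50)
    0.44,                        # male
    0.36, 0.24, 0.13,            # education bands
    0.23, 0.21, 0.19, 0.20,      # cities (reference Beijing)
    0.38, 0.36,                  # income bands
    0.64, 0.10, 0.05,            # insurance (reference URBMI)
    0.20, 0.25, 0.79, 0.90,      # smoking, drinking, exercise, diet control
    0.26, 0.24,                  # duration bands
    0.21, 0.49, 0.20, 0.08,      # comorbidities
    0.58,                        # BMI >= 24
    0.39,                        # baseline HbA1c < 6.5
    0.45,                        # baseline FBS < 7
    0.11,                        # baseline hypoglycemia
    0.40, 0.26, 0.39, 0.41,      # SBP, DBP, TC, TG cutoffs
    0.48,                        # baseline EQ-5D >= 0.9
)))

# Assignment intercepts: log arm-size ratios versus metformin, so the
# intercept-implied shares reproduce the published arm mix (covariate terms
# are centered and leave the average score unchanged).
DEFAULT_ASSIGNMENT_INTERCEPTS = {
    a: math.log(TABLE2_ARM_COUNTS[a] / TABLE2_ARM_COUNTS[ARM_METFORMIN])
    for a in ARMS if a != ARM_METFORMIN
}

# Confounding pattern: signs follow the observed baseline imbalance
# (e.g. other-TCM users concentrated in Shenyang, gliclazide in Nanjing,
# Xiaoke users more often glycemically controlled at baseline).
DEFAULT_ASSIGNMENT_COEFFICIENTS = {
    ARM_XIAOKE: {"city_shenyang": 0.8, "hba1c_ctrl_bl": 0.5,
                 "hypertension": -0.6},
    ARM_TCMS: {"city_shenyang": 1.5, "hba1c_ctrl_bl": -0.6,
               "heart_disease": 0.7},
    ARM_GLICLAZIDE: {"city_nanjing": 1.5, "ins_nrcm": 0.8},
    ARM_ACARBOSE: {"income_high": 0.7, "hypertension": 0.6},
    ARM_XIAOKE_PLUS: {"city_guangzhou": 1.2, "hba1c_ctrl_bl": 0.5},
    ARM_GLIBENCLAMIDE: {},
    ARM_OTHERS: {"city_guangzhou": 0.5, "hba1c_ctrl_bl": -0.3},
}

# True per-arm potential-outcome margins (location parameters) for the six
# component outcomes; defaults are the published covariate-adjusted margins.
DEFAULT_TRUE_MARGINS = {
    "hba1c_control": dict(zip(ARMS, (0.33, 0.45, 0.36, 0.41, 0.40, 0.43,
                                     0.28, 0.36))),
    "hypo_incidence": dict(zip(ARMS, (0.35, 0.42, 0.48, 0.43, 0.40, 0.36,
                                      0.42, 0.44))),
    "eq5d": dict(zip(ARMS, (0.89, 0.90, 0.89, 0.88, 0.88, 0.87,
                            0.89, 0.89))),
    "cost_inpatient": dict(zip(ARMS, (4.28, 1.63, 3.02, 1.94, 4.44, 1.99,
                                      0.53, 3.13))),
    "cost_outpatient": dict(zip(ARMS, (3.42, 2.90, 3.87, 3.83, 4.70, 3.40,
                                       3.26, 5.07))),
    "cost_otc": dict(zip(ARMS, (0.84, 0.81, 1.54, 0.74, 1.18, 0.89,
                                0.34, 0.87))),
}

# Covariate effects on outcomes (shared across arms, additive, centered);
# magnitudes follow the fitted outcome-regression coefficients for the
# prognostically dominant indicators.
DEFAULT_OUTCOME_EFFECTS = {
    "hba1c_control": {"hba1c_ctrl_bl": 0.26, "fbs_lt7": 0.12,
                      "city_chengdu": 0.24, "city_guangzhou": 0.19,
                      "city_nanjing": 0.11, "age_60_70": -0.11,
                      "age_ge70": -0.10, "sbp_ge140": -0.06},
    "hypo_incidence": {"city_shenyang": 0.56, "city_nanjing": 0.21,
                       "hypo_bl": 0.21, "fbs_lt7": 0.09,
                       "hrqol_ge09": -0.11},
    "eq5d": {"age_ge70": -0.04, "hrqol_ge09": 0.05, "stroke": -0.05,
             "exercise": 0.03, "dbp_ge90": -0.02},
    "cost_inpatient": {"age_ge70": 0.8, "hrqol_ge09": -0.4},
    "cost_outpatient": {"city_shenyang": -1.0, "income_high": 0.8},
    "cost_otc": {"heart_disease": 0.3, "tc_ge52": 0.2},
}

DEFAULT_NOISE_SD = {"eq5d": 0.05, "cost_inpatient": 1.0,
                    "cost_outpatient": 0.8, "cost_otc": 0.3}

COMPONENT_OUTCOMES = ("hba1c_control", "hypo_incidence", "eq5d",
                      "cost_inpatient", "cost_outpatient", "cost_otc")

_SINGLE_COLUMNS = tuple(c for c in COVARIATE_COLUMNS
                        if not any(c in g for g in DUMMY_GROUPS.values()))
# Health-related flags tilted by the optional latent severity factor.
_SEVERITY_LOADINGS = {
    "heart_disease": 1, "hypertension": 1, "dyslipidemia": 1, "stroke": 1,
    "sbp_ge140": 1, "dbp_ge90": 1, "tc_ge52": 1, "tg_ge17": 1,
    "hypo_bl": 1, "hba1c_ctrl_bl": -1, "fbs_lt7": -1, "hrqol_ge09": -1,
}


@dataclass
class SimulationConfig:
    """Study-condition parameters of the synthetic cohort.

    Defaults reproduce the published study conditions: n = 1903 patients,
    marginal covariate frequencies from the pooled balance table, arm mix
    from the published therapy counts, confounded assignment, adjusted
    margins as the true potential outcomes, and a 46 % on-treatment
    adherence rate (878 of 1903 adherent in the sensitivity cohort).
    """

    n_patients: int = 1903
    covariate_marginals: dict = field(
        default_factory=lambda: dict(DEFAULT_COVARIATE_MARGINALS))
    assignment_intercepts: dict = field(
        default_factory=lambda: dict(DEFAULT_ASSIGNMENT_INTERCEPTS))
    assignment_coefficients: dict = field(
        default_factory=lambda: {a: dict(v) for a, v in
                                 DEFAULT_ASSIGNMENT_COEFFICIENTS.items()})
    true_margins: dict = field(
        default_factory=lambda: {k: dict(v) for k, v in
                                 DEFAULT_TRUE_MARGINS.items()})
    outcome_effects: dict = field(
        default_factory=lambda: {k: dict(v) for k, v in
                                 DEFAULT_OUTCOME_EFFECTS.items()})
    noise_sd: dict = field(default_factory=lambda: dict(DEFAULT_NOISE_SD))
    adherence_prob: float = 0.46
    latent_severity: float = 0.0
    binary_mechanism: str = "linear"    # or "logistic"
    clip_tolerance: float = 0.1
    seed: int = 0

    def unconfounded(self) -> "SimulationConfig":
        """Copy with all assignment coefficients zeroed (random assignment)."""
        return replace(self, assignment_coefficients={
            a: {} for a in ARMS if a != ARM_METFORMIN})

    def null_effects(self) -> "SimulationConfig":
        """Copy in which every arm shares the metformin margins."""
        margins = {o: {a: m[ARM_METFORMIN] for a in ARMS}
                   for o, m in self.true_margins.items()}
        return replace(self, true_margins=margins)

    def validate(self) -> None:
        for c, p in self.covariate_marginals.items():
            if not 0.0 <= p <= 1.0:
                raise ConfigError(f"marginal for {c} outside [0,1]: {p}")
        for g, cols in DUMMY_GROUPS.items():
            s = sum(self.covariate_marginals[c] for c in cols)
            if s > 1.0 + 1e-9:
                raise ConfigError(
                    f"dummy group {g!r} marginals sum to {s:.3f} > 1")
        for o, m in self.true_margins.items():
            if set(m) != set(ARMS):
                raise ConfigError(f"margins for {o} must cover all 8 arms")
        if self.binary_mechanism not in ("linear", "logistic"):
            raise ConfigError(
                f"unknown binary mechanism {self.binary_mechanism!r}")
        if not 0.0 <= self.adherence_prob <= 1.0:
            raise ConfigError("adherence_prob outside [0,1]")
        if self.binary_mechanism == "linear":
            lo, hi = self._binary_index_range()
            tol = self.clip_tolerance
            if lo < -tol or hi > 1.0 + tol:
                raise ConfigError(
                    "implied glycemic-control probability range "
                    f"[{lo:.3f}, {hi:.3f}] exceeds [0,1] beyond the "
                    f"tolerance {tol}")

    def _binary_index_range(self):
        """Worst-case range of the linear-probability index over the
        covariate support (respecting mutually exclusive dummy groups)."""
        eff = self.outcome_effects.get("hba1c_control", {})
        mu = self.covariate_marginals
        base = -sum(b * mu[c] for c, b in eff.items())
        up = down = base
        grouped = set()
        for cols in DUMMY_GROUPS.values():
            opts = [0.0] + [eff.get(c, 0.0) for c in cols]
            up += max(opts)
            down += min(opts)
            grouped.update(cols)
        for c, b in eff.items():
            if c not in grouped:
                up += max(b, 0.0)
                down += min(b, 0.0)
        margins = self.true_margins["hba1c_control"]
        return min(margins.values()) + down, max(margins.values()) + up


@dataclass
class SimulatedCohort:
    """Array view of one simulated cohort (records built on demand)."""

    covariates: pd.DataFrame        # n x 35 binary indicators
    arms: pd.Series                 # arm label per patient
    outcomes: pd.DataFrame          # component + derived outcomes
    propensities: pd.DataFrame      # true P(arm | x), n x 8
    records: list | None = None


def _coef_matrix(mapping: dict, columns=COVARIATE_COLUMNS) -> np.ndarray:
    """Arm-major coefficient matrix (8 x 35); reference row fixed at zero."""
    out = np.zeros((len(ARMS), len(columns)))
    for a, coefs in mapping.items():
        if a == ARM_METFORMIN:
            continue
        i = ARMS.index(a)
        for c, b in coefs.items():
            out[i, columns.index(c)] = b
    return out


def _effect_vector(mapping: dict, columns=COVARIATE_COLUMNS) -> np.ndarray:
    out = np.zeros(len(columns))
    for c, b in mapping.items():
        out[columns.index(c)] = b
    return out


def _draw_covariates(config: SimulationConfig, n: int,
                     rng: np.random.Generator) -> np.ndarray:
    """Draw the n x 35 indicator matrix at the configured marginals."""
    mu = config.covariate_marginals
    X = np.zeros((n, len(COVARIATE_COLUMNS)))
    col = {c: i for i, c in enumerate(COVARIATE_COLUMNS)}
    z = rng.standard_normal(n) if config.latent_severity > 0 else None
    for cols in DUMMY_GROUPS.values():
        probs = np.array([mu[c] for c in cols])
        ref = 1.0 - probs.sum()
        draw = rng.choice(len(cols) + 1, size=n,
                          p=np.concatenate([[ref], probs]))
        for k, c in enumerate(cols, start=1):
            X[:, col[c]] = draw == k
    for c in _SINGLE_COLUMNS:
        p = np.full(n, mu[c])
        if z is not None and c in _SEVERITY_LOADINGS:
            p = np.clip(p + config.latent_severity * _SEVERITY_LOADINGS[c]
                        * 0.15 * z, 0.01, 0.99)
        X[:, col[c]] = rng.random(n) < p
    return X


def _assignment_probs(config: SimulationConfig, X: np.ndarray) -> np.ndarray:
    """True multinomial-logit propensities, n x 8 (rows sum to one)."""
    mu = np.array([config.covariate_marginals[c] for c in COVARIATE_COLUMNS])
    C = _coef_matrix(config.assignment_coefficients)
    scores = (X - mu) @ C.T
    for a, b0 in config.assignment_intercepts.items():
        scores[:, ARMS.index(a)] += b0
    scores -= scores.max(axis=1, keepdims=True)
    e = np.exp(scores)
    return e / e.sum(axis=1, keepdims=True)


def _draw_outcomes(config: SimulationConfig, X: np.ndarray,
                   arm_idx: np.ndarray, rng: np.random.Generator) -> dict:
    """Draw all component outcomes given covariates and assigned arms.

    Returns a dict of 1-D arrays plus the n x 4 per-wave hypoglycemia flags.
    """
    n = X.shape[0]
    mu = np.array([config.covariate_marginals[c] for c in COVARIATE_COLUMNS])
    Xc = X - mu
    out = {}

    def margin_of(outcome):
        m = config.true_margins[outcome]
        return np.array([m[a] for a in ARMS])[arm_idx]

    def shift_of(outcome):
        return Xc @ _effect_vector(config.outcome_effects.get(outcome, {}))

    # binary glycemic control
    m = np.clip(margin_of("hba1c_control"), 1e-6, 1 - 1e-6)
    shift = shift_of("hba1c_control")
    if config.binary_mechanism == "linear":
        p = np.clip(m + shift, 0.01, 0.99)
    else:
        # logistic link anchored so the margin is the probability at x = mu
        p = 1.0 / (1.0 + np.exp(-(np.log(m / (1.0 - m)) + shift)))
    out["hba1c_control"] = (rng.random(n) < p).astype(int)

    # hypoglycemia incidence: four per-wave Bernoulli flags
    p_wave = np.clip((margin_of("hypo_incidence")
                      + shift_of("hypo_incidence")) / 4.0, 0.0, 1.0)
    flags = rng.random((n, 4)) < p_wave[:, None]
    out["hypo_flags"] = flags.astype(int)
    out["hypo_incidence"] = flags.sum(axis=1)

    # EQ-5D utility
    out["eq5d"] = np.clip(
        margin_of("eq5d") + shift_of("eq5d")
        + config.noise_sd["eq5d"] * rng.standard_normal(n), 0.0, 1.0)

    # cost components: zero-truncated Gaussian
    for comp in ("cost_inpatient", "cost_outpatient", "cost_otc"):
        out[comp] = np.maximum(
            0.0, margin_of(comp) + shift_of(comp)
            + config.noise_sd[comp] * rng.standard_normal(n))
    out["cost_total"] = (out["cost_inpatient"] + out["cost_outpatient"]
                         + out["cost_otc"])
    return out


_ARM_BASELINE_DRUGS = {
    ARM_METFORMIN: frozenset({"metformin"}),
    ARM_XIAOKE: frozenset({XIAOKE_PILL}),
    ARM_TCMS: frozenset({TCMS}),
    ARM_GLICLAZIDE: frozenset({"gliclazide"}),
    ARM_ACARBOSE: frozenset({"acarbose"}),
    ARM_XIAOKE_PLUS: frozenset({XIAOKE_PILL, "metformin"}),
    ARM_GLIBENCLAMIDE: frozenset({"glibenclamide"}),
    ARM_OTHERS: frozenset({"gliclazide", "metformin"}),
}


def _followups(baseline: frozenset, adherent: bool, rng) -> tuple:
    """Four follow-up regimens: identical if adherent, else one wave adds a
    drug (the most common non-adherence pattern is add-on)."""
    if adherent:
        return (baseline,) * 4
    wave = int(rng.integers(0, 4))
    addon = "acarbose" if "acarbose" not in baseline else "glipizide"
    sets = [baseline] * 4
    sets[wave] = baseline | {addon}
    return tuple(sets)


def simulate_cohort(config: SimulationConfig | None = None,
                    rng: np.random.Generator | None = None,
                    with_records: bool = True) -> SimulatedCohort:
    """Simulate one cohort under ``config`` (defaults: study conditions).

    A fixed ``config.seed`` yields a byte-identical cohort. Pass ``rng`` to
    draw replicates from one stream instead.
    """
    config = config or SimulationConfig()
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n = config.n_patients
    X = _draw_covariates(config, n, rng)
    P = _assignment_probs(config, X)
    arm_idx = _sample_rows(P, rng)
    out = _draw_outcomes(config, X, arm_idx, rng)

    pids = pd.Index([f"S{i:05d}" for i in range(n)], name="patient_id")
    covariates = pd.DataFrame(X.astype(int), index=pids,
                              columns=list(COVARIATE_COLUMNS))
    arms = pd.Series(np.array(ARMS)[arm_idx], index=pids, name="arm")
    outcomes = pd.DataFrame(
        {k: out[k] for k in ("hba1c_control", "hypo_incidence", "eq5d",
                             "cost_inpatient", "cost_outpatient", "cost_otc",
                             "cost_total")}, index=pids)
    propensities = pd.DataFrame(P, index=pids, columns=list(ARMS))
    records = None
    if with_records:
        records = _build_records(config, X, arm_idx, out, rng)
    return SimulatedCohort(covariates, arms, outcomes, propensities, records)


def _sample_rows(P: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Vectorized categorical draw, one row of probabilities per patient."""
    u = rng.random(P.shape[0])[:, None]
    return (P.cumsum(axis=1) < u).sum(axis=1)


def generate_cohort(config: SimulationConfig | None = None) -> list:
    """Generate a list of :class:`PatientRecord` under ``config``."""
    return simulate_cohort(config, with_records=True).records


def _uniform_band(rng, n, low, high):
    return rng.uniform(low, high, size=n)


def _build_records(config, X, arm_idx, out, rng) -> list:
    """Synthesize raw patient fields consistent with the drawn indicators."""
    n = X.shape[0]
    col = {c: i for i, c in enumerate(COVARIATE_COLUMNS)}

    def ind(c):
        return X[:, col[c]].astype(bool)

    age = _uniform_band(rng, n, 35, 50)
    age[ind("age_50_60")] = _uniform_band(rng, ind("age_50_60").sum(), 50, 60)
    age[ind("age_60_70")] = _uniform_band(rng, ind("age_60_70").sum(), 60, 70)
    age[ind("age_ge70")] = _uniform_band(rng, ind("age_ge70").sum(), 70, 85)

    education = (1 + ind("edu_lower_sec") + 2 * ind("edu_upper_sec")
                 + 3 * ind("edu_tertiary")).astype(int)
    income = (1 + ind("income_mid") + 2 * ind("income_high")).astype(int)
    duration = (1 + ind("duration_5_10") + 2 * ind("duration_ge10")).astype(int)

    city = np.full(n, "Beijing", dtype=object)
    for c, label in (("city_shenyang", "Shenyang"), ("city_chengdu", "Chengdu"),
                     ("city_nanjing", "Nanjing"),
                     ("city_guangzhou", "Guangzhou")):
        city[ind(c)] = label
    insurance = np.full(n, "URBMI", dtype=object)
    for c, label in (("ins_uebmi", "UEBMI"), ("ins_nrcm", "NRCM"),
                     ("ins_gov", "government")):
        insurance[ind(c)] = label

    def measure(flag, lo_true, hi_true, lo_false, hi_false):
        m = ind(flag)
        v = _uniform_band(rng, n, lo_false, hi_false)
        v[m] = _uniform_band(rng, m.sum(), lo_true, hi_true)
        return v

    bmi = measure("bmi_ge24", 24.0, 32.0, 19.0, 23.99)
    hba1c = measure("hba1c_ctrl_bl", 5.5, 6.49, 6.5, 10.0)
    fbs = measure("fbs_lt7", 4.5, 6.99, 7.0, 12.0)
    sbp = measure("sbp_ge140", 140.0, 170.0, 105.0, 139.0)
    dbp = measure("dbp_ge90", 90.0, 105.0, 65.0, 89.0)
    tc = measure("tc_ge52", 5.2, 7.0, 3.5, 5.19)
    tg = measure("tg_ge17", 1.7, 4.0, 0.6, 1.69)
    eq5d_bl = measure("hrqol_ge09", 0.9, 1.0, 0.6, 0.89)

    # endpoint HbA1c consistent with the drawn control indicator
    ctrl = out["hba1c_control"].astype(bool)
    end_hba1c = _uniform_band(rng, n, 6.5, 9.5)
    end_hba1c[ctrl] = _uniform_band(rng, ctrl.sum(), 5.6, 6.49)

    adherent = rng.random(n) < config.adherence_prob
    records = []
    for i in range(n):
        arm = ARMS[arm_idx[i]]
        base = _ARM_BASELINE_DRUGS[arm]
        records.append(PatientRecord(
            patient_id=f"S{i:05d}", city=city[i], age_years=float(age[i]),
            male=int(ind("male")[i]), education=int(education[i]),
            income_band=int(income[i]), insurance=insurance[i],
            smoking=int(ind("smoking")[i]), drinking=int(ind("drinking")[i]),
            exercise=int(ind("exercise")[i]),
            diet_control=int(ind("diet_control")[i]),
            duration_band=int(duration[i]),
            heart_disease=int(ind("heart_disease")[i]),
            hypertension=int(ind("hypertension")[i]),
            dyslipidemia=int(ind("dyslipidemia")[i]),
            stroke=int(ind("stroke")[i]),
            bmi=float(bmi[i]), fbs=float(fbs[i]), hba1c=float(hba1c[i]),
            sbp=float(sbp[i]), dbp=float(dbp[i]), tc=float(tc[i]),
            tg=float(tg[i]), eq5d_baseline=float(eq5d_bl[i]),
            hypo_baseline=int(ind("hypo_bl")[i]),
            drugs_baseline=base,
            drugs_followup=_followups(base, bool(adherent[i]), rng),
            hypo_flags=tuple(int(f) for f in out["hypo_flags"][i]),
            endpoint_hba1c=float(end_hba1c[i]),
            endpoint_eq5d=float(out["eq5d"][i]),
            cost_inpatient=float(out["cost_inpatient"][i]),
            cost_outpatient=float(out["cost_outpatient"][i]),
            cost_otc=float(out["cost_otc"][i]),
        ))
    return records


def true_potential_margins(config: SimulationConfig | None = None,
                           n: int = 300_000,
                           seed: int = 20_211_028) -> pd.DataFrame:
    """Forced-arm Monte-Carlo oracle for the generator's true estimand.

    Draws a large unconfounded covariate sample and, for every arm, the
    potential outcome with that arm forced on every patient; the per-arm
    means are the potential-outcome margins implied by the configured
    mechanism *including* clipping and zero-truncation. Independent of
    every estimator in the package.

    Returns an arms x outcomes DataFrame (with the derived total cost) and
    attaches the Monte-Carlo standard errors as ``.attrs["se"]``.
    """
    config = config or SimulationConfig()
    config.validate()
    rng = np.random.default_rng(seed)
    X = _draw_covariates(config, n, rng)
    rows, se_rows = {}, {}
    for k, arm in enumerate(ARMS):
        out = _draw_outcomes(config, X, np.full(n, k, dtype=int), rng)
        rows[arm] = {o: float(np.mean(out[o]))
                     for o in (*COMPONENT_OUTCOMES, "cost_total")}
        se_rows[arm] = {o: float(np.std(out[o], ddof=1) / math.sqrt(n))
                        for o in (*COMPONENT_OUTCOMES, "cost_total")}
    res = pd.DataFrame(rows).T.loc[list(ARMS)]
    res.attrs["se"] = pd.DataFrame(se_rows).T.loc[list(ARMS)]
    return res


# --------------------------------------------------------------------------
# Deterministic fixture reproducing the published arm and city counts
# --------------------------------------------------------------------------

# Published unadjusted subgroup means, used as the fixture's constant
# outcome values per arm so subgroup summaries reproduce the printed table.
_FIXTURE_MEANS = {
    "hba1c_control": (0.33, 0.50, 0.20, 0.41, 0.45, 0.54, 0.25, 0.34),
    "hypo_incidence": (0.38, 0.50, 0.72, 0.49, 0.33, 0.27, 0.50, 0.39),
    "eq5d": (0.89, 0.90, 0.87, 0.86, 0.89, 0.88, 0.88, 0.89),
    "cost_inpatient": (4.22, 1.29, 4.14, 2.06, 4.36, 1.43, 1.04, 3.16),
    "cost_outpatient": (3.13, 1.96, 2.56, 2.48, 5.94, 3.82, 0.83, 5.57),
    "cost_otc": (0.98, 1.10, 2.50, 0.62, 1.07, 0.67, 0.55, 0.69),
}


def make_paper_fixture() -> list:
    """Deterministic 1903-patient fixture with the published arm counts
    (203/233/137/128/110/177/12/903) and city counts (Shenyang 440,
    Beijing 314, Chengdu 403, Nanjing 366, Guangzhou 380).

    This is a synthetic stand-in for the study's non-deposited survey data:
    arm sizes, city sizes and the per-arm outcome means reproduce the
    printed tables; everything else is filled with fixed valid values.
    Binary and count outcomes are integer-valued per patient, distributed
    so each arm's mean matches the printed subgroup mean to within rounding
    of n * mean.
    """
    rng = np.random.default_rng(1903)
    city_seq = np.concatenate([np.repeat(c, k) for c, k in
                               CITY_COUNTS.items()])
    rng.shuffle(city_seq)
    records = []
    i = 0
    for a, arm in enumerate(ARMS):
        n_a = TABLE2_ARM_COUNTS[arm]
        base = _ARM_BASELINE_DRUGS[arm]
        n_ctrl = round(n_a * _FIXTURE_MEANS["hba1c_control"][a])
        n_hypo = round(n_a * _FIXTURE_MEANS["hypo_incidence"][a])
        for j in range(n_a):
            ctrl = j < n_ctrl
            hypo = 1 if j < n_hypo else 0
            records.append(PatientRecord(
                patient_id=f"P{i:04d}", city=str(city_seq[i]),
                age_years=55.0, male=0, education=2, income_band=2,
                insurance="UEBMI", smoking=0, drinking=0, exercise=1,
                diet_control=1, duration_band=1, heart_disease=0,
                hypertension=0, dyslipidemia=0, stroke=0,
                bmi=23.0, fbs=6.0, hba1c=7.0, sbp=120.0, dbp=80.0,
                tc=4.5, tg=1.2, eq5d_baseline=0.85, hypo_baseline=0,
                drugs_baseline=base, drugs_followup=(base,) * 4,
                hypo_flags=(hypo, 0, 0, 0),
                endpoint_hba1c=6.0 if ctrl else 7.5,
                endpoint_eq5d=_FIXTURE_MEANS["eq5d"][a],
                cost_inpatient=_FIXTURE_MEANS["cost_inpatient"][a],
                cost_outpatient=_FIXTURE_MEANS["cost_outpatient"][a],
                cost_otc=_FIXTURE_MEANS["cost_otc"][a],
            ))
            i += 1
    return records
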