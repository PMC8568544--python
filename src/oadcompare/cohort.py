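"""Cohort data model for a multi-arm comparison of oral antidiabetic therapies.

One patient per record: baseline covariates, the drug regimen observed at the
baseline survey and at four quarterly follow-ups, and endpoint outcomes
(glycemic control, hypoglycemia incidence, EQ-5D utility, and three cost
components in 1000-RMB units).

Therapies are classified into eight arms: the five most prevalent
monotherapies (metformin, Xiaoke Pill, other TCMs, gliclazide, acarbose),
glibenclamide (kept despite its small size because it is the chemical
substance of the Xiaoke Pill), Xiaoke Pill combination therapy, and a pooled
"Others" arm. Arm membership is defined either intent-to-treat (baseline
regimen) or on-treatment (patients whose regimen never changed).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ARMS",
    "CITIES",
    "INSURANCE_TYPES",
    "COVARIATE_COLUMNS",
    "DUMMY_GROUPS",
    "OUTCOME_COLUMNS",
    "CohortError",
    "MissingDataError",
    "UnknownDrugWarning",
    "PatientRecord",
    "normalize_drug",
    "classify_therapy",
    "build_covariates",
    "covariate_matrix",
    "define_cohorts",
    "derive_outcomes",
    "outcome_table",
    "read_cohort_csv",
    "write_cohort_csv",
]

CITIES = ("Beijing", "Shenyang", "Chengdu", "Nanjing", "Guangzhou")
INSURANCE_TYPES = ("URBMI", "UEBMI", "NRCM", "government")

ARM_METFORMIN = "Metformin"
ARM_XIAOKE = "XiaokePill"
ARM_TCMS = "OtherTCMs"
ARM_GLICLAZIDE = "Gliclazide"
ARM_ACARBOSE = "Acarbose"
ARM_XIAOKE_PLUS = "XiaokePillPlus"
ARM_GLIBENCLAMIDE = "Glibenclamide"
ARM_OTHERS = "Others"

#: The eight therapy arms, reference (metformin) first.
ARMS = (
    ARM_METFORMIN,
    ARM_XIAOKE,
    ARM_TCMS,
    ARM_GLICLAZIDE,
    ARM_ACARBOSE,
    ARM_XIAOKE_PLUS,
    ARM_GLIBENCLAMIDE,
    ARM_OTHERS,
)

XIAOKE_PILL = "Xiaoke Pill"
TCMS = "TCMs"

#: The 15 monitored oral agents (13 chemical agents plus TCMs and the Xiaoke Pill).
MONITORED_DRUGS = (
    "metformin",
    "phenformin",
    "glibenclamide",
    "glipizide",
    "gliquidone",
    "gliclazide",
    "glimepiride",
    "acarbose",
    "voglibose",
    "repaglinide",
    "nateglinide",
    "rosiglitazone",
    "pioglitazone",
    TCMS,
    XIAOKE_PILL,
)

_CANONICAL = {d.lower(): d for d in MONITORED_DRUGS}
_CANONICAL.update({"tcm": TCMS, "other tcms": TCMS, "xiaoke": XIAOKE_PILL,
                   "xiao ke wan": XIAOKE_PILL})

_MONOTHERAPY_ARMS = {
    "metformin": ARM_METFORMIN,
    XIAOKE_PILL: ARM_XIAOKE,
    TCMS: ARM_TCMS,
    "gliclazide": ARM_GLICLAZIDE,
    "acarbose": ARM_ACARBOSE,
    "glibenclamide": ARM_GLIBENCLAMIDE,
}


class CohortError(ValueError):
    """Invalid cohort input (empty therapy, insulin use, negative cost, ...)."""


class MissingDataError(CohortError):
    """A required baseline or endpoint measure is absent; no silent imputation."""


class UnknownDrugWarning(UserWarning):
    """A drug name outside the monitored dictionary; classified under Others."""


def normalize_drug(name: str) -> str | None:
    """Normalize a drug name to its canonical form, or None if unknown.

    Matching is case-insensitive with whitespace collapsed. Insulin in any
    form raises :class:`CohortError` — insulin users are excluded upstream.
    """
    key = " ".join(str(name).strip().lower().split())
    if not key:
        raise CohortError("empty drug name")
    if "insulin" in key:
        raise CohortError(f"insulin user cannot be classified (got {name!r}); "
                          "insulin users are excluded at screening")
    return _CANONICAL.get(key)


def classify_therapy(drugs: Iterable[str]) -> str:
    """Map a set of drug names to one of the eight therapy arms.

    Singleton sets map to the matching monotherapy arm where one exists
    (metformin, Xiaoke Pill, TCMs, gliclazide, acarbose, glibenclamide);
    any multi-drug set containing the Xiaoke Pill maps to the Xiaoke Pill
    combination arm; everything else is pooled under Others. Unknown drug
    names are admitted with a warning (the observed plans include drugs
    outside the 15 monitored agents) and count toward Others.
    """
    drugs = set(drugs)
    if not drugs:
        raise CohortError("empty therapy: at least one oral agent required")
    canon = set()
    for d in drugs:
        c = normalize_drug(d)
        if c is None:
            warnings.warn(
                f"unknown drug name {d!r}; counted toward the Others arm",
                UnknownDrugWarning, stacklevel=2)
            c = " ".join(str(d).strip().lower().split())
        canon.add(c)
    if len(canon) == 1:
        (only,) = canon
        return _MONOTHERAPY_ARMS.get(only, ARM_OTHERS)
    if XIAOKE_PILL in canon:
        return ARM_XIAOKE_PLUS
    return ARM_OTHERS


# --------------------------------------------------------------------------
# Patient record
# --------------------------------------------------------------------------

@dataclass
class PatientRecord:
    """One subject: baseline covariates, drug history, endpoint outcomes.

    Costs are annual totals in 1000-RMB units; EQ-5D utilities live in [0, 1];
    ``drugs_followup`` and ``hypo_flags`` always have exactly four entries,
    one per quarterly follow-up survey.
    """

    patient_id: str
    city: str
    age_years: float
    male: int
    education: int          # 1 primary or below (ref) .. 4 tertiary
    income_band: int        # 1 <1000 RMB/month (ref), 2 1000-2000, 3 >2000
    insurance: str          # URBMI (ref), UEBMI, NRCM, government
    smoking: int
    drinking: int
    exercise: int
    diet_control: int
    duration_band: int      # 1 <5 years (ref), 2 5-10, 3 >10
    heart_disease: int
    hypertension: int
    dyslipidemia: int
    stroke: int
    bmi: float
    fbs: float              # fasting blood sugar, mmol/L
    hba1c: float            # baseline HbA1c, %
    sbp: float              # mmHg
    dbp: float              # mmHg
    tc: float               # total cholesterol, mmol/L
    tg: float               # triglycerides, mmol/L
    eq5d_baseline: float
    hypo_baseline: int
    drugs_baseline: frozenset = field(default_factory=frozenset)
    drugs_followup: tuple = ()
    hypo_flags: tuple = ()
    endpoint_hba1c: float = np.nan
    endpoint_eq5d: float = np.nan
    cost_inpatient: float = 0.0
    cost_outpatient: float = 0.0
    cost_otc: float = 0.0

    def __post_init__(self):
        self.drugs_baseline = frozenset(self.drugs_baseline)
        self.drugs_followup = tuple(frozenset(s) for s in self.drugs_followup)
        self.hypo_flags = tuple(int(f) for f in self.hypo_flags)
        if len(self.drugs_followup) != 4:
            raise CohortError(
                f"patient {self.patient_id}: expected 4 follow-up drug sets, "
                f"got {len(self.drugs_followup)}")
        if len(self.hypo_flags) != 4:
            raise CohortError(
                f"patient {self.patient_id}: expected 4 hypoglycemia flags, "
                f"got {len(self.hypo_flags)}")
        for label, c in (("inpatient", self.cost_inpatient),
                         ("outpatient", self.cost_outpatient),
                         ("OTC", self.cost_otc)):
            if c is not None and np.isfinite(c) and c < 0:
                raise CohortError(
                    f"patient {self.patient_id}: negative {label} cost {c}")
        for label, v in (("baseline", self.eq5d_baseline),
                         ("endpoint", self.endpoint_eq5d)):
            if v is not None and np.isfinite(v) and not (0.0 <= v <= 1.0):
                raise CohortError(
                    f"patient {self.patient_id}: {label} EQ-5D {v} outside [0, 1]")


# --------------------------------------------------------------------------
# Covariate construction (clinical cutoffs)
# --------------------------------------------------------------------------

#: The 35 binary control indicators, in the order the balance table reports them.
COVARIATE_COLUMNS = (
    "age_50_60", "age_60_70", "age_ge70",
    "male",
    "edu_lower_sec", "edu_upper_sec", "edu_tertiary",
    "city_shenyang", "city_chengdu", "city_nanjing", "city_guangzhou",
    "income_mid", "income_high",
    "ins_uebmi", "ins_nrcm", "ins_gov",
    "smoking", "drinking", "exercise", "diet_control",
    "duration_5_10", "duration_ge10",
    "heart_disease", "hypertension", "dyslipidemia", "stroke",
    "bmi_ge24",
    "hba1c_ctrl_bl",
    "fbs_lt7",
    "hypo_bl",
    "sbp_ge140", "dbp_ge90", "tc_ge52", "tg_ge17",
    "hrqol_ge09",
)

#: Mutually exclusive dummy groups (reference category encoded all-zero).
DUMMY_GROUPS = {
    "age": ("age_50_60", "age_60_70", "age_ge70"),
    "education": ("edu_lower_sec", "edu_upper_sec", "edu_tertiary"),
    "city": ("city_shenyang", "city_chengdu", "city_nanjing", "city_guangzhou"),
    "income": ("income_mid", "income_high"),
    "insurance": ("ins_uebmi", "ins_nrcm", "ins_gov"),
    "duration": ("duration_5_10", "duration_ge10"),
}

_REQUIRED_BASELINE = (
    "age_years", "bmi", "fbs", "hba1c", "sbp", "dbp", "tc", "tg",
    "eq5d_baseline",
)


def build_covariates(record: PatientRecord) -> dict:
    """Build the 35 binary control indicators for one patient.

    Continuous baseline measures are dichotomized at the clinical cutoffs:
    BMI >= 24, baseline HbA1c < 6.5 % (glycemic control at baseline),
    FBS < 7 mmol/L, SBP >= 140 mmHg, DBP >= 90 mmHg, TC >= 5.2 mmol/L,
    TG >= 1.7 mmol/L, and EQ-5D >= 0.9. Reference categories of the
    categorical factors (age < 50, primary education, Beijing, lowest
    income band, URBMI, duration < 5 years) are encoded all-zero.

    Raises
    ------
    MissingDataError
        If any required baseline measure is missing or non-finite.
    """
    missing = [f for f in _REQUIRED_BASELINE
               if getattr(record, f) is None
               or not np.isfinite(getattr(record, f))]
    if missing:
        raise MissingDataError(
            f"patient {record.patient_id}: missing baseline measures "
            f"{missing}; complete-case analysis admits no imputation")
    r = record
    v = dict.fromkeys(COVARIATE_COLUMNS, 0)
    v["age_50_60"] = int(50 <= r.age_years < 60)
    v["age_60_70"] = int(60 <= r.age_years < 70)
    v["age_ge70"] = int(r.age_years >= 70)
    v["male"] = int(r.male)
    v["edu_lower_sec"] = int(r.education == 2)
    v["edu_upper_sec"] = int(r.education == 3)
    v["edu_tertiary"] = int(r.education == 4)
    v["city_shenyang"] = int(r.city == "Shenyang")
    v["city_chengdu"] = int(r.city == "Chengdu")
    v["city_nanjing"] = int(r.city == "Nanjing")
    v["city_guangzhou"] = int(r.city == "Guangzhou")
    v["income_mid"] = int(r.income_band == 2)
    v["income_high"] = int(r.income_band == 3)
    v["ins_uebmi"] = int(r.insurance == "UEBMI")
    v["ins_nrcm"] = int(r.insurance == "NRCM")
    v["ins_gov"] = int(r.insurance == "government")
    v["smoking"] = int(r.smoking)
    v["drinking"] = int(r.drinking)
    v["exercise"] = int(r.exercise)
    v["diet_control"] = int(r.diet_control)
    v["duration_5_10"] = int(r.duration_band == 2)
    v["duration_ge10"] = int(r.duration_band == 3)
    v["heart_disease"] = int(r.heart_disease)
    v["hypertension"] = int(r.hypertension)
    v["dyslipidemia"] = int(r.dyslipidemia)
    v["stroke"] = int(r.stroke)
    v["bmi_ge24"] = int(r.bmi >= 24)
    v["hba1c_ctrl_bl"] = int(r.hba1c < 6.5)
    v["fbs_lt7"] = int(r.fbs < 7)
    v["hypo_bl"] = int(r.hypo_baseline)
    v["sbp_ge140"] = int(r.sbp >= 140)
    v["dbp_ge90"] = int(r.dbp >= 90)
    v["tc_ge52"] = int(r.tc >= 5.2)
    v["tg_ge17"] = int(r.tg >= 1.7)
    v["hrqol_ge09"] = int(r.eq5d_baseline >= 0.9)
    return v


def covariate_matrix(records: Sequence[PatientRecord]) -> pd.DataFrame:
    """Stack per-patient indicators into an n x 35 DataFrame (patient_id index)."""
    rows = [build_covariates(r) for r in records]
    return pd.DataFrame(rows, index=pd.Index(
        [r.patient_id for r in records], name="patient_id"),
        columns=list(COVARIATE_COLUMNS))


# --------------------------------------------------------------------------
# Cohort definitions
# --------------------------------------------------------------------------

def define_cohorts(records: Sequence[PatientRecord]):
    """Assign therapy arms under the intent-to-treat and on-treatment rules.

    The ITT arm is classified from the baseline regimen. The on-treatment
    cohort keeps a patient if and only if all four follow-up drug sets equal
    the baseline set (no discontinuation, switching, or add-on), with the
    arm label unchanged.

    Returns
    -------
    (itt, on_treatment) : tuple of DataFrame
        Each with columns ``patient_id``, ``arm``, ``regime``.
    """
    itt_rows, ot_rows = [], []
    for r in records:
        arm = classify_therapy(r.drugs_baseline)
        itt_rows.append({"patient_id": r.patient_id, "arm": arm,
                         "regime": "ITT"})
        if all(fs == r.drugs_baseline for fs in r.drugs_followup):
            ot_rows.append({"patient_id": r.patient_id, "arm": arm,
                            "regime": "on_treatment"})
    cols = ["patient_id", "arm", "regime"]
    return (pd.DataFrame(itt_rows, columns=cols),
            pd.DataFrame(ot_rows, columns=cols))


# --------------------------------------------------------------------------
# Derived outcomes
# --------------------------------------------------------------------------

OUTCOME_COLUMNS = (
    "hba1c_control", "hypo_incidence", "eq5d",
    "cost_inpatient", "cost_outpatient", "cost_otc", "cost_total",
)

#: Outcomes fit by every estimator, in reporting order.
PRIMARY_OUTCOMES = OUTCOME_COLUMNS


def derive_outcomes(record: PatientRecord) -> dict:
    """Derive the endpoint outcome vector for one patient.

    Glycemic control is the strict target ``endpoint HbA1c < 6.5 %``,
    hypoglycemia incidence is the sum of the four follow-up adverse-event
    flags (range 0-4), and total cost is the exact sum of the inpatient,
    outpatient, and OTC components.
    """
    r = record
    if r.endpoint_hba1c is None or not np.isfinite(r.endpoint_hba1c):
        raise MissingDataError(
            f"patient {r.patient_id}: missing endpoint HbA1c")
    if r.endpoint_eq5d is None or not np.isfinite(r.endpoint_eq5d):
        raise MissingDataError(
            f"patient {r.patient_id}: missing endpoint EQ-5D")
    for label, c in (("inpatient", r.cost_inpatient),
                     ("outpatient", r.cost_outpatient),
                     ("OTC", r.cost_otc)):
        if c is None or not np.isfinite(c):
            raise MissingDataError(
                f"patient {r.patient_id}: missing {label} cost")
        if c < 0:
            raise CohortError(
                f"patient {r.patient_id}: negative {label} cost {c}")
    return {
        "hba1c_control": int(r.endpoint_hba1c < 6.5),
        "hypo_incidence": int(sum(r.hypo_flags)),
        "eq5d": float(r.endpoint_eq5d),
        "cost_inpatient": float(r.cost_inpatient),
        "cost_outpatient": float(r.cost_outpatient),
        "cost_otc": float(r.cost_otc),
        "cost_total": float(r.cost_inpatient + r.cost_outpatient + r.cost_otc),
    }


def outcome_table(records: Sequence[PatientRecord]) -> pd.DataFrame:
    """Stack per-patient outcome vectors (patient_id index)."""
    rows = [derive_outcomes(r) for r in records]
    return pd.DataFrame(rows, index=pd.Index(
        [r.patient_id for r in records], name="patient_id"),
        columns=list(OUTCOME_COLUMNS))


# --------------------------------------------------------------------------
# CSV interfaces
# --------------------------------------------------------------------------

_BASELINE_FIELDS = (
    "patient_id", "city", "age_years", "male", "education", "income_band",
    "insurance", "smoking", "drinking", "exercise", "diet_control",
    "duration_band", "heart_disease", "hypertension", "dyslipidemia",
    "stroke", "bmi", "fbs", "hba1c", "sbp", "dbp", "tc", "tg",
    "eq5d_baseline", "hypo_baseline", "drugs_baseline",
    "endpoint_hba1c", "endpoint_eq5d",
    "cost_inpatient", "cost_outpatient", "cost_otc",
)


def write_cohort_csv(records: Sequence[PatientRecord], baseline_path,
                     followup_path) -> None:
    """Write one baseline+outcome CSV and one long-format follow-up CSV.

    Drug sets are serialized as semicolon-delimited, alphabetically sorted
    names; the follow-up file holds one row per patient per wave with the
    wave's regimen and hypoglycemia flag.
    """
    base_rows = []
    fu_rows = []
    for r in records:
        row = {f: getattr(r, f) for f in _BASELINE_FIELDS
               if f != "drugs_baseline"}
        row["drugs_baseline"] = ";".join(sorted(r.drugs_baseline))
        base_rows.append(row)
        for wave, (ds, flag) in enumerate(zip(r.drugs_followup, r.hypo_flags),
                                          start=1):
            fu_rows.append({"patient_id": r.patient_id, "wave": wave,
                            "drugs": ";".join(sorted(ds)),
                            "hypo_flag": int(flag)})
    pd.DataFrame(base_rows, columns=list(_BASELINE_FIELDS)).to_csv(
        baseline_path, index=False)
    pd.DataFrame(fu_rows, columns=["patient_id", "wave", "drugs",
                                   "hypo_flag"]).to_csv(
        followup_path, index=False)


def read_cohort_csv(baseline_path, followup_path) -> list[PatientRecord]:
    """Read the CSV pair written by :func:`write_cohort_csv`."""
    base = pd.read_csv(baseline_path, dtype={"patient_id": str})
    fu = pd.read_csv(followup_path, dtype={"patient_id": str})
    fu_by_pid: dict[str, dict[int, tuple]] = {}
    for row in fu.itertuples(index=False):
        drugs = frozenset(d for d in str(row.drugs).split(";") if d)
        fu_by_pid.setdefault(row.patient_id, {})[int(row.wave)] = (
            drugs, int(row.hypo_flag))
    records = []
    for row in base.itertuples(index=False):
        d = row._asdict()
        pid = d["patient_id"]
        waves = fu_by_pid.get(pid, {})
        if sorted(waves) != [1, 2, 3, 4]:
            raise CohortError(
                f"patient {pid}: expected follow-up waves 1-4, got "
                f"{sorted(waves)}")
        d["drugs_baseline"] = frozenset(
            x for x in str(d["drugs_baseline"]).split(";") if x)
        d["drugs_followup"] = tuple(waves[w][0] for w in (1, 2, 3, 4))
        d["hypo_flags"] = tuple(waves[w][1] for w in (1, 2, 3, 4))
        records.append(PatientRecord(**d))
    return records
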