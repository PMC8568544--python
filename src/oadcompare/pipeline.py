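"""End-to-end report pipeline: simulate/load -> classify -> describe ->
adjust -> weight -> double-select, emitting plain-CSV table analogues.

Outputs (all CSV, plus a JSON manifest) mirror the study's reporting:
arm counts, baseline balance, unadjusted subgroup means with letter groups,
adjusted coefficients and predictive margins, inverse-probability-weighted
outcomes and weighted balance, the variable-selection grid, and the
double-selection margins.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .cohort import (OUTCOME_COLUMNS, CohortError, covariate_matrix,
                     define_cohorts, outcome_table, read_cohort_csv,
                     write_cohort_csv)
from .descriptives import arm_table, balance_table, subgroup_summary
from .dslasso import build_candidate_pool, double_select, post_selection_fit
from .ipw import compute_weights, fit_propensity, merge_small_arms, \
    weighted_balance, weighted_outcomes
from .margins import coefficient_table, fit_outcome_model, predictive_margins
from .simulate import SimulationConfig, generate_cohort

log = logging.getLogger("oadcompare")

_FLOAT_FMT = "%.10g"


@dataclass
class PipelineConfig:
    """Run configuration: input mode, regime, estimators, seed, outputs."""

    mode: str = "synthetic"             # "synthetic" | "files"
    baseline_csv: str | None = None
    followup_csv: str | None = None
    regime: str = "ITT"                 # "ITT" | "on_treatment"
    estimators: tuple = ("describe", "adjust", "ipw", "dslasso")
    alpha: float = 0.05
    seed: int = 0
    n_patients: int = 1903
    output_dir: str = "oadcompare_report"

    def __post_init__(self):
        if self.regime not in ("ITT", "on_treatment"):
            raise ValueError(f"invalid regime {self.regime!r}")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError(f"alpha {self.alpha} outside (0, 1)")
        if self.mode not in ("synthetic", "files"):
            raise ValueError(f"invalid mode {self.mode!r}")
        if self.mode == "files" and not (self.baseline_csv
                                         and self.followup_csv):
            raise ValueError("files mode requires baseline_csv and "
                             "followup_csv")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "estimators" in raw:
            raw["estimators"] = tuple(raw["estimators"])
        return cls(**raw)

    def digest(self) -> str:
        payload = {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in self.__dict__.items()}
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True).encode()).hexdigest()[:16]


def _write(df: pd.DataFrame, path: Path, index_label=None) -> None:
    df.to_csv(path, float_format=_FLOAT_FMT,
              index_label=index_label or df.index.name)


def _stage(name):
    log.info("stage %s", name)
    return time.perf_counter()


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the configured stages; returns {table name: DataFrame}.

    Every emitted file is plain CSV; the manifest records seed, config
    hash, and package version so a bundle is reproducible byte-for-byte
    from its manifest.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundle: dict[str, pd.DataFrame] = {}

    t0 = _stage("load")
    if config.mode == "synthetic":
        sim = SimulationConfig(n_patients=config.n_patients,
                               seed=config.seed)
        records = generate_cohort(sim)
    else:
        records = read_cohort_csv(config.baseline_csv, config.followup_csv)
    log.info("loaded %d records in %.2fs", len(records),
             time.perf_counter() - t0)

    t0 = _stage("classify")
    itt, on_treatment = define_cohorts(records)
    assign = itt if config.regime == "ITT" else on_treatment
    keep = set(assign["patient_id"])
    records = [r for r in records if r.patient_id in keep]
    arms = assign.set_index("patient_id")["arm"].loc[
        [r.patient_id for r in records]].reset_index(drop=True)
    X = covariate_matrix(records).reset_index(drop=True)
    Y = outcome_table(records).reset_index(drop=True)
    log.info("%s cohort: n=%d (%.2fs)", config.regime, len(records),
             time.perf_counter() - t0)

    bundle["arm_counts"] = arm_table(arms)
    bundle["assignments"] = assign
    bundle["outcomes"] = Y
    bundle["baseline_balance"] = balance_table(X, arms)

    if "describe" in config.estimators:
        t0 = _stage("describe")
        rows = {}
        for o in OUTCOME_COLUMNS:
            tab = subgroup_summary(Y[o], arms, alpha=config.alpha)
            for a in tab.index:
                rows.setdefault(a, {})
                rows[a][f"{o}"] = tab.loc[a, "estimate"]
                rows[a][f"{o}_se"] = tab.loc[a, "se"]
                rows[a][f"{o}_letters"] = tab.loc[a, "letters"]
        tab = pd.DataFrame(rows).T
        tab.index.name = "arm"
        bundle["unadjusted_outcomes"] = tab
        log.info("describe done (%.2fs)", time.perf_counter() - t0)

    if "adjust" in config.estimators:
        t0 = _stage("adjust")
        coef_tables, marg_rows = [], {}
        for o in OUTCOME_COLUMNS:
            fit = fit_outcome_model(Y[o], arms, covariates=X)
            ct = coefficient_table(fit)
            ct.insert(0, "outcome", o)
            coef_tables.append(ct)
            marg = predictive_margins(fit, covariates=X, alpha=config.alpha)
            for a in marg.index:
                marg_rows.setdefault(a, {})
                marg_rows[a][o] = marg.loc[a, "margin"]
                marg_rows[a][f"{o}_se"] = marg.loc[a, "se"]
                marg_rows[a][f"{o}_letters"] = marg.loc[a, "letters"]
        bundle["adjusted_coefficients"] = pd.concat(coef_tables)
        tab = pd.DataFrame(marg_rows).T
        tab.index.name = "arm"
        bundle["adjusted_margins"] = tab
        log.info("adjust done (%.2fs)", time.perf_counter() - t0)

    if "ipw" in config.estimators:
        t0 = _stage("ipw")
        pfit = fit_propensity(arms, X)
        merged_arms, _ = merge_small_arms(arms)
        w = compute_weights(pfit, merged_arms)
        rows = {}
        for o in OUTCOME_COLUMNS:
            tab = weighted_outcomes(Y[o], merged_arms, w,
                                    alpha=config.alpha)
            for a in tab.index:
                rows.setdefault(a, {})
                rows[a][o] = tab.loc[a, "estimate"]
                rows[a][f"{o}_se"] = tab.loc[a, "se"]
        tab = pd.DataFrame(rows).T
        tab.index.name = "arm"
        bundle["ipw_outcomes"] = tab
        bundle["ipw_balance"] = weighted_balance(X, merged_arms, w)
        log.info("ipw done (%.2fs); propensity gradient norm %.1e",
                 time.perf_counter() - t0, pfit.gradient_norm)

    if "dslasso" in config.estimators:
        t0 = _stage("dslasso")
        pool = build_candidate_pool(X)
        sel_marks = pd.DataFrame("", index=pool.columns,
                                 columns=list(OUTCOME_COLUMNS))
        sel_marks.index.name = "candidate"
        marg_rows = {}
        for o in OUTCOME_COLUMNS:
            sel = double_select(Y[o], arms, pool)
            sel_marks.loc[sel.union, o] = "Y"
            _, marg = post_selection_fit(Y[o], arms, pool, sel.union,
                                         alpha=config.alpha)
            for a in marg.index:
                marg_rows.setdefault(a, {})
                marg_rows[a][o] = marg.loc[a, "margin"]
                marg_rows[a][f"{o}_se"] = marg.loc[a, "se"]
                marg_rows[a][f"{o}_letters"] = marg.loc[a, "letters"]
        bundle["selected_variables"] = sel_marks
        tab = pd.DataFrame(marg_rows).T
        tab.index.name = "arm"
        bundle["double_selection_margins"] = tab
        log.info("dslasso done (%.2fs)", time.perf_counter() - t0)

    for name, df in bundle.items():
        _write(df, out / f"{name}.csv")
    manifest = {"package_version": __version__, "seed": config.seed,
                "regime": config.regime, "n": len(records),
                "config_sha256": config.digest(),
                "tables": sorted(bundle)}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                  sort_keys=True) + "\n")
    return bundle


def simulate_to_csv(n_patients: int, seed: int, baseline_csv,
                    followup_csv) -> int:
    """Generate a synthetic cohort and write the CSV pair; returns n."""
    records = generate_cohort(SimulationConfig(n_patients=n_patients,
                                               seed=seed))
    write_cohort_csv(records, baseline_csv, followup_csv)
    return len(records)
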