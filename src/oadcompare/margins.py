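"""Covariate-adjusted treatment effects and predictive margins.

Outcome model: ordinary least squares of the outcome on an intercept, seven
treatment dummies (metformin is the reference arm), and the 35 baseline
indicators. Predictive margins are the G-computation averages — fix every
patient's arm, predict, and average over the sample's covariates — with
delta-method standard errors from the coefficient covariance. For a linear
model the margin contrast against the reference equals the arm coefficient
exactly, and with no covariates the margins collapse to subgroup means.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .cohort import ARMS, ARM_METFORMIN
from .descriptives import compact_letters, _arm_order

__all__ = [
    "OutcomeModelFit",
    "fit_outcome_model",
    "predictive_margins",
    "arm_dummies",
    "significance_stars",
    "coefficient_table",
]


def significance_stars(p: float) -> str:
    """Stars at the 0.10 / 0.05 / 0.01 two-sided levels."""
    return "***" if p < 0.01 else "**" if p < 0.05 else "*" if p < 0.10 else ""


def arm_dummies(arms, reference: str = ARM_METFORMIN,
                order=ARMS) -> pd.DataFrame:
    """0/1 indicator columns for every non-reference arm, in canonical order."""
    arms = pd.Series(arms)
    cols = [a for a in order if a != reference and (arms == a).any()]
    extra = [a for a in pd.unique(arms) if a not in order and a != reference]
    out = pd.DataFrame({a: (arms == a).astype(int) for a in [*cols, *extra]})
    out.index = arms.index
    return out


@dataclass
class OutcomeModelFit:
    """OLS fit of one outcome on arm dummies and covariates."""

    params: pd.Series
    cov_params: pd.DataFrame
    bse: pd.Series
    pvalues: pd.Series
    resid_var: float
    nobs: int
    arm_columns: list
    covariate_columns: list
    reference: str
    results: object = None      # underlying statsmodels results

    @property
    def arm_effects(self) -> pd.DataFrame:
        """Treatment contrasts versus the reference arm, with SEs and stars."""
        rows = {a: {"coef": self.params[a], "se": self.bse[a],
                    "p": self.pvalues[a],
                    "stars": significance_stars(self.pvalues[a])}
                for a in self.arm_columns}
        return pd.DataFrame(rows).T


def _check_rank(X: pd.DataFrame) -> None:
    """Raise with the names of collinear columns on rank deficiency."""
    A = X.to_numpy(dtype=float)
    rank = np.linalg.matrix_rank(A)
    if rank < A.shape[1]:
        # QR with pivoting: columns beyond the rank are linearly dependent
        from scipy.linalg import qr
        _, _, piv = qr(A, mode="economic", pivoting=True)
        bad = [X.columns[j] for j in sorted(piv[rank:])]
        raise np.linalg.LinAlgError(
            f"design matrix is rank deficient (rank {rank} of {A.shape[1]}); "
            f"collinear columns: {bad}")


def fit_outcome_model(outcome, arms, covariates: pd.DataFrame | None = None,
                      reference: str = ARM_METFORMIN,
                      robust: bool = False) -> OutcomeModelFit:
    """OLS of one outcome on arm dummies (+ optional covariates).

    Classical (homoskedastic) covariance by default, matching the study's
    reporting; ``robust=True`` switches to HC1. Requires n > p and a
    full-rank design; collinear columns are named in the error.
    """
    y = pd.Series(np.asarray(outcome, dtype=float)).reset_index(drop=True)
    arms = pd.Series(arms).reset_index(drop=True)
    D = arm_dummies(arms, reference=reference)
    parts = [pd.Series(1.0, index=y.index, name="const"), D]
    cov_cols = []
    if covariates is not None and covariates.shape[1] > 0:
        C = covariates.reset_index(drop=True).astype(float)
        cov_cols = list(C.columns)
        parts.append(C)
    X = pd.concat(parts, axis=1)
    if len(y) <= X.shape[1]:
        raise ValueError(f"n = {len(y)} must exceed p = {X.shape[1]}")
    _check_rank(X)
    res = sm.OLS(y, X).fit(cov_type="HC1" if robust else "nonrobust")
    return OutcomeModelFit(
        params=res.params, cov_params=res.cov_params(), bse=res.bse,
        pvalues=res.pvalues, resid_var=float(res.mse_resid),
        nobs=int(res.nobs), arm_columns=list(D.columns),
        covariate_columns=cov_cols, reference=reference, results=res)


def predictive_margins(fit: OutcomeModelFit,
                       covariates: pd.DataFrame | None = None,
                       alpha: float = 0.05,
                       letters: bool = True) -> pd.DataFrame:
    """Predictive margins per arm with delta-method SEs and letter groups.

    margin(arm) averages the model prediction over the estimation sample's
    covariate rows with the arm dummies set to that arm. The margin vector
    is G beta for a fixed gradient matrix G = [1, arm pattern, x-bar], so
    its covariance is G V G' with V the coefficient covariance (covariate
    means treated as fixed). The full margin covariance is attached as
    ``.attrs["cov"]`` and feeds the letter display.
    """
    if fit.covariate_columns:
        if covariates is None:
            raise ValueError("fit used covariates; their sample rows are "
                             "required to average over")
        missing = [c for c in fit.covariate_columns
                   if c not in covariates.columns]
        if missing:
            raise ValueError(f"covariate rows missing columns {missing}")
        xbar = covariates[fit.covariate_columns].astype(float).mean(axis=0)
    else:
        xbar = pd.Series(dtype=float)
    arms_out = [fit.reference, *fit.arm_columns]
    k = len(fit.params)
    G = np.zeros((len(arms_out), k))
    names = list(fit.params.index)
    for r, arm in enumerate(arms_out):
        g = pd.Series(0.0, index=names)
        g["const"] = 1.0
        if arm != fit.reference:
            g[arm] = 1.0
        for c, v in xbar.items():
            g[c] = v
        G[r] = g.to_numpy()
    beta = fit.params.to_numpy()
    V = fit.cov_params.to_numpy()
    m = G @ beta
    mcov = G @ V @ G.T
    order = _arm_order(arms_out)
    table = pd.DataFrame({"margin": m, "se": np.sqrt(np.diag(mcov))},
                         index=pd.Index(arms_out, name="arm")).loc[order]
    mcov = pd.DataFrame(mcov, index=arms_out, columns=arms_out) \
        .loc[order, order]
    table.attrs["cov"] = mcov
    if letters:
        from scipy import stats
        arms = list(table.index)
        p = pd.DataFrame(1.0, index=arms, columns=arms)
        for i, a in enumerate(arms):
            for b in arms[i + 1:]:
                var = (mcov.loc[a, a] + mcov.loc[b, b]
                       - 2.0 * mcov.loc[a, b])
                diff = table.loc[a, "margin"] - table.loc[b, "margin"]
                if var > 0:
                    pv = 2.0 * stats.norm.sf(abs(diff) / np.sqrt(var))
                else:
                    pv = 1.0 if diff == 0 else 0.0
                p.loc[a, b] = p.loc[b, a] = pv
        table["letters"] = pd.Series(compact_letters(p, alpha=alpha))
        table.attrs["pairwise_p"] = p
    return table


def coefficient_table(fit: OutcomeModelFit) -> pd.DataFrame:
    """Full coefficient listing (coef, SE, p, stars) in design order."""
    return pd.DataFrame({
        "coef": fit.params, "se": fit.bse, "p": fit.pvalues,
        "stars": [significance_stars(p) for p in fit.pvalues],
    })
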