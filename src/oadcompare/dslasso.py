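"""Double-selection adaptive lasso for multi-arm treatment effects.

The procedure:

1. select predictors of the outcome with an adaptive lasso over a candidate
   pool (35 main-effect indicators plus their interactions with the
   baseline glycemic-control indicator — 69 columns on the full schema);
2. select predictors of each of the seven treatment-arm indicators the same
   way (linear working model for the 0/1 indicator by default);
3. take the union of all selected sets;
4. refit the outcome by OLS on the arm dummies plus the union, and report
   predictive margins.

Selecting for the treatment equations as well as the outcome equation is
what protects the post-selection treatment effects from omitted-confounder
bias that a pure prediction lasso would introduce.

The adaptive penalty weights are |beta_init|^(-gamma) from a pilot OLS fit
(ridge fallback under rank deficiency), the penalty path is solved by
coordinate descent, and the penalty is tuned by minimizing the Gaussian BIC
n log(RSS/n) + df log(n) (extended BIC available).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.linear_model import lasso_path

from .cohort import ARMS, ARM_METFORMIN, COVARIATE_COLUMNS
from .margins import OutcomeModelFit, arm_dummies, fit_outcome_model, \
    predictive_margins

__all__ = [
    "build_candidate_pool",
    "adaptive_lasso_select",
    "double_select",
    "post_selection_fit",
    "SelectionResult",
    "DEFAULT_INTERACTION_ANCHOR",
]

#: Baseline glycemic-control indicator anchoring the interaction terms.
DEFAULT_INTERACTION_ANCHOR = "hba1c_ctrl_bl"


def build_candidate_pool(covariates: pd.DataFrame,
                         anchor: str = DEFAULT_INTERACTION_ANCHOR
                         ) -> pd.DataFrame:
    """Main effects plus anchor interactions, deduplicated.

    Every column interacts with the anchor except the anchor itself (a
    binary squared with itself reproduces the original column, the same
    reason squared terms are excluded altogether). Duplicate and constant
    columns are dropped deterministically, keeping the first occurrence in
    column order. On the full 35-indicator schema the pool has 69 columns.
    Column provenance is attached as ``.attrs["provenance"]``.
    """
    if anchor not in covariates.columns:
        raise ValueError(f"anchor column {anchor!r} not in covariates")
    cov = covariates.astype(float)
    bad = [c for c in cov.columns
           if not np.isin(cov[c].to_numpy(), (0.0, 1.0)).all()]
    if bad:
        raise ValueError(f"non-binary columns in interaction construction: "
                         f"{bad}")
    cols, provenance = {}, {}
    for c in cov.columns:
        if c not in cols:
            cols[c] = cov[c]
            provenance[c] = "main"
    a = cov[anchor]
    for c in cov.columns:
        if c == anchor:
            continue
        name = f"{c}_x_{anchor}"
        if name not in cols:
            cols[name] = cov[c] * a
            provenance[name] = "interaction"
    pool = pd.DataFrame(cols)
    # drop constant columns, then exact duplicates (keep first occurrence)
    keep = [c for c in pool.columns if pool[c].nunique() > 1]
    pool = pool[keep]
    seen: dict[bytes, str] = {}
    uniq = []
    for c in pool.columns:
        key = pool[c].to_numpy().tobytes()
        if key not in seen:
            seen[key] = c
            uniq.append(c)
    pool = pool[uniq]
    pool.attrs["provenance"] = {c: provenance[c] for c in pool.columns}
    return pool


def _bic(n: int, rss: np.ndarray, df: np.ndarray, p: int,
         kind: str) -> np.ndarray:
    rss = np.maximum(rss, 1e-12)
    bic = n * np.log(rss / n) + df * np.log(n)
    if kind == "extended":
        bic = bic + 2.0 * 0.5 * df * np.log(p)     # eBIC, gamma = 0.5
    elif kind != "gaussian":
        raise ValueError(f"unknown BIC kind {kind!r}")
    return bic


@dataclass
class AdaptiveLassoPath:
    """Penalty path and BIC-selected set from one adaptive lasso run."""

    selected: list
    alphas: np.ndarray
    bic: np.ndarray
    coefs: pd.DataFrame         # columns x alphas, original scale
    best_alpha: float
    weights: pd.Series
    ridge_fallback: bool


def adaptive_lasso_select(response, pool: pd.DataFrame, gamma: float = 1.0,
                          n_alphas: int = 80, eps: float = 1e-4,
                          bic: str = "gaussian",
                          tol: float = 1e-7) -> AdaptiveLassoPath:
    """Adaptive-lasso variable selection with BIC-tuned penalty.

    Columns are standardized and the response centered internally; penalty
    weights are |beta_init|^(-gamma) with beta_init from OLS on the
    standardized pool (ridge-initialized, with a warning, if that OLS is
    rank deficient). The weighted problem is solved as a plain lasso on the
    rescaled design X_j / w_j by coordinate descent over a log-spaced
    penalty grid; the reported selection minimizes the BIC. Selection is
    invariant to column order and to affine rescaling of the response.
    """
    y = np.asarray(response, dtype=float)
    X = pool.to_numpy(dtype=float)
    n, p = X.shape
    if n != len(y):
        raise ValueError("response length mismatch")
    sd = X.std(axis=0)
    if (sd == 0).any():
        bad = [pool.columns[j] for j in np.flatnonzero(sd == 0)]
        raise ValueError(f"constant columns in pool: {bad}")
    Xs = (X - X.mean(axis=0)) / sd
    y_sd = y.std() or 1.0
    yc = (y - y.mean()) / y_sd        # affine-invariant selection
    ridge_fallback = False
    if np.linalg.matrix_rank(Xs) < p:
        ridge_fallback = True
        warnings.warn("pilot OLS rank deficient; ridge-initialized adaptive "
                      "weights used", UserWarning, stacklevel=2)
        beta0 = np.linalg.solve(Xs.T @ Xs + 1e-3 * n * np.eye(p), Xs.T @ yc)
    else:
        beta0, *_ = np.linalg.lstsq(Xs, yc, rcond=None)
    with np.errstate(divide="ignore"):
        w = np.abs(beta0) ** (-gamma)
    w = np.minimum(w, 1e12)           # zero pilot coefficient => effectively excluded
    Xw = Xs / w
    alpha_max = np.max(np.abs(Xw.T @ yc)) / n
    alphas = np.geomspace(alpha_max, alpha_max * eps, n_alphas)
    alphas_out, coefs_w, _ = lasso_path(Xw, yc, alphas=alphas, tol=tol)
    resid = yc[:, None] - Xw @ coefs_w
    rss = np.sum(resid ** 2, axis=0)
    df = np.count_nonzero(coefs_w, axis=0)
    bic_path = _bic(n, rss, df, p, bic)
    best = int(np.argmin(bic_path))
    coefs = coefs_w / w[:, None] * (y_sd / sd[:, None])
    selected = [pool.columns[j] for j in
                np.flatnonzero(coefs_w[:, best] != 0)]
    return AdaptiveLassoPath(
        selected=selected, alphas=alphas_out, bic=bic_path,
        coefs=pd.DataFrame(coefs, index=pool.columns, columns=alphas_out),
        best_alpha=float(alphas_out[best]),
        weights=pd.Series(w, index=pool.columns),
        ridge_fallback=ridge_fallback)


@dataclass
class SelectionResult:
    """Per-equation adaptive-lasso selections and their union."""

    outcome_selected: list
    treatment_selected: dict
    union: list
    penalties: dict = field(default_factory=dict)
    bic_paths: dict = field(default_factory=dict)


def double_select(outcome, arms, pool: pd.DataFrame,
                  reference: str = ARM_METFORMIN,
                  treatment_model: str = "linear",
                  gamma: float = 1.0, bic: str = "gaussian"
                  ) -> SelectionResult:
    """Run the double-selection algorithm over one outcome and all arms.

    One adaptive lasso for the outcome, one per non-reference arm indicator
    (linear working model by default; ``treatment_model="logistic"`` uses an
    L1-penalized logistic model with the same adaptive weights), then the
    union of every selected set ordered by pool column position.
    """
    D = arm_dummies(pd.Series(arms).reset_index(drop=True),
                    reference=reference)
    penalties, bic_paths = {}, {}
    res_y = adaptive_lasso_select(outcome, pool, gamma=gamma, bic=bic)
    penalties["outcome"] = res_y.best_alpha
    bic_paths["outcome"] = res_y.bic
    treatment_selected = {}
    for arm in D.columns:
        if treatment_model == "linear":
            res_t = adaptive_lasso_select(D[arm], pool, gamma=gamma, bic=bic)
            treatment_selected[arm] = res_t.selected
            penalties[arm] = res_t.best_alpha
            bic_paths[arm] = res_t.bic
        elif treatment_model == "logistic":
            treatment_selected[arm] = _logistic_lasso_select(
                D[arm].to_numpy(), pool, gamma=gamma)
            penalties[arm] = np.nan
        else:
            raise ValueError(f"unknown treatment model {treatment_model!r}")
    in_union = set(res_y.selected)
    for s in treatment_selected.values():
        in_union.update(s)
    union = [c for c in pool.columns if c in in_union]
    return SelectionResult(outcome_selected=res_y.selected,
                           treatment_selected=treatment_selected,
                           union=union, penalties=penalties,
                           bic_paths=bic_paths)


def _logistic_lasso_select(t: np.ndarray, pool: pd.DataFrame,
                           gamma: float = 1.0, n_grid: int = 30) -> list:
    """Adaptive L1 logistic selection with BIC over a C grid (option)."""
    from sklearn.linear_model import LogisticRegression
    X = pool.to_numpy(dtype=float)
    n, p = X.shape
    Xs = (X - X.mean(axis=0)) / X.std(axis=0)
    pilot = np.linalg.lstsq(Xs, t - t.mean(), rcond=None)[0]
    w = np.minimum(np.abs(pilot) ** (-gamma), 1e12)
    Xw = Xs / w
    best_bic, best_sel = np.inf, []
    for C in np.geomspace(1e-3, 1e2, n_grid):
        clf = LogisticRegression(penalty="l1", C=C, solver="liblinear",
                                 max_iter=500)
        clf.fit(Xw, t)
        eta = clf.decision_function(Xw)
        ll = float(np.sum(t * eta - np.logaddexp(0.0, eta)))
        df = int(np.count_nonzero(clf.coef_)) + 1
        b = -2.0 * ll + df * np.log(n)
        if b < best_bic:
            best_bic = b
            best_sel = [pool.columns[j] for j in
                        np.flatnonzero(clf.coef_.ravel() != 0)]
    return best_sel


def post_selection_fit(outcome, arms, pool: pd.DataFrame,
                       union: list, reference: str = ARM_METFORMIN,
                       alpha: float = 0.05):
    """OLS on arm dummies plus the selected union; margins with letters.

    With the full pool selected this reproduces the fully adjusted model;
    with an empty union the margins collapse to subgroup means.

    Returns ``(OutcomeModelFit, margins DataFrame)``.
    """
    cov = pool[list(union)] if union else None
    fit = fit_outcome_model(outcome, arms, covariates=cov,
                            reference=reference)
    marg = predictive_margins(fit, covariates=cov, alpha=alpha)
    return fit, marg
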