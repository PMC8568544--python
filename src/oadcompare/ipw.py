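"""Inverse probability weighting over multiple therapy arms.

Multinomial-logit propensity model for the eight-arm treatment variable,
inverse-probability weights (raw and within-arm Hajek-normalized), weighted
outcome means with linearization standard errors, and weighted covariate
balance diagnostics. Arms too small to support a propensity model (the
glibenclamide arm has 12 patients) are merged into Others before fitting,
mirroring the study's handling.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .cohort import ARMS, ARM_METFORMIN, ARM_OTHERS
from .descriptives import _arm_order, compact_letters, pairwise_pvalues

__all__ = [
    "PropensityFit",
    "SeparationError",
    "merge_small_arms",
    "fit_propensity",
    "compute_weights",
    "weighted_outcomes",
    "weighted_anova_pvalue",
    "weighted_balance",
]


class SeparationError(RuntimeError):
    """Quasi-separation: some propensities diverge to 0/1."""


def merge_small_arms(arms, min_n: int = 30, into: str = ARM_OTHERS):
    """Relabel arms with fewer than ``min_n`` patients into ``into``.

    Returns the relabeled series and the list of merged arm names. The
    default threshold of 30 merges the glibenclamide arm at the published
    arm sizes.
    """
    arms = pd.Series(arms).copy()
    counts = arms.value_counts()
    merged = [a for a in counts.index
              if counts[a] < min_n and a != into]
    arms[arms.isin(merged)] = into
    return arms, merged


@dataclass
class PropensityFit:
    """Fitted multinomial-logit propensity model."""

    params: pd.DataFrame        # (arms x columns); reference row all zero
    probs: pd.DataFrame         # n x arms, rows sum to 1
    reference: str
    converged: bool
    llf: float
    gradient_norm: float
    results: object = None


def fit_propensity(arms, covariates: pd.DataFrame,
                   reference: str = ARM_METFORMIN,
                   min_n: int = 30, merge_into: str = ARM_OTHERS,
                   max_coef: float = 30.0) -> PropensityFit:
    """Maximum-likelihood multinomial logit of arm on the covariates.

    Arms below ``min_n`` are merged into ``merge_into`` first. Coefficients
    of the reference arm are fixed at zero. Divergent coefficients (any
    |coef| > ``max_coef``) are treated as separation and raise
    :class:`SeparationError` naming the offending covariate.
    """
    arms, merged = merge_small_arms(arms, min_n=min_n, into=merge_into)
    arm_levels = _arm_order(arms.unique())
    if reference not in arm_levels:
        raise ValueError(f"reference arm {reference!r} absent")
    arm_levels = [reference] + [a for a in arm_levels if a != reference]
    codes = pd.Categorical(arms, categories=arm_levels).codes
    X = sm.add_constant(covariates.reset_index(drop=True).astype(float),
                        has_constant="add")
    from .margins import _check_rank
    _check_rank(X)
    model = sm.MNLogit(pd.Series(codes), X)
    try:
        res = model.fit(method="newton", maxiter=200, tol=1e-10, disp=False)
    except np.linalg.LinAlgError as err:
        raise SeparationError(
            "propensity likelihood is degenerate (singular Hessian) — "
            "an arm is perfectly predicted by some covariate") from err
    params = np.asarray(res.params)            # (k_vars, n_arms - 1)
    if np.abs(params).max() > max_coef:
        j, _ = np.unravel_index(np.abs(params).argmax(), params.shape)
        raise SeparationError(
            f"propensity coefficients diverge (|coef| > {max_coef}); "
            f"offending covariate: {X.columns[j]!r} — likely separation")
    score = model.score(params.ravel(order="F"))
    gnorm = float(np.max(np.abs(score)))
    probs = pd.DataFrame(np.asarray(res.predict(X)), columns=arm_levels)
    probs.index = covariates.index
    ptab = pd.DataFrame(0.0, index=arm_levels, columns=X.columns)
    for k, a in enumerate(arm_levels[1:]):
        ptab.loc[a] = params[:, k]
    return PropensityFit(params=ptab, probs=probs, reference=reference,
                         converged=bool(res.mle_retvals.get("converged",
                                                            True)),
                         llf=float(res.llf), gradient_norm=gnorm,
                         results=res)


def compute_weights(probs: pd.DataFrame | PropensityFit, arms,
                    truncate: tuple | None = None,
                    floor: float = 1e-6) -> pd.DataFrame:
    """Inverse-probability weights for the observed arm.

    raw weight = 1 / P(observed arm | x); the Hajek-normalized column sums
    to one within each arm. Optional symmetric percentile truncation
    (e.g. ``truncate=(1, 99)``) clips raw weights before normalizing;
    off by default. A fitted probability below ``floor`` is a hard error —
    truncation or arm merging should be applied upstream.
    """
    if isinstance(probs, PropensityFit):
        probs = probs.probs
    arms = pd.Series(arms)
    arms.index = probs.index
    missing = set(arms.unique()) - set(probs.columns)
    if missing:
        raise ValueError(f"no fitted probabilities for arms {sorted(missing)}")
    p_obs = pd.Series(
        probs.to_numpy()[np.arange(len(arms)),
                         probs.columns.get_indexer(arms)],
        index=probs.index, name="p_observed")
    if (p_obs < floor).any():
        bad = p_obs.idxmin()
        raise ValueError(
            f"fitted propensity {p_obs.min():.2e} below floor {floor} "
            f"(patient {bad}); consider weight truncation or merging arms")
    raw = 1.0 / p_obs
    flagged = pd.Series(False, index=raw.index)
    if truncate is not None:
        lo, hi = np.percentile(raw, truncate)
        flagged = (raw < lo) | (raw > hi)
        raw = raw.clip(lo, hi)
    norm = raw / raw.groupby(arms).transform("sum")
    return pd.DataFrame({"arm": arms, "p_observed": p_obs, "raw": raw,
                         "normalized": norm, "truncated": flagged})


def weighted_outcomes(values, arms, weights, alpha: float = 0.05,
                      letters: bool = True) -> pd.DataFrame:
    """Per-arm Hajek-weighted means with linearization SEs.

    The Hajek estimator m = sum(w y)/sum(w) within arm; its Taylor
    (linearization) variance is sum(w^2 (y - m)^2) / (sum w)^2, invariant
    to rescaling the weights within an arm.
    """
    values = pd.Series(np.asarray(values, dtype=float)).reset_index(drop=True)
    arms = pd.Series(arms).reset_index(drop=True)
    w = pd.Series(np.asarray(
        weights["raw"] if isinstance(weights, pd.DataFrame) else weights,
        dtype=float)).reset_index(drop=True)
    if (w <= 0).any():
        raise ValueError("weights must be positive")
    rows = {}
    for arm in _arm_order(arms.unique()):
        mask = (arms == arm).to_numpy()
        wa, ya = w[mask].to_numpy(), values[mask].to_numpy()
        m = float(np.sum(wa * ya) / np.sum(wa))
        var = float(np.sum(wa ** 2 * (ya - m) ** 2) / np.sum(wa) ** 2)
        rows[arm] = {"n": int(mask.sum()), "estimate": m,
                     "se": float(np.sqrt(var))}
    table = pd.DataFrame(rows).T.loc[_arm_order(rows)]
    table["n"] = table["n"].astype(int)
    table.index.name = "arm"
    if letters:
        pmat = pairwise_pvalues(table["estimate"], table["se"])
        table["letters"] = pd.Series(compact_letters(pmat, alpha=alpha))
    return table


def weighted_anova_pvalue(values, arms, weights) -> float:
    """Weighted one-way ANOVA p-value (WLS F-test of arm-mean equality).

    Weights are normalized to sum to n overall; the F statistic compares the
    weighted between-arm sum of squares to the weighted within-arm residual
    with (k - 1, n - k) degrees of freedom. Degenerate (zero total weighted
    variance) returns p = 1 by convention.
    """
    from scipy import stats
    values = np.asarray(values, dtype=float)
    arms = pd.Series(arms).reset_index(drop=True)
    w = np.asarray(weights, dtype=float)
    n = len(values)
    w = w * n / w.sum()
    codes, levels = pd.factorize(arms)
    k = len(levels)
    if k < 2:
        raise ValueError("ANOVA needs at least two arms")
    sw = np.bincount(codes, weights=w, minlength=k)
    means = np.bincount(codes, weights=w * values, minlength=k) / sw
    grand = float(np.sum(w * values) / np.sum(w))
    ssb = float(np.sum(sw * (means - grand) ** 2))
    ssw = float(np.sum(w * (values - means[codes]) ** 2))
    sst = ssb + ssw
    if sst <= 1e-12 * max(1.0, grand ** 2):
        return 1.0
    if ssw <= 1e-12 * sst:
        return 0.0
    f = (ssb / (k - 1)) / (ssw / (n - k))
    return float(stats.f.sf(f, k - 1, n - k))


def weighted_balance(covariates: pd.DataFrame, arms,
                     weights) -> pd.DataFrame:
    """Weighted covariate means per arm with weighted ANOVA p-values.

    With well-specified propensity weights the weighted arm-specific means
    converge to the pooled covariate means and ~5% of p-values fall below
    0.05 under the null.
    """
    from .descriptives import balance_table
    w = weights["raw"] if isinstance(weights, pd.DataFrame) else weights
    return balance_table(covariates, arms, weights=w)
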