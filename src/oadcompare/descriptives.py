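"""Unadjusted subgroup summaries, balance tests, and compact letter display.

Subgroup means with per-arm standard errors, one-way ANOVA balance tests
across arms, pairwise z-tests, and a compact letter display (CLD) in which
two arms share a letter if and only if their pairwise difference is not
significant at the stated level.
"""

from __future__ import annotations

import itertools
import warnings
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import ARMS

__all__ = [
    "subgroup_summary",
    "pairwise_pvalues",
    "anova_balance",
    "compact_letters",
    "letters_consistent",
    "arm_table",
    "balance_table",
]

_LETTERS = "abcdefghijklmnopqrstuvwxyz"


def _arm_order(index) -> list:
    """Stable arm ordering: canonical arm order first, extras appended."""
    present = list(index)
    ordered = [a for a in ARMS if a in present]
    ordered += [a for a in present if a not in ordered]
    return ordered


def subgroup_summary(values, arms, binary: bool | None = None,
                     alpha: float = 0.05, letters: bool = True) -> pd.DataFrame:
    """Per-arm mean, standard error, and letter group for one outcome.

    SE is the sample SD / sqrt(n); for a binary outcome the binomial form
    sqrt(p(1-p)/n) is used (``binary=None`` auto-detects a 0/1 outcome).
    Arms with no patients are omitted; an arm with a single patient keeps
    its mean but gets an undefined (NaN) SE and is flagged.
    """
    values = pd.Series(np.asarray(values, dtype=float))
    arms = pd.Series(arms).reset_index(drop=True)
    if values.isna().any():
        raise ValueError("non-finite outcome values")
    if binary is None:
        binary = set(np.unique(values)) <= {0.0, 1.0}
    rows = {}
    for arm, grp in values.groupby(arms, observed=True):
        n = len(grp)
        mean = float(grp.mean())
        if n == 1:
            se = np.nan
            warnings.warn(f"arm {arm!r} has a single patient; SE undefined",
                          UserWarning, stacklevel=2)
        elif binary:
            se = float(np.sqrt(mean * (1.0 - mean) / n))
        else:
            se = float(grp.std(ddof=1) / np.sqrt(n))
        rows[arm] = {"n": n, "estimate": mean, "se": se}
    table = pd.DataFrame(rows).T.loc[_arm_order(rows)]
    table["n"] = table["n"].astype(int)
    table.index.name = "arm"
    if letters:
        pmat = pairwise_pvalues(table["estimate"], table["se"])
        table["letters"] = pd.Series(compact_letters(pmat, alpha=alpha))
    return table


def pairwise_pvalues(estimates: pd.Series, ses: pd.Series) -> pd.DataFrame:
    """Symmetric matrix of two-sided pairwise z-test p-values.

    Unadjusted for multiplicity (apply e.g. Bonferroni upstream if wanted).
    Degenerate SEs: two exactly equal estimates with zero SE give p = 1,
    unequal ones p = 0.
    """
    arms = list(estimates.index)
    p = pd.DataFrame(1.0, index=arms, columns=arms)
    for a, b in combinations(arms, 2):
        var = ses[a] ** 2 + ses[b] ** 2
        diff = estimates[a] - estimates[b]
        if var > 0:
            z = diff / np.sqrt(var)
            pv = 2.0 * stats.norm.sf(abs(z))
        else:
            pv = 1.0 if diff == 0 else 0.0
        p.loc[a, b] = p.loc[b, a] = pv
    return p


def anova_balance(values, arms) -> float:
    """One-way ANOVA F-test p-value for a covariate (0/1 treated as numeric).

    Convention for degenerate inputs: a covariate with no total variance
    returns p = 1; zero within-group variance with distinct group means
    returns p = 0.
    """
    values = np.asarray(values, dtype=float)
    codes, _ = pd.factorize(pd.Series(arms).reset_index(drop=True))
    k = codes.max() + 1
    if k < 2:
        raise ValueError("ANOVA needs at least two arms")
    n = len(values)
    counts = np.bincount(codes, minlength=k)
    if counts.min() < 2:
        raise ValueError("every arm needs n >= 2 for the ANOVA balance test")
    grand = values.mean()
    means = np.bincount(codes, weights=values, minlength=k) / counts
    ssb = float(np.sum(counts * (means - grand) ** 2))
    ssw = float(np.sum((values - means[codes]) ** 2))
    sst = ssb + ssw
    if sst <= 1e-12 * max(1.0, abs(grand)):
        return 1.0
    if ssw <= 1e-12 * sst:
        return 0.0
    f = (ssb / (k - 1)) / (ssw / (n - k))
    return float(stats.f.sf(f, k - 1, n - k))


# --------------------------------------------------------------------------
# Compact letter display
# --------------------------------------------------------------------------

def _maximal_cliques(adj: dict) -> list:
    """Bron-Kerbosch over the (tiny) non-significance graph."""
    nodes = sorted(adj)
    cliques = []

    def extend(r, p, x):
        if not p and not x:
            cliques.append(frozenset(r))
            return
        pivot = max(p | x, key=lambda v: len(adj[v] & p))
        for v in sorted(p - adj[pivot]):
            extend(r | {v}, p & adj[v], x & adj[v])
            p = p - {v}
            x = x | {v}

    extend(set(), set(nodes), set())
    return cliques


def compact_letters(pvalues: pd.DataFrame, alpha: float = 0.05) -> dict:
    """Assign letter groups so arms share a letter iff p >= alpha.

    Solves the minimum clique cover of the non-significance graph exactly:
    every letter is a maximal clique of the "not significantly different"
    relation, every non-significant pair (and every arm) is covered, and
    the number of letters is minimal. Non-transitive significance patterns
    yield overlapping letters, never an error. Deterministic: cliques are
    ordered by their first arm in index order and lettered a, b, c, ...

    Exact search is viable because the display never spans more than a
    handful of arms (eight here); beyond ~15 arms a heuristic would be
    needed.
    """
    arms = list(pvalues.index)
    idx = {a: i for i, a in enumerate(arms)}
    adj = {i: set() for i in range(len(arms))}
    for a, b in combinations(arms, 2):
        if pvalues.loc[a, b] >= alpha:
            adj[idx[a]].add(idx[b])
            adj[idx[b]].add(idx[a])
    cliques = _maximal_cliques(adj)
    edges = {frozenset((i, j)) for i in adj for j in adj[i] if i < j}
    required = edges | {frozenset((i,)) for i in adj}

    def covers(sel):
        cov = set()
        for c in sel:
            cov.update(frozenset((i, j)) for i, j in
                       combinations(sorted(c), 2))
            cov.update(frozenset((i,)) for i in c)
        return required <= cov

    cliques_sorted = sorted(cliques, key=lambda c: (min(c), -len(c),
                                                    sorted(c)))
    chosen = None
    for k in range(1, len(cliques_sorted) + 1):
        for sel in itertools.combinations(cliques_sorted, k):
            if covers(sel):
                chosen = sel
                break
        if chosen is not None:
            break
    assert chosen is not None  # full vertex set is always coverable
    ordered = sorted(chosen, key=lambda c: (min(c), sorted(c)))
    out = {a: "" for a in arms}
    for li, c in enumerate(ordered):
        letter = _LETTERS[li % 26] * (1 + li // 26)
        for i in sorted(c):
            out[arms[i]] += letter
    return out


def letters_consistent(letters: dict, pvalues: pd.DataFrame,
                       alpha: float = 0.05) -> bool:
    """Check the defining CLD relation: share a letter iff p >= alpha."""
    for a, b in combinations(pvalues.index, 2):
        share = bool(set(letters[a]) & set(letters[b]))
        if share != (pvalues.loc[a, b] >= alpha):
            return False
    return all(letters[a] for a in pvalues.index)


# --------------------------------------------------------------------------
# Table analogues
# --------------------------------------------------------------------------

def arm_table(arms) -> pd.DataFrame:
    """Arm counts with percentage and cumulative percentage shares."""
    arms = pd.Series(arms)
    counts = arms.value_counts()
    counts = counts.loc[_arm_order(counts.index)]
    total = int(counts.sum())
    out = pd.DataFrame({"n": counts.astype(int)})
    out["proportion_pct"] = 100.0 * out["n"] / total
    out["cumulative_pct"] = out["proportion_pct"].cumsum()
    out.index.name = "arm"
    return out


def balance_table(covariates: pd.DataFrame, arms,
                  weights=None) -> pd.DataFrame:
    """Per-arm covariate means with an ANOVA balance p-value per covariate.

    With ``weights`` (per-patient, e.g. inverse propensity) the means are
    weighted and the p-value comes from the weighted one-way ANOVA in
    :mod:`oadcompare.ipw`.
    """
    arms = pd.Series(arms).reset_index(drop=True)
    cov = covariates.reset_index(drop=True)
    if weights is not None:
        from .ipw import weighted_anova_pvalue
        w = pd.Series(weights).reset_index(drop=True)
    order = _arm_order(arms.unique())
    rows = {}
    for c in cov.columns:
        v = cov[c].astype(float)
        if weights is None:
            means = v.groupby(arms, observed=True).mean()
            p = anova_balance(v, arms)
        else:
            means = (v * w).groupby(arms, observed=True).sum() \
                / w.groupby(arms, observed=True).sum()
            p = weighted_anova_pvalue(v, arms, w)
        rows[c] = {**{a: means.get(a, np.nan) for a in order},
                   "anova_p": p}
    out = pd.DataFrame(rows).T
    out = out[[*order, "anova_p"]]
    out.index.name = "covariate"
    return out
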