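"""Shared independent oracles for the letter-display tests."""

import itertools

import numpy as np
import pandas as pd


def pattern_pmat(sig: np.ndarray) -> pd.DataFrame:
    """Turn a boolean significance pattern into a p-value matrix."""
    arms = [f"a{i}" for i in range(sig.shape[0])]
    p = pd.DataFrame(1.0, index=arms, columns=arms)
    for i, j in itertools.combinations(range(len(arms)), 2):
        p.iloc[i, j] = p.iloc[j, i] = 0.01 if sig[i, j] else 0.50
    return p


def brute_force_min_letters(sig: np.ndarray) -> int:
    """Minimum number of letters over ALL families of arm subsets that
    satisfy the share-a-letter-iff-not-significant relation."""
    n = sig.shape[0]
    arms = list(range(n))
    subsets = []
    for r in range(1, n + 1):
        for c in itertools.combinations(arms, r):
            if all(not sig[i, j] for i, j in itertools.combinations(c, 2)):
                subsets.append(frozenset(c))
    for k in range(1, len(subsets) + 1):
        for fam in itertools.combinations(subsets, k):
            letters = {a: {i for i, s in enumerate(fam) if a in s}
                       for a in arms}
            if any(not letters[a] for a in arms):
                continue
            ok = all((len(letters[i] & letters[j]) > 0) == (not sig[i, j])
                     for i, j in itertools.combinations(arms, 2))
            if ok:
                return k
    raise AssertionError("uncoverable pattern")
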