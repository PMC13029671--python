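"""Shared rank-correlation machinery.

Spearman's rho is computed as the Pearson correlation of (tie-averaged)
ranks.  At very small sample sizes the usual t approximation for the
p-value is unreliable, so for n <= ``EXACT_MAX_N`` the permutation null
is enumerated exhaustively (n! <= 5040 arrangements); above that the
t approximation with tie correction is used.
"""

from __future__ import annotations

import itertools
from functools import lru_cache

import numpy as np
from scipy import stats

EXACT_MAX_N = 7


@lru_cache(maxsize=8)
def _permutation_matrix(n: int) -> np.ndarray:
    """All n! permutations of range(n) as an (n!, n) int array."""
    return np.array(list(itertools.permutations(range(n))), dtype=np.intp)


def _pearson_of_ranks(rx: np.ndarray, ry: np.ndarray) -> float:
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    denom = np.sqrt((rx * rx).sum() * (ry * ry).sum())
    if denom == 0:
        return np.nan
    return float((rx * ry).sum() / denom)


@lru_cache(maxsize=1024)
def _exact_null(rx_key: tuple, ry_key: tuple) -> np.ndarray:
    """Sorted |rho| values over all permutations of the y ranks.

    Keyed by the two rank vectors so tie structure is respected; for
    continuous data the cache collapses to one entry per n.
    """
    rx = np.asarray(rx_key, dtype=float)
    ry = np.asarray(ry_key, dtype=float)
    n = rx.size
    perms = _permutation_matrix(n)
    ry_perm = ry[perms]                       # (n!, n)
    rxc = rx - rx.mean()
    ryc = ry_perm - ry_perm.mean(axis=1, keepdims=True)
    num = ryc @ rxc
    denom = np.sqrt((rxc * rxc).sum() * (ryc * ryc).sum(axis=1))
    with np.errstate(invalid="ignore"):
        rho = num / denom
    return np.sort(np.abs(rho))


def spearman_rho_p(x, y, exact_max_n: int = EXACT_MAX_N) -> tuple[float, float]:
    """Spearman rho and two-sided p-value.

    Exact permutation p for n <= ``exact_max_n``; t approximation
    otherwise.  Returns (nan, nan) for constant inputs.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if n != y.size:
        raise ValueError("x and y must have equal length")
    if n < 3:
        raise ValueError("need at least 3 observations")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rho = _pearson_of_ranks(rx, ry)
    if np.isnan(rho):
        return np.nan, np.nan
    if n <= exact_max_n:
        # the |rho| multiset over all permutations depends on the two rank
        # vectors only through their multisets, so sort both for caching
        null = _exact_null(tuple(np.sort(rx)), tuple(np.sort(ry)))
        p = float(np.mean(null >= abs(rho) - 1e-12))
    else:
        p = _t_pvalue(rho, n)
    return rho, min(p, 1.0)


def _t_pvalue(rho: float, n: int) -> float:
    if abs(rho) >= 1.0:
        return 0.0
    t = rho * np.sqrt((n - 2) / (1.0 - rho * rho))
    return float(2.0 * stats.t.sf(abs(t), df=n - 2))


def spearman_matrix(X: np.ndarray) -> np.ndarray:
    """Tie-corrected Spearman correlation matrix between columns of X."""
    R = np.apply_along_axis(stats.rankdata, 0, np.asarray(X, dtype=float))
    Rc = R - R.mean(axis=0)
    sd = Rc.std(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        C = (Rc.T @ Rc) / X.shape[0]
        C /= np.outer(sd, sd)
    np.clip(C, -1.0, 1.0, out=C)
    return C


def pairwise_spearman_table(a_df, b_df, exact_max_n: int = EXACT_MAX_N):
    """rho and p DataFrames for every (column of a, column of b) pair.

    Constant columns yield NaN entries rather than an error.
    """
    import pandas as pd

    rho = pd.DataFrame(index=a_df.columns, columns=b_df.columns, dtype=float)
    pval = rho.copy()
    for ca in a_df.columns:
        for cb in b_df.columns:
            r, p = spearman_rho_p(a_df[ca].to_numpy(), b_df[cb].to_numpy(),
                                  exact_max_n=exact_max_n)
            rho.loc[ca, cb] = r
            pval.loc[ca, cb] = p
    return rho, pval
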