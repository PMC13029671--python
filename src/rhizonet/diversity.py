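"""Alpha diversity (Shannon, ACE), Bray-Curtis dissimilarity, non-metric
multidimensional scaling, Mantel tests and ordination-axis/environment
correlations.

Shannon entropy is reported in nats by default (a base switch is
provided).  No rarefaction is applied by default; ``rarefy`` offers a
seeded subsample-to-minimum-depth step for users who want depth
normalisation before diversity or network inference.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist, squareform
from skbio.diversity.alpha import ace as _skbio_ace, chao1 as _skbio_chao1
from sklearn.manifold import MDS

from ._stats import pairwise_spearman_table
from .io import OtuTable, RelAbundanceTable, SampleMetadata


def shannon(counts, base: float = np.e) -> float:
    """Shannon entropy -sum p log p over nonzero proportions (nats by
    default; pass base=2 for bits)."""
    c = np.asarray(counts, dtype=float)
    total = c.sum()
    if total <= 0:
        raise ValueError("all-zero count vector")
    p = c[c > 0] / total
    return float(-(p * np.log(p)).sum() / np.log(base))


@dataclass
class AceResult:
    estimate: float
    used_chao1_fallback: bool = False


def ace(counts, rare_threshold: int = 10) -> AceResult:
    """Abundance-based coverage estimator of richness.

    S_ACE = S_abund + S_rare/C_ACE + (F1/C_ACE) * gamma^2 with
    C_ACE = 1 - F1/N_rare and gamma^2 the rare-class CV floored at 0.
    When every rare individual is a singleton (C_ACE = 0) the estimator
    is undefined and Chao1 is returned with a flag.
    """
    c = np.asarray(counts)
    c = c[c > 0]
    if c.size == 0:
        raise ValueError("all-zero count vector")
    rare = c[c <= rare_threshold]
    f1 = int((c == 1).sum())
    if rare.size and f1 == rare.sum():
        return AceResult(float(_skbio_chao1(c)), used_chao1_fallback=True)
    return AceResult(float(_skbio_ace(c, rare_threshold=rare_threshold)))


def alpha_diversity(t: OtuTable) -> pd.DataFrame:
    """Per-sample Shannon (nats) and ACE richness."""
    rows = {}
    for s in t.sample_ids:
        c = t.counts.loc[s].to_numpy()
        a = ace(c)
        rows[s] = {"shannon": shannon(c), "ace": a.estimate,
                   "ace_chao1_fallback": a.used_chao1_fallback}
    return pd.DataFrame(rows).T.infer_objects()


def bray_curtis(rel: RelAbundanceTable | pd.DataFrame) -> pd.DataFrame:
    """Symmetric Bray-Curtis distance matrix between samples."""
    df = rel.values if isinstance(rel, RelAbundanceTable) else rel
    if len(df) < 2:
        raise ValueError("need at least 2 samples")
    d = squareform(pdist(df.to_numpy(), metric="braycurtis"))
    return pd.DataFrame(d, index=df.index, columns=df.index)


@dataclass
class OrdinationResult:
    coordinates: pd.DataFrame     # samples x axes (NMDS1, NMDS2, ...)
    stress: float                 # Kruskal stress-1
    converged: bool
    n_restarts: int
    degenerate: bool = False


def nmds(d: pd.DataFrame, k: int = 2, n_restarts: int = 20,
         max_iter: int = 500, tol: float = 1e-9,
         seed: int | None = 0) -> OrdinationResult:
    """Non-metric MDS of a distance matrix; best of ``n_restarts`` SMACOF
    runs, reporting Kruskal stress-1.  Coordinates are mean-centered."""
    D = d.to_numpy(dtype=float)
    n = D.shape[0]
    if D.shape[0] != D.shape[1] or not np.allclose(D, D.T):
        raise ValueError("distance matrix must be square symmetric")
    if n < k + 2:
        raise ValueError("need at least k + 2 samples")
    off = D[np.triu_indices(n, 1)]
    # degenerate = no dissimilarity information at all (identical samples)
    if np.max(off) < 1e-15:
        warnings.warn("degenerate (all-equal) distances; returning zeros")
        coords = pd.DataFrame(np.zeros((n, k)), index=d.index,
                              columns=[f"NMDS{i+1}" for i in range(k)])
        return OrdinationResult(coords, 0.0, True, 0, degenerate=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", FutureWarning)
        model = MDS(n_components=k, metric_mds=False, n_init=n_restarts,
                    max_iter=max_iter, eps=tol, random_state=seed,
                    metric="precomputed", normalized_stress=True,
                    init="random")
        X = model.fit_transform(D)
    X = X - X.mean(axis=0)
    coords = pd.DataFrame(X, index=d.index,
                          columns=[f"NMDS{i+1}" for i in range(k)])
    return OrdinationResult(coords, float(model.stress_),
                            model.n_iter_ < max_iter, n_restarts)


@dataclass
class MantelResult:
    r: float
    p: float
    n_perm: int
    method: str


def mantel(d1: pd.DataFrame, d2: pd.DataFrame, method: str = "spearman",
           n_perm: int = 999, seed: int | None = None,
           alternative: str = "greater",
           exact: bool | None = None) -> MantelResult:
    """Mantel test: correlation of two distance matrices with a
    permutation p-value (rows/columns of d2 permuted jointly).

    Sampled permutations give p = (1 + #{r_perm >= r_obs}) / (n_perm + 1),
    one-sided 'greater' by default; 'two-sided' compares |r|.  With
    ``exact`` (the default for n <= 6) every permutation is enumerated and
    p is the exact null fraction at least as extreme.
    """
    D1, D2 = d1.to_numpy(dtype=float), d2.to_numpy(dtype=float)
    if D1.shape != D2.shape or D1.shape[0] != D1.shape[1]:
        raise ValueError("matrices must be square and same shape")
    n = D1.shape[0]
    iu = np.triu_indices(n, 1)
    v1, v2 = D1[iu], D2[iu]
    if np.ptp(v1) == 0 or np.ptp(v2) == 0:
        raise ValueError("constant off-diagonal distances")
    if method == "spearman":
        v1 = stats.rankdata(v1)
    elif method != "pearson":
        raise ValueError("method must be 'spearman' or 'pearson'")
    v1c = (v1 - v1.mean()) / v1.std()

    def corr_with(vals: np.ndarray) -> np.ndarray:
        # vals: (m, n_pairs); Pearson of each row against v1c
        if method == "spearman":
            vals = stats.rankdata(vals, axis=1)
        vc = vals - vals.mean(axis=1, keepdims=True)
        sd = vc.std(axis=1)
        return (vc @ v1c) / (vals.shape[1] * np.where(sd == 0, np.nan, sd))

    r_obs = float(corr_with(v2[None, :])[0])
    if exact is None:
        exact = n <= 6
    if exact:
        import itertools

        perms = np.array(list(itertools.permutations(range(n))))
    else:
        rng = np.random.default_rng(seed)
        perms = np.array([rng.permutation(n) for _ in range(n_perm)])
    pv = D2[perms[:, iu[0]], perms[:, iu[1]]]       # (n_perm, n_pairs)
    r_perm = corr_with(pv)
    if alternative == "greater":
        hits = int(np.sum(r_perm >= r_obs - 1e-12))
    elif alternative == "two-sided":
        hits = int(np.sum(np.abs(r_perm) >= abs(r_obs) - 1e-12))
    else:
        raise ValueError("alternative must be 'greater' or 'two-sided'")
    if exact:
        p = hits / len(perms)
    else:
        p = (1 + hits) / (n_perm + 1)
    return MantelResult(r=r_obs, p=float(p), n_perm=len(perms),
                        method=method)


def permanova_groups(d: pd.DataFrame, groups: pd.Series,
                     n_perm: int = 999, seed: int | None = 0):
    """Group-separation permutation test (PERMANOVA pseudo-F) on a
    distance matrix; the companion significance for an NMDS display."""
    from skbio.stats.distance import DistanceMatrix, permanova

    dm = DistanceMatrix(d.to_numpy(dtype=float), ids=[str(i) for i in d.index])
    rng = np.random.default_rng(seed)
    with _seeded_global_rng(rng):
        res = permanova(dm, grouping=groups.loc[d.index].to_numpy(),
                        permutations=n_perm)
    return {"pseudo_F": float(res["test statistic"]),
            "p": float(res["p-value"]), "n_perm": n_perm}


class _seeded_global_rng:
    """skbio's permanova uses the global numpy RNG; pin it temporarily."""

    def __init__(self, rng):
        self.seed = int(rng.integers(2**31 - 1))

    def __enter__(self):
        self.state = np.random.get_state()
        np.random.seed(self.seed)

    def __exit__(self, *exc):
        np.random.set_state(self.state)


def axis_env_correlation(ordination: OrdinationResult, meta: SampleMetadata,
                         variables=None) -> pd.DataFrame:
    """Spearman rho and p for each (ordination axis, soil variable) pair.

    Constant variables are reported as missing.  Exact permutation
    p-values are used automatically at n <= 7.
    """
    env = meta.numeric(variables)
    env = env.loc[ordination.coordinates.index]
    rho, p = pairwise_spearman_table(ordination.coordinates, env)
    out = rho.stack().rename("rho").to_frame()
    out["p"] = p.stack()
    out.index.names = ["axis", "variable"]
    return out.reset_index()


def rarefy(t: OtuTable, depth: int | None = None,
           seed: int | None = 0) -> OtuTable:
    """Subsample every sample to ``depth`` (default: minimum library
    size) without replacement."""
    rng = np.random.default_rng(seed)
    sizes = t.library_sizes()
    if depth is None:
        depth = int(sizes.min())
    if (sizes < depth).any():
        raise ValueError("depth exceeds the smallest library size")
    out = {}
    for s in t.sample_ids:
        row = t.counts.loc[s].to_numpy()
        pool = np.repeat(np.arange(row.size), row)
        keep = rng.choice(pool, size=depth, replace=False)
        out[s] = np.bincount(keep, minlength=row.size)
    df = pd.DataFrame(out, index=t.counts.columns).T.astype(np.int64)
    df.index.name = t.counts.index.name
    return OtuTable(counts=df, kingdom=t.kingdom)
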