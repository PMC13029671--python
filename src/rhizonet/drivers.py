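"""Dominant-taxon selection, random-forest explanatory power, variation
partitioning over predictor sets, and taxon-environment Spearman tables.

Variable-set membership for variation partitioning defaults to
physical = {pH, SWC, EC, Na, K}, chemical = {TC, TOC, TN, TP, AN, OP},
biomass = {MBC, MBN, MBP}; all three sets are configurable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor
from statsmodels.stats.multitest import multipletests

from ._stats import pairwise_spearman_table
from .io import RelAbundanceTable, SampleMetadata

PHYSICAL_VARS = ("pH", "SWC", "EC", "Na", "K")
CHEMICAL_VARS = ("TC", "TOC", "TN", "TP", "AN", "OP")
BIOMASS_VARS = ("MBC", "MBN", "MBP")


@dataclass
class DominantTaxa:
    rank: str
    rule: str
    taxa: pd.Series               # taxon -> mean relative abundance
    flagged: bool = False


def select_dominant(rel: RelAbundanceTable, rule: str,
                    rank: str = "") -> DominantTaxa:
    """Dominant taxa of an aggregated table.

    'phylum_1pct': every taxon whose mean relative abundance exceeds 1%.
    'top10_genus': the 10 most abundant taxa (ties at the cut broken
    lexicographically, the smaller name kept).
    """
    means = rel.values.mean(axis=0)
    if rule == "phylum_1pct":
        chosen = means[means > 0.01]
        chosen = chosen.sort_values(ascending=False)
        return DominantTaxa(rank or "phylum", rule, chosen)
    if rule == "top10_genus":
        # deterministic: descending abundance, then lexicographic name
        df = means.rename("abundance").reset_index()
        df = df.sort_values(["abundance", "index"], ascending=[False, True])
        top = df.head(10)
        flagged = len(df) < 10
        chosen = pd.Series(top["abundance"].to_numpy(),
                           index=top["index"].to_numpy())
        return DominantTaxa(rank or "genus", rule, chosen, flagged=flagged)
    raise ValueError("rule must be 'phylum_1pct' or 'top10_genus'")


@dataclass
class RfExplained:
    taxon: str
    percent_explained: float      # out-of-bag pseudo-R^2 x 100, floored at 0
    importances: pd.Series
    p: float | None
    n_perm: int


def rf_explained(taxon_abundance, env: pd.DataFrame, n_trees: int = 500,
                 seed: int = 0, n_perm: int = 99,
                 taxon: str = "") -> RfExplained:
    """Random-forest regression of one taxon's abundance on environmental
    variables; explanatory power is the out-of-bag pseudo-R^2 (percent,
    floored at 0) and significance comes from response permutation."""
    y = np.asarray(taxon_abundance, dtype=float)
    X = env.to_numpy(dtype=float)
    if y.size < 6:
        raise ValueError("need at least 6 samples")
    if np.ptp(y) == 0:
        raise ValueError("constant response")
    # canonical sample order: the forest's bootstrap draws depend on row
    # order through the seed, so sort rows to make the result invariant
    # to how the caller happened to order the samples
    order = np.lexsort(tuple(X.T) + (y,))
    y, X = y[order], X[order]

    def oob(y_vec, rf_seed):
        rf = RandomForestRegressor(n_estimators=n_trees, oob_score=True,
                                   random_state=rf_seed, n_jobs=1,
                                   bootstrap=True)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # few-sample OOB warnings
            rf.fit(X, y_vec)
        return rf.oob_score_, rf.feature_importances_

    score, imp = oob(y, seed)
    p = None
    if n_perm:
        rng = np.random.default_rng(seed)
        hits = sum(oob(rng.permutation(y), seed)[0] >= score - 1e-12
                   for _ in range(n_perm))
        p = (1 + hits) / (n_perm + 1)
    return RfExplained(taxon=taxon,
                       percent_explained=float(max(score, 0.0) * 100.0),
                       importances=pd.Series(imp, index=env.columns),
                       p=p, n_perm=n_perm)


def hellinger(df: pd.DataFrame) -> pd.DataFrame:
    """Hellinger transform: sqrt of row-proportions (for compositional
    community data ahead of redundancy analysis)."""
    rows = df.to_numpy(dtype=float)
    sums = rows.sum(axis=1, keepdims=True)
    if (sums <= 0).any():
        raise ValueError("all-zero rows cannot be Hellinger-transformed")
    return pd.DataFrame(np.sqrt(rows / sums), index=df.index,
                        columns=df.columns)


def _adjusted_rda_r2(Y: np.ndarray, X: np.ndarray | None) -> float:
    """Ezekiel-adjusted multivariate redundancy R^2 of Y on X."""
    n = Y.shape[0]
    Yc = Y - Y.mean(axis=0)
    ss_tot = (Yc ** 2).sum()
    if X is None or X.shape[1] == 0 or ss_tot == 0:
        return 0.0
    Xc = X - X.mean(axis=0)
    rank = np.linalg.matrix_rank(Xc, tol=1e-8)
    if n - 1 - rank <= 0:
        raise ValueError("too few samples for the predictor rank")
    beta, *_ = np.linalg.lstsq(Xc, Yc, rcond=None)
    ss_fit = ((Xc @ beta) ** 2).sum()
    r2 = ss_fit / ss_tot
    return float(1.0 - (1.0 - r2) * (n - 1) / (n - 1 - rank))


@dataclass
class VarPartResult:
    """Venn fractions of adjusted explained variation across three
    predictor sets (individual fractions may be negative)."""

    fractions: dict[str, float]   # a,b,c,ab,ac,bc,abc + residual
    total_adj_r2: float
    set_names: tuple[str, str, str]

    def check_sum(self) -> float:
        return sum(self.fractions.values())


def _drop_collinear(X: pd.DataFrame) -> pd.DataFrame:
    Xc = X.to_numpy(dtype=float)
    Xc = Xc - Xc.mean(axis=0)
    keep: list[int] = []
    for j in range(Xc.shape[1]):
        trial = Xc[:, keep + [j]]
        if np.linalg.matrix_rank(trial, tol=1e-8) == len(keep) + 1:
            keep.append(j)
    if len(keep) < X.shape[1]:
        dropped = [c for i, c in enumerate(X.columns) if i not in keep]
        warnings.warn(f"dropping collinear predictor(s): {dropped}")
    return X.iloc[:, keep]


def variation_partitioning(Y: pd.DataFrame, X1: pd.DataFrame,
                           X2: pd.DataFrame, X3: pd.DataFrame,
                           set_names=("physical", "chemical", "biomass")
                           ) -> VarPartResult:
    """Partition the adjusted redundancy R^2 of a (Hellinger-transformed)
    multivariate response over three predictor sets into 7 Venn fractions
    plus a residual, by inclusion-exclusion over the adjusted R^2 of the
    seven set unions."""
    sets = [_drop_collinear(x) if x is not None and x.shape[1] else x
            for x in (X1, X2, X3)]
    Yv = Y.to_numpy(dtype=float)

    def f(idx: tuple[int, ...]) -> float:
        cols = [sets[i] for i in idx if sets[i] is not None
                and sets[i].shape[1]]
        if not cols:
            return 0.0
        X = _drop_collinear(pd.concat(cols, axis=1))
        return _adjusted_rda_r2(Yv, X.to_numpy(dtype=float))

    r = {idx: f(idx) for k in (1, 2, 3) for idx in combinations(range(3), k)}
    full = r[(0, 1, 2)]
    a = full - r[(1, 2)]
    b = full - r[(0, 2)]
    c = full - r[(0, 1)]
    # remaining Venn cells by inclusion-exclusion on the union values
    abc = r[(0,)] + r[(1,)] + r[(2,)] - r[(0, 1)] - r[(0, 2)] - r[(1, 2)] + full
    ab = r[(0, 2)] + r[(1, 2)] - full - r[(2,)]
    ac = r[(0, 1)] + r[(1, 2)] - full - r[(1,)]
    bc = r[(0, 1)] + r[(0, 2)] - full - r[(0,)]
    fractions = {
        set_names[0]: a, set_names[1]: b, set_names[2]: c,
        f"{set_names[0]}&{set_names[1]}": ab,
        f"{set_names[0]}&{set_names[2]}": ac,
        f"{set_names[1]}&{set_names[2]}": bc,
        "&".join(set_names): abc,
        "residual": 1.0 - full,
    }
    return VarPartResult(fractions=fractions, total_adj_r2=full,
                         set_names=tuple(set_names))


def metadata_variable_sets(meta: SampleMetadata,
                           physical=PHYSICAL_VARS, chemical=CHEMICAL_VARS,
                           biomass=BIOMASS_VARS):
    """Slice a metadata table into the three predictor-set frames,
    keeping only columns actually present."""
    num = meta.numeric()
    return tuple(num[[c for c in cols if c in num.columns]]
                 for cols in (physical, chemical, biomass))


def taxa_env_spearman(taxa: pd.DataFrame, env: pd.DataFrame,
                      bh_correct: bool = False):
    """Spearman rho/p between each taxon and each environmental variable;
    optional Benjamini-Hochberg adjusted p column."""
    rho, p = pairwise_spearman_table(taxa, env)
    out = rho.stack().rename("rho").to_frame()
    out["p"] = p.stack()
    out.index.names = ["taxon", "variable"]
    out = out.reset_index()
    if bh_correct:
        mask = out["p"].notna()
        adj = np.full(len(out), np.nan)
        if mask.any():
            adj[mask.to_numpy()] = multipletests(out.loc[mask, "p"],
                                                 method="fdr_bh")[1]
        out["p_bh"] = adj
    return out
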