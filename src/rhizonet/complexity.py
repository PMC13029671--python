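"""Network complexity index (NCI): the first principal component of a
per-sample subnetwork parameter matrix (nodes, edges, density,
transitivity, diameter, average path length), sign-oriented so that more
edges means a higher index, plus group tests and phylum-vs-NCI fits."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .soil import GroupSummary, anova_with_letters


@dataclass
class NciResult:
    scores: pd.Series             # NCI per sample (PC1, oriented)
    loadings: pd.DataFrame        # metrics x components
    percent_variance: pd.Series   # per component
    used_metrics: list[str]
    dropped_samples: list[str]
    dropped_metrics: list[str]


def nci(metrics: pd.DataFrame, orient_by: str = "edges") -> NciResult:
    """PCA (via SVD of the z-scored parameter matrix) of subnetwork
    topology parameters; the first component score is the NCI.

    Samples with missing metrics are dropped with a warning, as are
    constant metric columns.  PC1 is reflected when its correlation with
    the orienting column (edge count by default) is negative, so higher
    NCI always reads as "more complex".
    """
    complete = metrics.dropna(axis=0, how="any")
    dropped_samples = [s for s in metrics.index if s not in complete.index]
    if dropped_samples:
        warnings.warn(f"dropping {len(dropped_samples)} sample(s) with "
                      "missing metrics")
    if len(complete) < 3:
        raise ValueError("need >= 3 samples with complete metrics")
    sd = complete.std(ddof=1)
    keep = sd.index[sd > 0]
    dropped_metrics = [c for c in complete.columns if c not in keep]
    if dropped_metrics:
        warnings.warn(f"dropping constant metric(s): {dropped_metrics}")
    if not len(keep):
        raise ValueError("all metric columns are constant")
    Z = (complete[keep] - complete[keep].mean()) / sd[keep]
    U, S, Vt = np.linalg.svd(Z.to_numpy(), full_matrices=False)
    scores = U * S
    var = S ** 2 / (len(complete) - 1)
    pct = 100.0 * var / var.sum()
    pc1 = scores[:, 0]
    orient_col = orient_by if orient_by in keep else keep[0]
    anchor = complete[orient_col].to_numpy(dtype=float)
    flip = 1.0
    if np.std(anchor) > 0 and np.corrcoef(pc1, anchor)[0, 1] < 0:
        flip = -1.0
    comp_names = [f"PC{i + 1}" for i in range(len(S))]
    loadings = pd.DataFrame(Vt.T, index=keep, columns=comp_names)
    loadings["PC1"] *= flip
    return NciResult(
        scores=pd.Series(pc1 * flip, index=complete.index, name="NCI"),
        loadings=loadings,
        percent_variance=pd.Series(pct, index=comp_names),
        used_metrics=list(keep),
        dropped_samples=dropped_samples,
        dropped_metrics=dropped_metrics,
    )


def nci_group_test(scores: pd.Series, groups: pd.Series,
                   alpha: float = 0.05) -> GroupSummary:
    """ANOVA with Tukey letters on NCI scores by plant group."""
    groups = groups.loc[scores.index]
    if groups.nunique() == 1:
        g = groups.iloc[0]
        vals = scores.to_numpy()
        return GroupSummary(
            variable="NCI",
            means=pd.Series({g: vals.mean()}),
            ses=pd.Series({g: vals.std(ddof=1) / np.sqrt(len(vals))}),
            ns=pd.Series({g: len(vals)}), f=np.nan, p=np.nan,
            letters={g: "a"}, alpha=alpha)
    by_group = {g: scores[groups == g].to_numpy()
                for g in sorted(groups.unique())}
    return anova_with_letters(by_group, variable="NCI", alpha=alpha)


@dataclass
class LinearFit:
    slope: float
    intercept: float
    r2: float
    p: float
    n: int


def phylum_vs_nci(phylum_abundance: pd.Series,
                  nci_scores: pd.Series) -> LinearFit:
    """OLS of a phylum's relative abundance on the NCI (two-sided slope p)."""
    common = [s for s in nci_scores.index if s in phylum_abundance.index]
    if len(common) < 3:
        raise ValueError("need >= 3 aligned samples")
    x = nci_scores.loc[common].to_numpy(dtype=float)
    y = phylum_abundance.loc[common].to_numpy(dtype=float)
    if np.ptp(x) == 0:
        raise ValueError("zero-variance NCI")
    res = stats.linregress(x, y)
    return LinearFit(slope=float(res.slope), intercept=float(res.intercept),
                     r2=float(res.rvalue ** 2), p=float(res.pvalue),
                     n=len(common))
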