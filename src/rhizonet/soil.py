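"""Soil summaries: fumigation-extraction microbial biomass, group ratio
statistics, and one-way ANOVA with a Tukey compact letter display."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

#: chloroform fumigation-extraction efficiency coefficients
BIOMASS_COEFFICIENTS = {"C": 0.45, "N": 0.54, "P": 0.40}


class NegativeBiomassWarning(UserWarning):
    """Fumigated extract below the non-fumigated one."""


def microbial_biomass(fumigated, nonfumigated, element: str):
    """Microbial biomass pool (mg/kg) from a fumigation-extraction pair.

    MB_E = (E_fumigated - E_non-fumigated) / k_E with k_C = 0.45,
    k_N = 0.54, k_P = 0.40.  Negative results (non-fumigated extract
    larger) are returned as-is but trigger ``NegativeBiomassWarning``.
    """
    if element not in BIOMASS_COEFFICIENTS:
        raise ValueError(f"element must be one of {set(BIOMASS_COEFFICIENTS)}")
    fumigated = np.asarray(fumigated, dtype=float)
    nonfumigated = np.asarray(nonfumigated, dtype=float)
    if not (np.isfinite(fumigated).all() and np.isfinite(nonfumigated).all()):
        raise ValueError("fumigation measurements must be finite")
    out = (fumigated - nonfumigated) / BIOMASS_COEFFICIENTS[element]
    if np.any(out < 0):
        warnings.warn("negative microbial biomass (non-fumigated > fumigated)",
                      NegativeBiomassWarning, stacklevel=2)
    return out if out.ndim else float(out)


def ratio_excess(a: float, b: float, mode: str = "times") -> float:
    """How much larger a is than b: 'times' -> a/b - 1, 'percent' -> 100x that."""
    if b <= 0:
        raise ValueError("reference mean must be positive")
    if mode not in ("times", "percent"):
        raise ValueError("mode must be 'times' or 'percent'")
    excess = a / b - 1.0
    return excess * 100.0 if mode == "percent" else excess


@dataclass
class GroupSummary:
    """Per-group mean/SE/n with ANOVA F, p and significance letters."""

    variable: str
    means: pd.Series
    ses: pd.Series
    ns: pd.Series
    f: float
    p: float
    letters: dict[str, str]
    alpha: float = 0.05
    tukey_p: pd.DataFrame | None = field(default=None, repr=False)

    def format_row(self) -> dict[str, str]:
        return {g: f"{self.means[g]:.2f} ± {self.ses[g]:.2f} "
                   f"{self.letters[g]}" for g in self.means.index}


def _compact_letter_display(names, means, pmat, alpha):
    """Insert-and-absorb compact letter display.

    Letter sets start as one set of all groups; each significant pair
    splits every set containing both; subsets of other sets are absorbed.
    Letters are assigned 'a', 'b', ... in descending-mean order.
    """
    order = sorted(range(len(names)), key=lambda i: -means[i])
    sets: list[set[int]] = [set(range(len(names)))]
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            if pmat[i][j] <= alpha:
                new_sets = []
                for s in sets:
                    if i in s and j in s:
                        new_sets.extend((s - {i}, s - {j}))
                    else:
                        new_sets.append(s)
                # absorb: drop sets contained in another
                sets = [s for s in new_sets
                        if s and not any(s < t for t in new_sets)]
                # dedupe
                uniq = []
                for s in sets:
                    if s not in uniq:
                        uniq.append(s)
                sets = uniq
    # order letter sets by the best (largest) mean they contain
    sets.sort(key=lambda s: min(order.index(i) for i in s))
    letters = {i: "" for i in range(len(names))}
    for k, s in enumerate(sets):
        ch = chr(ord("a") + k)
        for i in s:
            letters[i] += ch
    return {names[i]: "".join(sorted(letters[i])) for i in range(len(names))}


def anova_with_letters(values_by_group: dict, variable: str = "",
                       alpha: float = 0.05) -> GroupSummary:
    """One-way ANOVA + Tukey HSD with a compact letter display.

    Groups sharing a letter are not significantly different at ``alpha``;
    the group with the largest mean always carries 'a'.
    """
    names = list(values_by_group)
    arrays = [np.asarray(values_by_group[g], dtype=float) for g in names]
    if len(names) < 2 or any(a.size < 2 for a in arrays):
        raise ValueError("need >= 2 groups with >= 2 values each")
    if all(np.ptp(a) == 0 for a in arrays):
        raise ValueError("zero within-group variance in every group")
    f, p = stats.f_oneway(*arrays)
    hsd = stats.tukey_hsd(*arrays)
    pmat = hsd.pvalue
    means = np.array([a.mean() for a in arrays])
    letters = _compact_letter_display(names, means, pmat, alpha)
    return GroupSummary(
        variable=variable,
        means=pd.Series(means, index=names),
        ses=pd.Series([a.std(ddof=1) / np.sqrt(a.size) for a in arrays],
                      index=names),
        ns=pd.Series([a.size for a in arrays], index=names),
        f=float(f), p=float(p), letters=letters, alpha=alpha,
        tukey_p=pd.DataFrame(pmat, index=names, columns=names),
    )


def summarize_soil(meta, variables=None, alpha: float = 0.05) -> pd.DataFrame:
    """Summary table (one row per variable, one 'mean +/- SE letter'
    column per group) plus ANOVA F and p columns."""
    df = meta.table
    if variables is None:
        variables = [c for c in df.columns
                     if c != "group" and pd.api.types.is_numeric_dtype(df[c])]
    groups = sorted(df["group"].unique())
    rows = {}
    for v in variables:
        by_group = {g: df.loc[df["group"] == g, v].to_numpy() for g in groups}
        s = anova_with_letters(by_group, variable=v, alpha=alpha)
        row = s.format_row()
        row["F"] = f"{s.f:.2f}"
        row["p"] = f"{s.p:.4g}"
        rows[v] = row
    return pd.DataFrame(rows).T
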