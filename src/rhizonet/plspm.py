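"""Partial least squares path modeling (PLS-PM), Lohmöller style.

Latent variables are composites of reflective (mode A) indicator blocks.
The algorithm alternates outer estimation (latent = standardized weighted
sum of its indicators) and inner estimation (proxy = weighted sum of
connected latents under the centroid, factorial or path scheme) until the
outer weights stabilise.  Structural path coefficients then come from OLS
of each endogenous latent on its predecessors; significance from a
row-resampling bootstrap with sign alignment.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

SCHEMES = ("centroid", "factorial", "path")


@dataclass
class PlsPmSpec:
    """Block definitions and the (lower-triangular) inner path structure.

    ``inner.loc[j, k] = True`` means block k -> block j (row receives
    from column) in the block order given by ``blocks``.
    """

    blocks: dict[str, list[str]]         # block -> indicator columns
    inner: pd.DataFrame                  # boolean, lower triangular
    scheme: str = "centroid"
    max_iter: int = 300
    tol: float = 1e-7
    bootstrap_n: int = 500
    seed: int = 0

    def __post_init__(self):
        names = list(self.blocks)
        self.inner = self.inner.reindex(index=names,
                                        columns=names).fillna(False)
        inner = self.inner.to_numpy(dtype=bool)
        if np.any(np.triu(inner, k=0)):
            raise ValueError("inner matrix must be strictly lower "
                             "triangular in block order (acyclic)")
        if self.scheme not in SCHEMES:
            raise ValueError(f"scheme must be one of {SCHEMES}")
        seen: set[str] = set()
        for b, cols in self.blocks.items():
            if not cols:
                raise ValueError(f"block {b!r} has no indicators")
            dup = seen & set(cols)
            if dup:
                raise ValueError(f"indicator(s) in two blocks: {dup}")
            seen |= set(cols)

    @property
    def block_names(self) -> list[str]:
        return list(self.blocks)

    def edges(self) -> list[tuple[str, str]]:
        names = self.block_names
        inner = self.inner.to_numpy(dtype=bool)
        return [(names[k], names[j]) for j in range(len(names))
                for k in range(len(names)) if inner[j, k]]


@dataclass
class PlsPmResult:
    outer_weights: pd.Series
    loadings: pd.Series
    scores: pd.DataFrame                 # samples x blocks, unit variance
    paths: pd.DataFrame                  # rows: endogenous, cols: predecessors
    r2: pd.Series
    iterations: int
    bootstrap: pd.DataFrame | None = None

    def path_table(self) -> pd.DataFrame:
        rows = []
        for j in self.paths.index:
            for k in self.paths.columns:
                v = self.paths.loc[j, k]
                if not np.isnan(v):
                    rows.append({"from": k, "to": j, "coefficient": v})
        return pd.DataFrame(rows)


def _standardize(X: np.ndarray) -> np.ndarray:
    sd = X.std(axis=0)
    if np.any(sd == 0):
        raise ValueError("constant indicator column")
    return (X - X.mean(axis=0)) / sd


class ConvergenceError(RuntimeError):
    def __init__(self, delta):
        super().__init__(f"outer weights did not converge (last delta "
                         f"{delta:.3e})")
        self.delta = delta


def fit_plspm(data: pd.DataFrame, spec: PlsPmSpec,
              _return_weights: bool = False) -> PlsPmResult:
    """Fit the path model.  Indicators are standardized internally; latent
    scores have unit variance.  After convergence each latent is oriented
    so the sum of its outer loadings is positive."""
    names = spec.block_names
    if len(data) <= len(names):
        raise ValueError("need more samples than blocks")
    missing = [c for cols in spec.blocks.values() for c in cols
               if c not in data.columns]
    if missing:
        raise KeyError(f"indicator column(s) not in data: {missing}")
    n = len(data)
    Xb = {b: _standardize(data[cols].to_numpy(dtype=float))
          for b, cols in spec.blocks.items()}
    inner = spec.inner.to_numpy(dtype=bool)
    linked = inner | inner.T
    w = {b: np.ones(X.shape[1]) for b, X in Xb.items()}

    def latent_scores(weights):
        Y = np.column_stack([Xb[b] @ weights[b] for b in names])
        return _standardize(Y)

    it = 0
    for it in range(1, spec.max_iter + 1):
        Y = latent_scores(w)
        C = (Y.T @ Y) / n
        # inner estimation
        E = np.zeros_like(C)
        for j in range(len(names)):
            for k in range(len(names)):
                if not linked[j, k]:
                    continue
                if spec.scheme == "centroid":
                    E[j, k] = np.sign(C[j, k]) or 1.0
                elif spec.scheme == "factorial":
                    E[j, k] = C[j, k]
        if spec.scheme == "path":
            for j in range(len(names)):
                pred = np.nonzero(inner[j])[0]
                if pred.size:
                    coefs = np.linalg.lstsq(Y[:, pred], Y[:, j],
                                            rcond=None)[0]
                    E[j, pred] = coefs
                succ = np.nonzero(inner[:, j])[0]
                for s in succ:
                    E[j, s] = C[j, s]
        Z = Y @ E.T
        new_w = {}
        delta = 0.0
        for bi, b in enumerate(names):
            # isolated blocks self-proxy: power iteration toward the
            # block's first principal axis
            z = Y[:, bi] if not linked[bi].any() else Z[:, bi]
            if np.std(z) == 0:
                new_w[b] = w[b]
                continue
            wb = Xb[b].T @ z / n               # mode A: corr(indicator, proxy)
            wb = wb / np.sqrt((Xb[b] @ wb).var())
            # fix sign freedom per iteration for comparability
            if wb.sum() < 0:
                wb = -wb
            delta = max(delta, float(np.max(np.abs(wb - w[b]))))
            new_w[b] = wb
        w = new_w
        if delta < spec.tol:
            break
    else:
        raise ConvergenceError(delta)

    Y = latent_scores(w)
    # orient: sum of loadings positive per block
    for bi, b in enumerate(names):
        load = Xb[b].T @ Y[:, bi] / n
        if load.sum() < 0:
            Y[:, bi] = -Y[:, bi]
            w[b] = -w[b]
    scores = pd.DataFrame(Y, index=data.index, columns=names)
    weights, loadings = {}, {}
    for bi, b in enumerate(names):
        load = Xb[b].T @ Y[:, bi] / n
        for c, wv, lv in zip(spec.blocks[b], w[b], load):
            weights[c] = wv
            loadings[c] = lv
    paths = pd.DataFrame(np.nan, index=names, columns=names)
    r2 = {}
    for j, b in enumerate(names):
        pred = np.nonzero(inner[j])[0]
        if not pred.size:
            continue
        coefs = np.linalg.lstsq(Y[:, pred], Y[:, j], rcond=None)[0]
        fitted = Y[:, pred] @ coefs
        r2[b] = float(fitted.var() / Y[:, j].var())
        for k, c in zip(pred, coefs):
            paths.loc[b, names[k]] = float(c)
    result = PlsPmResult(
        outer_weights=pd.Series(weights), loadings=pd.Series(loadings),
        scores=scores, paths=paths,
        r2=pd.Series(r2, dtype=float), iterations=it)
    if _return_weights:
        result._weights = {b: w[b].copy() for b in names}  # type: ignore
    return result


def bootstrap_paths(data: pd.DataFrame, spec: PlsPmSpec,
                    max_failure_rate: float = 0.2) -> pd.DataFrame:
    """Bootstrap path coefficients: resample rows with replacement, refit,
    align each replicate's latent orientations to the full-sample solution
    (by outer-weight inner product), and summarise.

    Returns one row per structural edge with the estimate, bootstrap mean,
    SE, percentile CI and a two-sided normal-approximation p-value.
    """
    if spec.bootstrap_n < 100:
        raise ValueError("bootstrap_n must be >= 100")
    full = fit_plspm(data, spec, _return_weights=True)
    full_w = full._weights  # type: ignore[attr-defined]
    names = spec.block_names
    edges = spec.edges()
    rng = np.random.default_rng(spec.seed)
    draws = []
    failures = 0
    for _ in range(spec.bootstrap_n):
        idx = rng.integers(0, len(data), len(data))
        sample = data.iloc[idx]
        try:
            rep = fit_plspm(sample, spec, _return_weights=True)
        except (ValueError, ConvergenceError, np.linalg.LinAlgError):
            failures += 1
            continue
        rep_w = rep._weights  # type: ignore[attr-defined]
        flip = {b: (-1.0 if float(rep_w[b] @ full_w[b]) < 0 else 1.0)
                for b in names}
        draws.append([rep.paths.loc[j, k] * flip[j] * flip[k]
                      for k, j in edges])
    if failures > max_failure_rate * spec.bootstrap_n:
        raise RuntimeError(f"{failures}/{spec.bootstrap_n} bootstrap "
                           "replicates failed to converge")
    B = np.array(draws)
    rows = []
    from scipy import stats as sps
    for e, (k, j) in enumerate(edges):
        est = full.paths.loc[j, k]
        se = float(B[:, e].std(ddof=1))
        lo, hi = np.percentile(B[:, e], [2.5, 97.5])
        p = (2.0 * sps.norm.sf(abs(est) / se)) if se > 0 else (
            0.0 if est != 0 else 1.0)
        rows.append({"from": k, "to": j, "estimate": float(est),
                     "boot_mean": float(B[:, e].mean()), "boot_se": se,
                     "ci_low": float(lo), "ci_high": float(hi),
                     "p": float(p)})
    return pd.DataFrame(rows)


#: default latent structure: soil physical state feeding chemistry,
#: biomass and diversity; chemistry feeding biomass and diversity; and
#: biomass, diversity and dominant-phylum composition feeding network
#: complexity, with diversity also shaping the dominant phyla.
DEFAULT_EDGES = [
    ("physical", "chemical"),
    ("physical", "biomass"),
    ("physical", "diversity"),
    ("chemical", "biomass"),
    ("chemical", "diversity"),
    ("biomass", "network_complexity"),
    ("diversity", "dominant_phyla"),
    ("diversity", "network_complexity"),
    ("dominant_phyla", "network_complexity"),
]

DEFAULT_BLOCKS = {
    "physical": ["pH", "SWC", "Na", "K"],
    "chemical": ["TC", "TOC", "TN", "TP", "AN", "OP"],
    "biomass": ["MBC", "MBN", "MBP"],
    "diversity": ["bact_shannon", "bact_ace", "fungi_shannon", "fungi_ace"],
    "dominant_phyla": ["dominant_phylum_abundance"],
    "network_complexity": ["NCI"],
}


def default_spec(blocks: dict[str, list[str]] | None = None,
                 edges: list[tuple[str, str]] | None = None,
                 **kwargs) -> PlsPmSpec:
    """The pipeline's default path model over soil physical, chemical and
    biomass blocks, alpha diversity, dominant phyla and the NCI."""
    blocks = dict(blocks or DEFAULT_BLOCKS)
    edges = list(edges or DEFAULT_EDGES)
    names = list(blocks)
    inner = pd.DataFrame(False, index=names, columns=names)
    for src, dst in edges:
        inner.loc[dst, src] = True
    return PlsPmSpec(blocks=blocks, inner=inner, **kwargs)
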