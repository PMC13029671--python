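"""Truth-known synthetic data: soil tables matching the published group
means, compositional OTU count tables with planted association blocks,
and latent-path indicator data for path-model recovery.

The soil simulator treats each reported group mean +/- SE (n = 6) as a
generative Normal(mean, SE * sqrt(n)) truncated at zero by resampling.
Fumigation pairs are constructed so that applying the fumigation-
extraction formulas recovers the drawn biomass values exactly.

OTU tables follow a log-normal latent factor model: per-OTU baseline
plus signed block-factor loadings plus Gaussian noise on the log scale,
converted to counts by a multinomial draw per sample at a log-normally
distributed library size.  Members of a block sharing a loading sign are
positively rank-associated; opposite signs are negatively associated.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import OtuTable, SampleMetadata, TaxonomyMap, UNCLASSIFIED
from .reference import SOIL_SUMMARY_N, soil_summary_frames
from .soil import BIOMASS_COEFFICIENTS

#: baseline non-fumigated extract levels (mg/kg) used when inverting the
#: fumigation formulas; arbitrary plausible values, the recovered biomass
#: does not depend on them
_NONFUM_BASELINE = {"DOC": 120.0, "TN": 30.0, "TP": 5.0}
_BIOMASS_OF = {"DOC": ("MBC", "C"), "TN": ("MBN", "N"), "TP": ("MBP", "P")}


@dataclass
class SoilSimParams:
    """Per-group per-variable mean and SE (defaults: the published soil
    table), group size and seed."""

    means: pd.DataFrame = None          # variables x groups
    ses: pd.DataFrame = None
    n_per_group: int = 6
    reported_n: int = SOIL_SUMMARY_N    # n behind the published SEs
    seed: int = 0

    def __post_init__(self):
        if self.means is None or self.ses is None:
            means, ses = soil_summary_frames()
            self.means = means if self.means is None else self.means
            self.ses = ses if self.ses is None else self.ses
        if (self.ses.to_numpy() < 0).any():
            raise ValueError("SEs must be non-negative")
        if self.n_per_group < 2:
            raise ValueError("n_per_group must be >= 2")


def _truncated_normal(rng, mean, sd, size):
    """Normal draws resampled (not clipped) until non-negative."""
    out = rng.normal(mean, sd, size)
    for _ in range(1000):
        bad = out < 0
        if not bad.any():
            return out
        out[bad] = rng.normal(mean, sd, bad.sum())
    return np.maximum(out, 0.0)


def simulate_soil(params: SoilSimParams | None = None) -> SampleMetadata:
    """Draw a per-sample soil table; group SD is SE * sqrt(reported_n).

    Fumigation pairs (DOC/TN/TP, fumigated and non-fumigated) are emitted
    such that the fumigation-extraction formulas reproduce the drawn
    MBC/MBN/MBP exactly.
    """
    params = params or SoilSimParams()
    rng = np.random.default_rng(params.seed)
    sd = params.ses * np.sqrt(params.reported_n)
    rows = []
    index = []
    for g in params.means.columns:
        for i in range(params.n_per_group):
            index.append(f"{g}{i + 1}")
            rows.append({"group": g})
    df = pd.DataFrame(rows, index=index)
    for v in params.means.index:
        vals = np.concatenate([
            _truncated_normal(rng, params.means.loc[v, g], sd.loc[v, g],
                              params.n_per_group)
            for g in params.means.columns])
        df[v] = vals
    for extract, (pool, element) in _BIOMASS_OF.items():
        if pool not in df.columns:
            continue
        base = _NONFUM_BASELINE[extract] * (1 + 0.05 * rng.standard_normal(len(df)))
        df[f"{extract}_nonfum"] = base
        df[f"{extract}_fum"] = base + BIOMASS_COEFFICIENTS[element] * df[pool]
    return SampleMetadata(table=df)


@dataclass
class AssociationBlock:
    """A planted association block: member OTUs, a loading sign per
    member, and a shared strength in [0, 1]."""

    members: list[str]
    signs: list[int] | None = None
    strength: float = 0.95

    def __post_init__(self):
        if self.signs is None:
            self.signs = [1] * len(self.members)
        if len(self.signs) != len(self.members):
            raise ValueError("signs must match members")
        if not 0.0 <= self.strength <= 1.0:
            raise ValueError("strength must lie in [0, 1]")


@dataclass
class NetworkSimParams:
    n_bacterial_otus: int = 200
    n_fungal_otus: int = 100
    n_samples: int = 18
    blocks: list[AssociationBlock] = field(default_factory=list)
    library_size_median: float = 1e5
    library_size_sigma: float = 0.25     # log-normal sigma
    baseline_sd: float = 0.5
    factor_sd: float = 1.0               # SD of the per-(block, sample) factor
    noise_sd: float = 0.1                # overdispersion on the log scale
    sample_groups: list[str] | None = None
    group_otu_offsets: dict[str, dict[str, float]] | None = None
    seed: int = 0

    def __post_init__(self):
        if self.n_samples < 4:
            raise ValueError("need n_samples >= 4")
        seen: set[str] = set()
        for b in self.blocks:
            overlap = seen & set(b.members)
            if overlap:
                raise ValueError(f"blocks must be disjoint; reused {overlap}")
            seen |= set(b.members)


@dataclass
class SyntheticTruth:
    """Ground truth of a simulation run."""

    associated_pairs: list[tuple[str, str, int]] = field(default_factory=list)
    latent: pd.DataFrame | None = None          # samples x OTUs, log scale
    group_offsets: dict | None = None
    path_coefficients: pd.DataFrame | None = None
    standardized_paths: pd.DataFrame | None = None
    latent_scores: pd.DataFrame | None = None


def default_otu_ids(n_bact: int, n_fungi: int) -> tuple[list[str], list[str]]:
    return ([f"B{i:04d}" for i in range(1, n_bact + 1)],
            [f"F{i:04d}" for i in range(1, n_fungi + 1)])


def make_blocks(otu_ids, n_blocks: int, block_size: int,
                strength: float = 0.95,
                signs: list[int] | None = None) -> list[AssociationBlock]:
    """Disjoint association blocks over the head of the OTU pool, each
    with the same strength and per-member loading signs."""
    if n_blocks * block_size > len(otu_ids):
        raise ValueError("not enough OTUs for the requested blocks")
    return [AssociationBlock(
        members=list(otu_ids[b * block_size:(b + 1) * block_size]),
        signs=list(signs) if signs else None, strength=strength)
        for b in range(n_blocks)]


_BACT_PHYLA = ("Proteobacteria", "Firmicutes", "Actinobacteriota",
               "Gemmatimonadota", "Desulfobacterota", "Acidobacteriota",
               "Bacteroidota")
_FUNGI_PHYLA = ("Ascomycota", "Basidiomycota", "Mucoromycota",
                "Mortierellomycota")


def default_taxonomy(bact_ids, fungi_ids) -> TaxonomyMap:
    """Cyclic phylum/genus assignment over realistic phylum names."""
    rows = {}
    for i, o in enumerate(bact_ids):
        rows[o] = {"kingdom": "bacteria",
                   "phylum": _BACT_PHYLA[i % len(_BACT_PHYLA)],
                   "genus": f"Genus{i % 12:02d}"}
    for i, o in enumerate(fungi_ids):
        rows[o] = {"kingdom": "fungi",
                   "phylum": _FUNGI_PHYLA[i % len(_FUNGI_PHYLA)],
                   "genus": f"FGenus{i % 8:02d}"}
    df = pd.DataFrame(rows).T
    for rank in ("class", "order", "family"):
        df[rank] = UNCLASSIFIED
    return TaxonomyMap(table=df)


def simulate_otu_tables(params: NetworkSimParams
                        ) -> tuple[OtuTable, OtuTable, TaxonomyMap,
                                   SyntheticTruth]:
    """Compositional bacterial + fungal count tables with planted blocks.

    Latent log abundance: baseline_o (+ group offset) + sum over blocks of
    strength * sign * factor_{block,sample} + noise.  Counts are drawn
    multinomially per sample from softmax(latent) at a log-normal library
    size.  The truth lists every within-block pair with the sign given by
    the product of the member loading signs.
    """
    rng = np.random.default_rng(params.seed)
    bact_ids, fungi_ids = default_otu_ids(params.n_bacterial_otus,
                                          params.n_fungal_otus)
    all_ids = bact_ids + fungi_ids
    known = set(all_ids)
    for b in params.blocks:
        unknown = set(b.members) - known
        if unknown:
            raise ValueError(f"block references unknown OTUs: {unknown}")
    n, m = params.n_samples, len(all_ids)
    baseline = rng.normal(0.0, params.baseline_sd, m)
    Z = np.tile(baseline, (n, 1))
    if params.sample_groups is not None:
        if len(params.sample_groups) != n:
            raise ValueError("sample_groups must have one label per sample")
        offsets = params.group_otu_offsets or {}
        col = {o: k for k, o in enumerate(all_ids)}
        for s, grp in enumerate(params.sample_groups):
            for otu, off in offsets.get(grp, {}).items():
                Z[s, col[otu]] += off
    for b in params.blocks:
        factor = rng.normal(0.0, params.factor_sd, n)
        for otu, sign in zip(b.members, b.signs):
            Z[:, all_ids.index(otu)] += b.strength * sign * factor
    Z += rng.normal(0.0, params.noise_sd, Z.shape)
    probs = np.exp(Z - Z.max(axis=1, keepdims=True))
    probs /= probs.sum(axis=1, keepdims=True)
    sizes = np.maximum(1, rng.lognormal(np.log(params.library_size_median),
                                        params.library_size_sigma, n)
                       ).astype(np.int64)
    counts = np.vstack([rng.multinomial(sizes[s], probs[s])
                        for s in range(n)])
    samples = [f"S{s + 1:03d}" for s in range(n)]
    table = pd.DataFrame(counts, index=samples, columns=all_ids)
    bact = OtuTable(counts=table[bact_ids], kingdom="bacteria")
    fungi = OtuTable(counts=table[fungi_ids], kingdom="fungi")
    tax = default_taxonomy(bact_ids, fungi_ids)
    pairs = []
    for b in params.blocks:
        for i in range(len(b.members)):
            for j in range(i + 1, len(b.members)):
                pairs.append((b.members[i], b.members[j],
                              b.signs[i] * b.signs[j]))
    truth = SyntheticTruth(
        associated_pairs=pairs,
        latent=pd.DataFrame(Z, index=samples, columns=all_ids),
        group_offsets=params.group_otu_offsets,
    )
    return bact, fungi, tax, truth


# ---------------------------------------------------------------------------
# latent path-model data


@dataclass
class PlsSimParams:
    """Blocks of reflective indicators around a recursive latent path
    structure (lower-triangular coefficient matrix in block order)."""

    blocks: dict[str, list[float]]       # block -> indicator loadings (0, 1]
    paths: pd.DataFrame                  # square, lower triangular, floats
    noise_sd: float = 0.2                # indicator measurement noise SD
    disturbance: str = "standardize"     # keep every latent at unit variance
    n: int = 500
    seed: int = 0

    def __post_init__(self):
        names = list(self.blocks)
        self.paths = self.paths.reindex(index=names, columns=names).fillna(0.0)
        upper = np.triu(self.paths.to_numpy(), k=0)
        if np.any(upper != 0):
            raise ValueError("path matrix must be strictly lower triangular "
                             "(acyclic in block order)")
        for b, loadings in self.blocks.items():
            if not loadings or any(not 0 < l <= 1 for l in loadings):
                raise ValueError(f"loadings of {b} must lie in (0, 1]")


def simulate_plspm_data(params: PlsSimParams
                        ) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Generate latent scores recursively along the path equations and
    reflective indicators indicator = loading * latent + noise.

    Each endogenous latent is rescaled to unit variance after adding its
    Gaussian disturbance, so the prescribed coefficients are directly the
    standardized path coefficients (stored in the truth both ways).
    """
    rng = np.random.default_rng(params.seed)
    names = list(params.blocks)
    B = params.paths.to_numpy()
    n = params.n
    scores = np.zeros((n, len(names)))
    for j, name in enumerate(names):
        pred = np.nonzero(B[j])[0]
        if pred.size == 0:
            scores[:, j] = rng.standard_normal(n)
            continue
        mean = scores[:, pred] @ B[j, pred]
        explained = float(np.var(mean))
        resid_var = max(1.0 - explained, 1e-6)
        xi = mean + rng.normal(0.0, np.sqrt(resid_var), n)
        scores[:, j] = (xi - xi.mean()) / xi.std()
    data = {}
    for j, name in enumerate(names):
        for k, lam in enumerate(params.blocks[name]):
            data[f"{name}_x{k + 1}"] = (lam * scores[:, j]
                                        + rng.normal(0.0, params.noise_sd, n))
    indicators = pd.DataFrame(data, index=[f"S{i + 1:04d}" for i in range(n)])
    truth = SyntheticTruth(
        path_coefficients=params.paths.copy(),
        standardized_paths=params.paths.copy(),
        latent_scores=pd.DataFrame(scores, index=indicators.index,
                                   columns=names),
    )
    return indicators, truth
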