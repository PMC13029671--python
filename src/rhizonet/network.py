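"""Bacterial-fungal Spearman co-occurrence networks and their topology.

Edges connect OTU pairs (within and across kingdoms) whose tie-corrected
Spearman correlation passes |rho| > rho_threshold with p < p_threshold.
At n <= 7 shared samples the permutation null is enumerated exactly
(the t approximation is unreliable there); larger n uses the t
approximation.  Edge distance weight defaults to 1 - |rho| so that
stronger correlations are shorter; path-based statistics use it.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from networkx.algorithms import community as nx_community

from ._stats import (pairwise_spearman_table, spearman_matrix,
                     spearman_rho_p)
from .io import (OtuTable, RelAbundanceTable, SampleMetadata, TaxonomyMap,
                 UNCLASSIFIED)

METRIC_COLUMNS = ("nodes", "edges", "density", "transitivity", "diameter",
                  "avg_path_length")


@dataclass
class CorrelationNetwork:
    """Signed undirected OTU graph with correlation-derived weights."""

    graph: nx.Graph
    rho_threshold: float = 0.9
    p_threshold: float = 0.01
    weighting: str = "one_minus_abs_rho"
    empty_flag: bool = False

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def edge_table(self) -> pd.DataFrame:
        rows = [{"source": u, "target": v, **d}
                for u, v, d in self.graph.edges(data=True)]
        return pd.DataFrame(rows)


def _distance_weight(rho: float, weighting: str) -> float:
    if weighting == "one_minus_abs_rho":
        return 1.0 - abs(rho)
    if weighting == "unit":
        return 1.0
    if weighting == "inverse_abs_rho":
        return 1.0 / abs(rho)
    raise ValueError(f"unknown weighting {weighting!r}")


def spearman_edges(bact: RelAbundanceTable, fungi: RelAbundanceTable,
                   taxonomy: TaxonomyMap | None = None,
                   prevalence_min: int = 3, rho_threshold: float = 0.9,
                   p_threshold: float = 0.01,
                   weighting: str = "one_minus_abs_rho") -> CorrelationNetwork:
    """Build the co-occurrence network over concatenated bacterial and
    fungal OTUs.

    OTUs seen (abundance > 0) in fewer than ``prevalence_min`` samples are
    excluded first: with few samples, zero-dominated pairs yield spurious
    perfect rank correlations.  Isolated nodes are dropped.
    """
    shared = [s for s in bact.sample_ids if s in set(fungi.sample_ids)]
    if len(shared) < 4:
        raise ValueError("need at least 4 shared samples")
    tables = {"bacteria": bact.values.loc[shared],
              "fungi": fungi.values.loc[shared]}
    frames, kingdom_of = [], {}
    for kingdom, df in tables.items():
        keep = df.columns[(df > 0).sum(axis=0) >= prevalence_min]
        frames.append(df[keep])
        kingdom_of.update({o: kingdom for o in keep})
    X = pd.concat(frames, axis=1)
    otus = list(X.columns)
    n = len(shared)
    C = spearman_matrix(X.to_numpy())

    g = nx.Graph()
    for i, j in zip(*np.nonzero(np.triu(np.abs(C) > rho_threshold, k=1))):
        rho, p = spearman_rho_p(X.iloc[:, i], X.iloc[:, j])
        if np.isnan(rho) or abs(rho) <= rho_threshold or p >= p_threshold:
            continue
        u, v = otus[i], otus[j]
        g.add_edge(u, v, rho=float(rho), sign=int(np.sign(rho)),
                   p=float(p), distance=_distance_weight(rho, weighting))
    for node in g.nodes:
        g.nodes[node]["kingdom"] = kingdom_of[node]
        if taxonomy is not None and node in taxonomy.table.index:
            g.nodes[node]["phylum"] = str(taxonomy.table.loc[node, "phylum"])
        else:
            g.nodes[node]["phylum"] = UNCLASSIFIED
    return CorrelationNetwork(graph=g, rho_threshold=rho_threshold,
                              p_threshold=p_threshold, weighting=weighting)


@dataclass
class NetworkMetrics:
    """One networks-parameter row: node/edge counts plus topology."""

    bacterial_nodes: int
    fungal_nodes: int
    edges: int
    positive_edges: int
    negative_edges: int
    modularity: float
    n_modules: int
    avg_path_length: float
    diameter: float
    density: float
    clustering_coefficient: float
    betweenness_centralization: float
    pos_neg_ratio: float

    def as_series(self) -> pd.Series:
        return pd.Series(vars(self))


def modules(net: CorrelationNetwork) -> list[frozenset]:
    """Node partition from deterministic greedy (CNM) modularity
    maximization on the unweighted graph."""
    return [frozenset(c) for c in
            nx_community.greedy_modularity_communities(net.graph)]


def betweenness_centralization(g: nx.Graph) -> float:
    """Freeman centralization of normalized shortest-path betweenness,
    1 for a star (unweighted paths)."""
    n = g.number_of_nodes()
    if n < 3:
        return 0.0
    b = nx.betweenness_centrality(g, normalized=True)
    bmax = max(b.values())
    return float(sum(bmax - v for v in b.values()) / (n - 1))


def _pairwise_distances(g: nx.Graph, weight: str | None):
    dists = []
    for source, lengths in nx.all_pairs_dijkstra_path_length(g, weight=weight):
        for target, dist in lengths.items():
            if source < target:
                dists.append(dist)
    return dists


def topology(net: CorrelationNetwork,
             weight: str | None = "distance") -> NetworkMetrics:
    """Topology statistics of a correlation network.

    Modularity and module count come from deterministic greedy (CNM)
    modularity maximization on the unweighted graph; average path length
    and diameter use the edge distance weights and cover connected pairs
    only; density, transitivity and betweenness centralization are
    unweighted.
    """
    g = net.graph
    if g.number_of_nodes() == 0:
        return NetworkMetrics(*([0] * 5), *([np.nan] * 7),
                              pos_neg_ratio=np.nan)  # type: ignore[misc]
    kingdoms = nx.get_node_attributes(g, "kingdom")
    n_bact = sum(1 for k in kingdoms.values() if k == "bacteria")
    n_fungi = sum(1 for k in kingdoms.values() if k == "fungi")
    signs = [d.get("sign", 1) for _, _, d in g.edges(data=True)]
    pos = sum(1 for s in signs if s > 0)
    neg = len(signs) - pos
    communities = modules(net)
    q = nx_community.modularity(g, communities)
    dists = _pairwise_distances(g, weight)
    finite = [d for d in dists if np.isfinite(d)]
    return NetworkMetrics(
        bacterial_nodes=n_bact, fungal_nodes=n_fungi,
        edges=g.number_of_edges(), positive_edges=pos, negative_edges=neg,
        modularity=float(q), n_modules=len(communities),
        avg_path_length=float(np.mean(finite)) if finite else np.nan,
        diameter=float(np.max(finite)) if finite else np.nan,
        density=float(nx.density(g)),
        clustering_coefficient=float(nx.transitivity(g)),
        betweenness_centralization=betweenness_centralization(g),
        pos_neg_ratio=pos / neg if neg else np.nan,
    )


def sample_subnetwork(net: CorrelationNetwork, t: OtuTable | pd.DataFrame,
                      sample_id: str,
                      presence_min: int = 1) -> CorrelationNetwork:
    """Induced subgraph on OTUs with count >= presence_min in one sample.

    ``t`` may be an OtuTable or a plain samples x OTUs count frame (e.g.
    the bacterial and fungal tables stacked over the OTU axis).
    """
    counts = t.counts if isinstance(t, OtuTable) else t
    if sample_id not in counts.index:
        raise KeyError(f"unknown sample {sample_id!r}")
    row = counts.loc[sample_id]
    present = set(row.index[row >= presence_min]) & set(net.graph.nodes)
    sub = net.graph.subgraph(present).copy()
    return CorrelationNetwork(graph=sub, rho_threshold=net.rho_threshold,
                              p_threshold=net.p_threshold,
                              weighting=net.weighting,
                              empty_flag=sub.number_of_nodes() == 0)


def per_sample_metrics(net: CorrelationNetwork, tables: list[OtuTable],
                       presence_min: int = 1,
                       metrics=METRIC_COLUMNS) -> pd.DataFrame:
    """Subnetwork parameter matrix, one row per sample.

    ``tables`` are stacked over the OTU axis (e.g. the bacterial and
    fungal tables); a sample's subnetwork keeps OTUs present in it.
    """
    counts = pd.concat([t.counts for t in tables], axis=1)
    rows = {}
    for s in counts.index:
        sub = sample_subnetwork(net, counts, s, presence_min=presence_min)
        m = topology(sub)
        rows[s] = {"nodes": sub.n_nodes, "edges": m.edges,
                   "density": m.density, "transitivity":
                   m.clustering_coefficient, "diameter": m.diameter,
                   "avg_path_length": m.avg_path_length}
    df = pd.DataFrame(rows).T
    return df[list(metrics)]


def subnetwork_env_correlation(metrics: pd.DataFrame, meta: SampleMetadata,
                               variables=None) -> pd.DataFrame:
    """Spearman rho/p between each subnetwork metric and each soil
    variable; constant metrics come back as missing values."""
    env = meta.numeric(variables)
    common = [s for s in metrics.index if s in env.index]
    if len(common) < 5:
        raise ValueError("need >= 5 samples with metrics and metadata")
    usable = metrics.loc[common].dropna(axis=1, how="any")
    rho, p = pairwise_spearman_table(usable, env.loc[common])
    out = rho.stack().rename("rho").to_frame()
    out["p"] = p.stack()
    out.index.names = ["metric", "variable"]
    return out.reset_index()
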