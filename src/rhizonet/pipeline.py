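"""File-based pipeline stages behind the command-line interface.

Stages communicate through TSV artifacts in one output directory so each
is independently runnable and resumable; a JSON manifest records the
configuration hash, seeds and per-stage row counts.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import complexity as cx
from . import diversity as dv
from . import drivers as dr
from . import io as rio
from . import network as nw
from . import plspm as pm
from . import simulate as sim
from . import soil as sl

log = logging.getLogger("rhizonet")

STAGES = ("simulate", "soil", "diversity", "drivers", "network", "nci",
          "plspm")

DEFAULT_CONFIG = {
    "n_per_group": 6,
    "rho_threshold": 0.9,
    "p_threshold": 0.01,
    "prevalence_min": 3,
    "presence_min": 1,
    "dominance_phylum": 0.01,
    "scheme": "centroid",
    "bootstrap_n": 200,
    "n_bacterial_otus": 40,
    "n_fungal_otus": 20,
    "n_blocks": 6,
    "block_size": 6,
    "block_strength": 0.95,
    "noise_sd": 0.1,
}


def stage_seeds(seed: int) -> dict[str, int]:
    """Deterministically split one top-level seed into per-stage seeds."""
    children = np.random.SeedSequence(seed).spawn(len(STAGES))
    return {s: int(c.generate_state(1, np.uint32)[0] % (2**31 - 1))
            for s, c in zip(STAGES, children)}


def _require(path: Path, producer: str) -> Path:
    if not path.exists():
        raise FileNotFoundError(
            f"missing artifact {path.name}: run the '{producer}' stage first")
    return path


def _config_hash(config: dict) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True).encode()).hexdigest()[:16]


class Pipeline:
    def __init__(self, outdir, config: dict | None = None, seed: int = 0):
        self.outdir = Path(outdir)
        self.outdir.mkdir(parents=True, exist_ok=True)
        self.config = {**DEFAULT_CONFIG, **(config or {})}
        self.seed = seed
        self.seeds = stage_seeds(seed)
        self.manifest: dict = {
            "seed": seed, "stage_seeds": self.seeds,
            "config": self.config, "config_hash": _config_hash(self.config),
            "stages": {},
        }

    # -- artifact paths ----------------------------------------------------
    def path(self, name: str) -> Path:
        return self.outdir / name

    def _record(self, stage: str, **info):
        self.manifest["stages"][stage] = info
        with open(self.path("manifest.json"), "w") as fh:
            json.dump(self.manifest, fh, indent=2, sort_keys=True,
                      default=str)

    # -- stages ------------------------------------------------------------
    def simulate(self):
        cfg = self.config
        seed = self.seeds["simulate"]
        meta = sim.simulate_soil(sim.SoilSimParams(
            n_per_group=cfg["n_per_group"], seed=seed))
        bact_ids, fungi_ids = sim.default_otu_ids(cfg["n_bacterial_otus"],
                                                  cfg["n_fungal_otus"])
        pool = bact_ids + fungi_ids
        blocks, k = [], 0
        for _ in range(cfg["n_blocks"]):
            members = pool[k:k + cfg["block_size"]]
            k += cfg["block_size"]
            blocks.append(sim.AssociationBlock(
                members=members, strength=cfg["block_strength"]))
        groups = list(meta.groups)
        params = sim.NetworkSimParams(
            n_bacterial_otus=cfg["n_bacterial_otus"],
            n_fungal_otus=cfg["n_fungal_otus"],
            n_samples=len(groups), blocks=blocks,
            noise_sd=cfg["noise_sd"], sample_groups=groups,
            group_otu_offsets=_complexity_offsets(blocks, groups),
            seed=seed)
        bact, fungi, tax, truth = sim.simulate_otu_tables(params)
        bact.counts.index = meta.table.index
        fungi.counts.index = meta.table.index
        rio.write_metadata(meta, self.path("metadata.tsv"))
        rio.write_otu_table(bact, self.path("otu_bacteria.tsv"))
        rio.write_otu_table(fungi, self.path("otu_fungi.tsv"))
        rio.write_taxonomy(tax, self.path("taxonomy.tsv"))
        pd.DataFrame(truth.associated_pairs,
                     columns=["otu_a", "otu_b", "sign"]).to_csv(
            self.path("truth_pairs.tsv"), sep="\t", index=False)
        self._record("simulate", seed=seed, n_samples=len(groups),
                     n_otus=len(pool), n_truth_pairs=len(
                         truth.associated_pairs))

    def load_inputs(self):
        meta = rio.read_metadata(_require(self.path("metadata.tsv"),
                                          "simulate"))
        bact = rio.read_otu_table(_require(self.path("otu_bacteria.tsv"),
                                           "simulate"), "bacteria")
        fungi = rio.read_otu_table(_require(self.path("otu_fungi.tsv"),
                                            "simulate"), "fungi")
        tax = rio.read_taxonomy(_require(self.path("taxonomy.tsv"),
                                         "simulate"))
        return meta, bact, fungi, tax

    def soil(self):
        meta = rio.read_metadata(_require(self.path("metadata.tsv"),
                                          "simulate"))
        table = sl.summarize_soil(meta)
        table.to_csv(self.path("soil_summary.tsv"), sep="\t")
        self._record("soil", n_variables=len(table))

    def diversity(self):
        meta, bact, fungi, _ = self.load_inputs()
        seed = self.seeds["diversity"]
        alphas = []
        mantels = []
        for t in (bact, fungi):
            a = dv.alpha_diversity(t)
            a.insert(0, "kingdom", t.kingdom)
            alphas.append(a)
            rel = rio.to_relative_abundance(t)
            d = dv.bray_curtis(rel)
            d.to_csv(self.path(f"braycurtis_{t.kingdom}.tsv"), sep="\t")
            ordn = dv.nmds(d, seed=seed)
            ordn.coordinates.assign(stress=ordn.stress).to_csv(
                self.path(f"nmds_{t.kingdom}.tsv"), sep="\t")
            perma = dv.permanova_groups(d, meta.groups, seed=seed)
            env = meta.numeric()
            envd = pd.DataFrame(
                dv.squareform(dv.pdist(
                    (env - env.mean()).div(env.std().replace(0, 1)))),
                index=env.index, columns=env.index)
            mt = dv.mantel(d, envd, seed=seed)
            mantels.append({"kingdom": t.kingdom, "mantel_r": mt.r,
                            "mantel_p": mt.p, "stress": ordn.stress,
                            "permanova_F": perma["pseudo_F"],
                            "permanova_p": perma["p"]})
            axis = dv.axis_env_correlation(ordn, meta)
            axis.to_csv(self.path(f"axis_env_{t.kingdom}.tsv"), sep="\t",
                        index=False)
        pd.concat(alphas).to_csv(self.path("alpha_diversity.tsv"), sep="\t")
        pd.DataFrame(mantels).to_csv(self.path("beta_summary.tsv"),
                                     sep="\t", index=False)
        self._record("diversity", seed=seed, n_samples=len(meta.table))

    def drivers(self):
        meta, bact, fungi, tax = self.load_inputs()
        seed = self.seeds["drivers"]
        dominant_rows = []
        for t in (bact, fungi):
            rel = rio.to_relative_abundance(t)
            phyla = rio.aggregate_by_rank(rel, tax, "phylum")
            dom = dr.select_dominant(phyla, "phylum_1pct")
            for taxon, ab in dom.taxa.items():
                dominant_rows.append({"kingdom": t.kingdom, "rank": "phylum",
                                      "taxon": taxon, "mean_abundance": ab})
            genera = rio.aggregate_by_rank(rel, tax, "genus")
            top = dr.select_dominant(genera, "top10_genus")
            env = meta.numeric()
            heat = dr.taxa_env_spearman(
                genera.values[list(top.taxa.index)], env)
            heat.to_csv(self.path(f"genus_env_{t.kingdom}.tsv"),
                        sep="\t", index=False)
            x1, x2, x3 = dr.metadata_variable_sets(meta)
            vp = dr.variation_partitioning(
                dr.hellinger(genera.values[list(top.taxa.index)]),
                x1, x2, x3)
            pd.Series(vp.fractions).rename("fraction").to_csv(
                self.path(f"varpart_{t.kingdom}.tsv"), sep="\t")
        pd.DataFrame(dominant_rows).to_csv(self.path("dominant_taxa.tsv"),
                                           sep="\t", index=False)
        self._record("drivers", seed=seed, n_dominant=len(dominant_rows))

    def network(self):
        meta, bact, fungi, tax = self.load_inputs()
        cfg = self.config
        relb = rio.to_relative_abundance(bact)
        relf = rio.to_relative_abundance(fungi)
        net = nw.spearman_edges(relb, relf, taxonomy=tax,
                                prevalence_min=cfg["prevalence_min"],
                                rho_threshold=cfg["rho_threshold"],
                                p_threshold=cfg["p_threshold"])
        rio.write_edge_list(net, self.path("network_edges.tsv"))
        rio.write_graphml(net, self.path("network.graphml"))
        m = nw.topology(net)
        m.as_series().rename("value").to_csv(self.path("network_metrics.tsv"),
                                             sep="\t")
        per_sample = nw.per_sample_metrics(net, [bact, fungi],
                                           presence_min=cfg["presence_min"])
        per_sample.to_csv(self.path("subnetwork_metrics.tsv"), sep="\t")
        env_corr = nw.subnetwork_env_correlation(per_sample, meta)
        env_corr.to_csv(self.path("subnetwork_env.tsv"), sep="\t",
                        index=False)
        self._record("network", n_nodes=net.n_nodes, n_edges=net.n_edges)

    def nci(self):
        metrics = pd.read_csv(_require(self.path("subnetwork_metrics.tsv"),
                                       "network"), sep="\t", index_col=0)
        meta = rio.read_metadata(_require(self.path("metadata.tsv"),
                                          "simulate"))
        res = cx.nci(metrics)
        out = res.scores.to_frame()
        out["group"] = meta.groups.loc[out.index]
        for i, pct in enumerate(res.percent_variance):
            out[f"pct_var_PC{i + 1}"] = pct
        out.to_csv(self.path("nci.tsv"), sep="\t")
        summary = cx.nci_group_test(res.scores, meta.groups)
        pd.DataFrame([summary.format_row()]).to_csv(
            self.path("nci_groups.tsv"), sep="\t", index=False)
        self._record("nci", n_samples=len(res.scores),
                     pc1_pct=float(res.percent_variance.iloc[0]))

    def plspm(self):
        meta, bact, fungi, tax = self.load_inputs()
        cfg = self.config
        nci_path = _require(self.path("nci.tsv"), "nci")
        nci_scores = pd.read_csv(nci_path, sep="\t", index_col=0)["NCI"]
        table = meta.numeric().copy()
        for t in (bact, fungi):
            a = dv.alpha_diversity(t)
            table[f"{'bact' if t.kingdom == 'bacteria' else 'fungi'}"
                  "_shannon"] = a["shannon"]
            table[f"{'bact' if t.kingdom == 'bacteria' else 'fungi'}"
                  "_ace"] = a["ace"]
        for t in (bact, fungi):
            rel = rio.to_relative_abundance(t)
            phyla = rio.aggregate_by_rank(rel, tax, "phylum")
            dom = dr.select_dominant(phyla, "phylum_1pct")
            top = dom.taxa.index[0]
            key = "bact" if t.kingdom == "bacteria" else "fungi"
            table[f"{key}_dominant_phylum"] = phyla.values[top]
        table["NCI"] = nci_scores
        table = table.dropna()
        blocks = dict(pm.DEFAULT_BLOCKS)
        blocks["dominant_phyla"] = ["bact_dominant_phylum",
                                    "fungi_dominant_phylum"]
        # keep only indicators that exist and vary in this run
        blocks = {b: [c for c in cols if c in table.columns
                      and table[c].nunique() > 1]
                  for b, cols in blocks.items()}
        spec = pm.default_spec(blocks=blocks, scheme=cfg["scheme"],
                               bootstrap_n=cfg["bootstrap_n"],
                               seed=self.seeds["plspm"])
        result = pm.fit_plspm(table, spec)
        result.path_table().to_csv(self.path("plspm_paths.tsv"), sep="\t",
                                   index=False)
        result.r2.rename("r2").to_csv(self.path("plspm_r2.tsv"), sep="\t")
        boot = pm.bootstrap_paths(table, spec)
        boot.to_csv(self.path("plspm_bootstrap.tsv"), sep="\t", index=False)
        self._record("plspm", n_samples=len(table),
                     n_paths=len(result.path_table()))

    def run(self, stage: str):
        if stage == "all":
            for s in STAGES:
                log.info("running stage %s", s)
                getattr(self, s)()
        elif stage in STAGES:
            log.info("running stage %s", stage)
            getattr(self, stage)()
        else:
            raise ValueError(f"unknown stage {stage!r}")


def _complexity_offsets(blocks, groups) -> dict[str, dict[str, float]]:
    """Planted complexity gradient: later blocks are suppressed in the
    KC- and NT-like groups so RS subnetworks carry the most nodes/edges."""
    uniq = sorted(set(groups))
    offsets: dict[str, dict[str, float]] = {g: {} for g in uniq}
    n = len(blocks)
    for gi, g in enumerate(uniq):
        # group 0 loses the last half, group 1 the last quarter, last none
        n_lost = {0: n // 2, 1: n // 4}.get(gi, 0)
        for b in blocks[n - n_lost:]:
            for otu in b.members:
                offsets[g][otu] = -9.0
    return offsets
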