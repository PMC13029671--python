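"""Tabular and graph I/O: OTU count tables, taxonomy, sample metadata,
relative-abundance tables and network export.

All tabular formats are UTF-8 tab-separated text.  OTU tables on disk may
be oriented either way (QIIME-style OTU x sample exports start the header
with an ``#OTU`` token; otherwise rows are taken to be samples); in memory
tables are always samples x OTUs.
"""

from __future__ import annotations

from dataclasses import dataclass
import networkx as nx
import numpy as np
import pandas as pd

KINGDOMS = ("bacteria", "fungi")
GROUPS = ("KC", "NT", "RS")
RANKS = ("kingdom", "phylum", "class", "order", "family", "genus")
UNCLASSIFIED = "unclassified"


class FormatError(ValueError):
    """Malformed input file (non-numeric/negative cell, bad header...)."""


class ValidationError(ValueError):
    """Structurally valid file violating a domain invariant."""


@dataclass
class OtuTable:
    """Non-negative integer count matrix, samples x OTUs, for one kingdom."""

    counts: pd.DataFrame          # index: sample ids, columns: OTU ids
    kingdom: str

    def __post_init__(self):
        if self.kingdom not in KINGDOMS:
            raise ValidationError(f"unknown kingdom {self.kingdom!r}")
        c = self.counts
        if c.index.duplicated().any():
            raise ValidationError("duplicate sample ids: "
                                  f"{sorted(c.index[c.index.duplicated()])}")
        if c.columns.duplicated().any():
            raise ValidationError("duplicate OTU ids: "
                                  f"{sorted(c.columns[c.columns.duplicated()])}")
        if (c.to_numpy() < 0).any():
            r, k = np.argwhere(c.to_numpy() < 0)[0]
            raise ValidationError(
                f"negative count at sample {c.index[r]!r}, OTU {c.columns[k]!r}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def otu_ids(self) -> list[str]:
        return list(self.counts.columns)

    def library_sizes(self) -> pd.Series:
        return self.counts.sum(axis=1)


@dataclass
class RelAbundanceTable:
    """Per-sample proportions with the same axes as an OtuTable."""

    values: pd.DataFrame
    kingdom: str | None = None

    def __post_init__(self):
        v = self.values.to_numpy()
        if ((v < -1e-12) | (v > 1 + 1e-12)).any():
            raise ValidationError("relative abundances must lie in [0, 1]")
        sums = v.sum(axis=1)
        if np.any(np.abs(sums - 1.0) > 1e-9):
            bad = self.values.index[np.abs(sums - 1.0) > 1e-9][0]
            raise ValidationError(f"row {bad!r} does not sum to 1")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.index)


@dataclass
class TaxonomyMap:
    """OTU id -> lineage; missing ranks are the literal 'unclassified'."""

    table: pd.DataFrame           # index: otu ids, columns: RANKS

    def __post_init__(self):
        for r in RANKS:
            if r not in self.table.columns:
                self.table[r] = UNCLASSIFIED
        self.table = self.table[list(RANKS)].fillna(UNCLASSIFIED).replace(
            "", UNCLASSIFIED)

    def lineage(self, otu_id: str) -> pd.Series:
        return self.table.loc[otu_id]

    def rank_of(self, otu_ids, rank: str) -> pd.Series:
        missing = [o for o in otu_ids if o not in self.table.index]
        if missing:
            raise ValidationError(f"OTUs missing from taxonomy: {missing[:10]}")
        return self.table.loc[list(otu_ids), rank]


#: numeric soil variables recognised in metadata files, with loose units
SOIL_VARIABLES = ("pH", "SWC", "EC", "Na", "K", "TC", "TOC", "TIC", "TN",
                  "TP", "AN", "OP", "MBC", "MBN", "MBP")
FUMIGATION_PAIRS = ("DOC_fum", "DOC_nonfum", "TN_fum", "TN_nonfum",
                    "TP_fum", "TP_nonfum")


@dataclass
class SampleMetadata:
    """Per-sample soil physicochemical / biomass variables + plant group."""

    table: pd.DataFrame           # index: sample ids; 'group' + numeric cols

    def __post_init__(self):
        t = self.table
        if "group" not in t.columns:
            raise ValidationError("metadata requires a 'group' column")
        bad = set(t["group"]) - set(GROUPS)
        if bad:
            raise ValidationError(f"unknown plant groups: {sorted(bad)}")
        if t.index.duplicated().any():
            raise ValidationError("duplicate sample ids in metadata")
        num = t.drop(columns=["group"]).select_dtypes("number")
        nonneg = [c for c in num.columns if c != "pH"]
        if (num[nonneg].to_numpy() < 0).any():
            raise ValidationError("negative concentration in metadata")

    @property
    def groups(self) -> pd.Series:
        return self.table["group"]

    def numeric(self, columns=None) -> pd.DataFrame:
        num = self.table.select_dtypes("number")
        if columns is not None:
            columns = [c for c in columns if c in num.columns]
            num = num[columns]
        return num


# ---------------------------------------------------------------------------
# readers / writers


def _read_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0, dtype={0: str})
    df.index.name = None
    return df


def read_otu_table(path, kingdom: str, orientation: str = "auto") -> OtuTable:
    """Read a tab-separated count table.

    orientation: 'auto' (header token '#OTU'/'OTU' in the id column means
    rows are OTUs), 'otus_as_rows', or 'samples_as_rows'.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    if orientation == "auto":
        token = str(df.index.name or "").lstrip("#").strip().lower()
        orientation = ("otus_as_rows" if token.startswith("otu")
                       else "samples_as_rows")
    if orientation == "otus_as_rows":
        df = df.T
    elif orientation != "samples_as_rows":
        raise ValueError(f"unknown orientation {orientation!r}")
    arr = df.to_numpy()
    if not np.issubdtype(arr.dtype, np.number):
        for j, col in enumerate(df.columns):
            coerced = pd.to_numeric(df[col], errors="coerce")
            if coerced.isna().any():
                row = df.index[coerced.isna().to_numpy().argmax()]
                raise FormatError(
                    f"non-numeric count at row {row!r}, column {col!r}")
        df = df.apply(pd.to_numeric)
        arr = df.to_numpy()
    if (arr < 0).any():
        i, j = np.argwhere(arr < 0)[0]
        raise FormatError(f"negative count at row {df.index[i]!r}, "
                          f"column {df.columns[j]!r}")
    df = df.astype(np.int64)
    df.index = pd.Index(df.index.astype(str))
    df.columns = pd.Index(df.columns.astype(str))
    df.index.name = df.columns.name = None
    return OtuTable(counts=df, kingdom=kingdom)


def write_otu_table(t: OtuTable, path) -> None:
    out = t.counts.copy()
    out.index.name = "sample_id"
    out.to_csv(path, sep="\t", lineterminator="\n")


def read_taxonomy(path) -> TaxonomyMap:
    df = _read_tsv(path)
    df.index = df.index.astype(str)
    return TaxonomyMap(table=df)


def write_taxonomy(tax: TaxonomyMap, path) -> None:
    out = tax.table.copy()
    out.index.name = "otu_id"
    out.to_csv(path, sep="\t", lineterminator="\n")


def read_metadata(path) -> SampleMetadata:
    df = _read_tsv(path)
    df.index = df.index.astype(str)
    return SampleMetadata(table=df)


def write_metadata(meta: SampleMetadata, path) -> None:
    out = meta.table.copy()
    out.index.name = "sample_id"
    out.to_csv(path, sep="\t", lineterminator="\n")


def align_samples(t: OtuTable, meta: SampleMetadata,
                  intersect: bool = False) -> tuple[OtuTable, SampleMetadata]:
    """Match OTU-table and metadata samples by exact id.

    A mismatch is an error unless intersect=True, in which case the common
    subset (in table order) is returned.
    """
    a, b = set(t.sample_ids), set(meta.table.index)
    if a != b and not intersect:
        raise ValidationError(
            f"sample mismatch: only-in-table {sorted(a - b)[:5]}, "
            f"only-in-metadata {sorted(b - a)[:5]} (pass intersect=True)")
    common = [s for s in t.sample_ids if s in b]
    if not common:
        raise ValidationError("no samples in common")
    return (OtuTable(t.counts.loc[common], t.kingdom),
            SampleMetadata(meta.table.loc[common]))


# ---------------------------------------------------------------------------
# transforms


def to_relative_abundance(t: OtuTable) -> RelAbundanceTable:
    sizes = t.library_sizes()
    empty = sizes.index[sizes == 0]
    if len(empty):
        raise ValidationError(f"all-zero sample(s): {list(empty)}")
    return RelAbundanceTable(values=t.counts.div(sizes, axis=0),
                             kingdom=t.kingdom)


def aggregate_by_rank(rel: RelAbundanceTable, tax: TaxonomyMap,
                      rank: str) -> RelAbundanceTable:
    """Sum relative abundances within each taxon at ``rank`` per sample.

    Unclassified OTUs pool into the 'unclassified' taxon; per-sample totals
    are conserved.
    """
    if rank not in RANKS:
        raise ValueError(f"rank must be one of {RANKS}")
    labels = tax.rank_of(rel.values.columns, rank)
    agg = rel.values.T.groupby(labels.to_numpy()).sum().T
    agg = agg[sorted(agg.columns)]
    return RelAbundanceTable(values=agg, kingdom=rel.kingdom)


# ---------------------------------------------------------------------------
# network export (Cytoscape-importable)

EDGE_COLUMNS = ("source", "target", "rho", "sign", "p")


def write_edge_list(net, path) -> None:
    """Tab-separated edge list: source, target, rho, sign, p."""
    rows = [{"source": u, "target": v, "rho": d["rho"],
             "sign": d["sign"], "p": d["p"]}
            for u, v, d in net.graph.edges(data=True)]
    df = pd.DataFrame(rows, columns=list(EDGE_COLUMNS))
    df.to_csv(path, sep="\t", index=False, lineterminator="\n")


def write_graphml(net, path) -> None:
    nx.write_graphml(net.graph, path)


def read_edge_list(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def read_graphml(path) -> nx.Graph:
    g = nx.read_graphml(path)
    return nx.relabel_nodes(g, {n: str(n) for n in g.nodes})
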