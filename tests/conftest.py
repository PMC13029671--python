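import networkx as nx
import numpy as np
import pandas as pd
import pytest

from rhizonet import io as rio
from rhizonet.network import CorrelationNetwork


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_otu_table():
    counts = pd.DataFrame(
        [[5, 0, 3, 2], [1, 7, 0, 4], [2, 2, 2, 2]],
        index=["S1", "S2", "S3"],
        columns=["B0001", "B0002", "B0003", "B0004"],
    )
    return rio.OtuTable(counts=counts, kingdom="bacteria")


@pytest.fixture
def small_taxonomy():
    table = pd.DataFrame(
        {
            "kingdom": ["bacteria"] * 4,
            "phylum": ["Proteobacteria", "Proteobacteria", "Firmicutes",
                       "unclassified"],
            "genus": ["GenA", "GenB", "GenC", "unclassified"],
        },
        index=["B0001", "B0002", "B0003", "B0004"],
    )
    return rio.TaxonomyMap(table=table)


def build_network(edges, kingdoms=None) -> CorrelationNetwork:
    """Toy correlation network from (u, v, rho) triples."""
    g = nx.Graph()
    for u, v, rho in edges:
        g.add_edge(u, v, rho=rho, sign=int(np.sign(rho)), p=0.001,
                   distance=1.0 - abs(rho))
    for node in g.nodes:
        g.nodes[node]["kingdom"] = (kingdoms or {}).get(node, "bacteria")
        g.nodes[node]["phylum"] = "unclassified"
    return CorrelationNetwork(graph=g)
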