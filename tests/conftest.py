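import numpy as np
import pandas as pd
import pytest

from fluvnet.network import SiteNode, StreamNetwork
from fluvnet.otu import OTUTable


@pytest.fixture
def y_network():
    """Two headwater tributaries joining at a sampled recipient."""
    sites = [
        SiteNode("A", -100.0, 100.0, 700.0, 1.2),
        SiteNode("B", 100.0, 100.0, 710.0, 4.8),
        SiteNode("R", 0.0, 0.0, 650.0, 6.5),
    ]
    edges = [("A", "R", 100.0), ("B", "R", 250.0)]
    return StreamNetwork(sites, edges)


@pytest.fixture
def chain_network():
    """Four sites on one flow path (all pairs flow-connected)."""
    sites = [SiteNode(f"C{i}", 0.0, float(i) * 100, 600.0, 5.0 - i) for i in range(4)]
    edges = [(f"C{i}", f"C{i-1}", 100.0) for i in range(1, 4)]
    return StreamNetwork(sites, edges)


def random_tree_network(n_leaves: int, rng: np.random.Generator) -> StreamNetwork:
    """Small random bifurcation tree used for brute-force oracle checks."""
    from fluvnet.simulate import SynthConfig, generate_network

    return generate_network(n_leaves, rng, SynthConfig(n_headwaters=n_leaves, add_outlet_site=False))


def random_otu_table(
    rng: np.random.Generator, n_samples: int = 6, n_otus: int = 20, depth: int = 200
) -> OTUTable:
    counts = rng.multinomial(depth, rng.dirichlet(np.ones(n_otus)), size=n_samples)
    keep = counts.sum(axis=0) > 0
    counts = counts[:, keep]
    df = pd.DataFrame(
        counts,
        index=[f"s{i}" for i in range(n_samples)],
        columns=[f"otu{j}" for j in range(counts.shape[1])],
    )
    return OTUTable(df)
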