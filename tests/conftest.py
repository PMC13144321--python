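import networkx as nx
import numpy as np
import pandas as pd
import pytest

from signet import synthetic as syn
from signet.types import OmicsView


@pytest.fixture(scope="session")
def small_world():
    """A 120-node planted interactome shared by read-only tests."""
    graph = syn.generate_network(120, 3, seed=11)
    truth = syn.plant_truth(graph, n_receptors=2, n_paths=2, path_length=4,
                            seed=11)
    ann = syn.generate_annotations(graph, truth, seed=11)
    return graph, truth, ann


@pytest.fixture(scope="session")
def omics(small_world):
    _, truth, _ = small_world
    syn.simulate_regulons(truth, targets_per_tf=8, seed=11)
    return syn.simulate_omics(truth, replicates=3, effect_size=2.0,
                              noise_sd=0.5, missing_rate=0.1, seed=11)


def make_view(matrix, label="protein", genotype=None, treatment=None):
    """Hand-built OmicsView from a samples x features frame."""
    n = matrix.shape[0]
    meta = pd.DataFrame({
        "genotype": genotype or ["WT"] * n,
        "treatment": treatment or ["untreated"] * n,
        "replicate": range(1, n + 1),
        "batch": ["b1"] * n,
    }, index=matrix.index)
    return OmicsView(label, matrix, meta)


@pytest.fixture
def random_weighted_graph():
    def build(n, p, seed, low=0.2, high=1.0):
        rng = np.random.default_rng(seed)
        g = nx.gnp_random_graph(n, p, seed=int(rng.integers(2**31)))
        for u, v in g.edges():
            g[u][v]["confidence"] = float(rng.uniform(low, high))
        return g
    return build
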