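import numpy as np
import pytest

from grnsb import FixtureSpec, GeneNetwork, RankedPrediction, Universe, generate_grn


def net(edges, directed=True, name="toy", nodes=(), tfs=()):
    """Shorthand network builder for tests."""
    return GeneNetwork.build(name, directed, edges, nodes=nodes, tf_list=tfs)


def pred(entries, method="m", network_type="CAUS", directed=True):
    return RankedPrediction(method, network_type, tuple(entries), directed)


@pytest.fixture
def toy_gs():
    """Small directed GS: 2 TFs, one autoregulator, shared target."""
    return net(
        [("t1", "a"), ("t1", "b"), ("t2", "b"), ("t2", "c"), ("t2", "t2")],
        tfs=["t1", "t2"],
    )


@pytest.fixture
def small_grn():
    return generate_grn(FixtureSpec(n_genes=120, n_tfs=12, n_edges=360, seed=11))


@pytest.fixture
def full_universe(toy_gs):
    return Universe(frozenset(toy_gs.regulators), frozenset(toy_gs.nodes))


def random_digraph(rng, n_max=30, p=0.15):
    """Random directed graph as (nodes, arcs) for oracle comparisons."""
    n = int(rng.integers(4, n_max + 1))
    nodes = [f"n{i:02d}" for i in range(n)]
    arcs = {
        (nodes[i], nodes[j])
        for i in range(n)
        for j in range(n)
        if i != j and rng.random() < p
    }
    return nodes, arcs


def rng_for(seed):
    return np.random.default_rng(seed)
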