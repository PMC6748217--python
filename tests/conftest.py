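import networkx as nx
import numpy as np
import pandas as pd
import pytest

from transcriptogram import (
    InteractionNetwork,
    TranscriptogramProfile,
    call_clusters,
    gen_expression,
    gen_network,
    moderated_t,
    order_genes,
    window_average,
)
from transcriptogram.synthetic import DEMO_PARAMS


def make_network(edges, score=900, nodes=()):
    g = nx.Graph()
    g.add_nodes_from(nodes)
    for e in edges:
        if len(e) == 3:
            u, v, s = e
        else:
            (u, v), s = e, score
        g.add_edge(u, v, score=s)
    return InteractionNetwork(g)


def make_profile(values, samples=None):
    """Position x sample profile straight from an array (radius 0)."""
    values = np.asarray(values, dtype=float)
    n_pos, n_samp = values.shape
    samples = samples or [f"s{i}" for i in range(n_samp)]
    df = pd.DataFrame(values, index=pd.RangeIndex(1, n_pos + 1), columns=samples)
    return TranscriptogramProfile(radius=0, values=df,
                                  gene_by_position=[f"g{i}" for i in range(n_pos)])


def make_metadata(case, control):
    idx = list(case) + list(control)
    return pd.DataFrame(
        {"condition": ["case"] * len(case) + ["control"] * len(control), "day": 0},
        index=pd.Index(idx, name="sample"),
    )


@pytest.fixture
def path3():
    return make_network([("a", "b"), ("b", "c")])


@pytest.fixture
def triangle():
    return make_network([("a", "b"), ("b", "c"), ("a", "c")])


@pytest.fixture
def k4():
    return make_network([(u, v) for u in "abcd" for v in "abcd" if u < v])


def run_demo(seed):
    """One full demo analysis with ground truth, shared across recovery tests."""
    p = DEMO_PARAMS
    net, truth = gen_network(n_modules=p["n_modules"], module_size=p["module_size"],
                             p_in=p["p_in"], p_out=p["p_out"], seed=seed,
                             noise_sd=p["noise_sd"])
    expr = gen_expression(truth, n_case=p["n_case"], n_control=p["n_control"],
                          seed=10000 + seed)
    order = order_genes(net, seed=seed)
    profile = window_average(expr, order, p["radius"])
    tests = moderated_t(profile, expr.metadata)
    clusters = call_clusters(tests, alpha=p["alpha"], order=order)
    return {"net": net, "truth": truth, "expr": expr, "order": order,
            "profile": profile, "tests": tests, "clusters": clusters,
            "seed": seed}


@pytest.fixture(scope="session")
def demo_batch():
    """Ten seeded end-to-end demo analyses (planted-module scenario)."""
    return [run_demo(seed) for seed in range(10)]
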