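"""Cluster subnetworks, connectivity statistics and cross-analysis matching.

"Connections" are counted as edges, once each: a cluster's inner edges have
both endpoints inside the cluster, its outer edges exactly one.  The average
connectivity <k> of a cluster is (inner + outer) / n_nodes, so an isolated
triangle has <k> = 1.0 and a hub with three outside neighbours has <k> = 3.0.

Matching relates the clusters of two analyses performed on the same ordering
(e.g. two time intervals): each later cluster inherits the label of the
earlier cluster with the largest positional overlap; clusters with no overlap,
or whose best match is already taken, receive fresh capital letters in
left-to-right order.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .dataio import InteractionNetwork
from .profiles import DECluster


@dataclass
class ClusterConnectivity:
    label: str
    n_nodes: int
    inner_edges: int
    outer_edges: int
    avg_k: float


@dataclass
class ClusterMatch:
    pairs: list          # (label in A, label in B, positional overlap length)
    relabel: dict        # original B label -> inherited/fresh label


def subnetwork(cluster: DECluster, net: InteractionNetwork) -> InteractionNetwork:
    """Induced subgraph of the interactome on the cluster's gene set."""
    return net.subgraph(cluster.genes & net.nodes)


def connectivity(cluster: DECluster, net: InteractionNetwork) -> ClusterConnectivity:
    genes = set(cluster.genes)
    if not genes:
        raise ValueError(f"cluster {cluster.label}: empty gene set")
    outside = genes - net.nodes
    if outside:
        raise ValueError(
            f"cluster {cluster.label}: gene(s) not in network: {sorted(outside)[:5]}")
    inner = 0
    outer = 0
    for u, v in net.graph.edges:
        inside = (u in genes) + (v in genes)
        if inside == 2:
            inner += 1
        elif inside == 1:
            outer += 1
    n = len(genes)
    return ClusterConnectivity(label=cluster.label, n_nodes=n, inner_edges=inner,
                               outer_edges=outer, avg_k=(inner + outer) / n)


def interactome_coverage(clusters, net: InteractionNetwork) -> float:
    """Fraction of interactome genes belonging to at least one cluster."""
    if net.n_nodes == 0:
        return 0.0
    covered = set()
    for c in clusters:
        covered |= set(c.genes)
    return len(covered & net.nodes) / net.n_nodes


def _fresh_labels():
    """A, B, ..., Z, AA, AB, ..."""
    import itertools
    import string
    for size in itertools.count(1):
        for combo in itertools.product(string.ascii_uppercase, repeat=size):
            yield "".join(combo)


def match_clusters(a, b, checksum_a: str = None, checksum_b: str = None) -> ClusterMatch:
    """Match analysis-B clusters to analysis-A clusters by positional overlap.

    Both cluster lists must come from the same ordering; pass the ordering
    checksums to have this verified.  Invariant to the order of the input
    lists (clusters are processed left to right by interval).
    """
    if checksum_a is not None and checksum_b is not None and checksum_a != checksum_b:
        raise ValueError("cluster sets come from different orderings")
    a_sorted = sorted(a, key=lambda c: (c.start, c.end, c.label))
    b_sorted = sorted(b, key=lambda c: (c.start, c.end, c.label))

    pairs = []
    relabel = {}
    taken = set()
    fresh = _fresh_labels()
    for cb in b_sorted:
        best_label = None
        best_overlap = 0
        for ca in a_sorted:
            overlap = min(ca.end, cb.end) - max(ca.start, cb.start) + 1
            if overlap > best_overlap:  # ties resolved toward the leftmost A
                best_overlap = overlap
                best_label = ca.label
        if best_label is not None and best_label not in taken:
            relabel[cb.label] = best_label
            taken.add(best_label)
            pairs.append((best_label, cb.label, best_overlap))
        else:
            relabel[cb.label] = next(fresh)
    return ClusterMatch(pairs=pairs, relabel=relabel)


# ---------------------------------------------------------------------------
# Tabular output
# ---------------------------------------------------------------------------


def connectivity_table(stats) -> pd.DataFrame:
    return pd.DataFrame(
        [(s.label, s.n_nodes, s.inner_edges, s.outer_edges, s.avg_k) for s in stats],
        columns=["label", "n_nodes", "inner_edges", "outer_edges", "avg_k"],
    )


def write_cluster_edges(cluster: DECluster, net: InteractionNetwork, path) -> None:
    sub = subnetwork(cluster, net)
    rows = sorted((min(u, v), max(u, v), d["score"])
                  for u, v, d in sub.graph.edges(data=True))
    with open(path, "w") as fh:
        fh.write("gene1\tgene2\tscore\n")
        for u, v, s in rows:
            fh.write(f"{u}\t{v}\t{s}\n")


def match_table(match: ClusterMatch) -> pd.DataFrame:
    overlap_by_b = {b: o for _, b, o in match.pairs}
    rows = [(b_label, new, overlap_by_b.get(b_label, 0))
            for b_label, new in sorted(match.relabel.items())]
    return pd.DataFrame(rows, columns=["cluster_b", "label", "overlap_positions"])
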