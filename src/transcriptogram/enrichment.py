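"""GO-term over-representation per cluster and Jaccard term dendrograms.

Each cluster's gene set is tested against every annotated term with the
upper-tail hypergeometric law on a universe of annotated, ordered genes;
p-values are BH-adjusted across the tested terms.  Enriched terms are then
related all-against-all by the Jaccard index of their (universe-restricted)
gene sets and agglomerated with average linkage on distance 1 - J; cutting
the dendrogram at height 1 - cutoff (the study convention is a 0.25 Jaccard
cutoff) yields the term groups.  Annotations are taken as given -- the table
is expected to be pre-propagated if ontology ancestry should count.

Per-term occupation rate: overlap with the cluster divided by term size,
normalised by the maximum such ratio in the cluster (so the best-covered
term scores 1.0).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .dataio import AnnotationTable


@dataclass
class EnrichedTerm:
    term: str
    name: str
    term_size: int          # annotated genes in the universe
    overlap: int            # cluster genes carrying the term
    p: float
    padj: float
    occupation: float       # overlap / term_size
    occupation_norm: float  # occupation / max occupation in the cluster


@dataclass
class TermTree:
    """Average-linkage merge tree over enriched terms (heights = 1 - Jaccard)."""

    terms: list                  # leaf term ids, in linkage input order
    linkage: np.ndarray          # scipy linkage matrix (empty for one leaf)
    cutoff: float                # Jaccard cutoff; groups read at height 1 - cutoff
    groups: dict                 # term -> group id at the cutoff
    attributes: pd.DataFrame     # term, term_size, occupation, occupation_norm

    @property
    def n_groups(self) -> int:
        return len(set(self.groups.values()))


# ---------------------------------------------------------------------------
# Over-representation
# ---------------------------------------------------------------------------


def ora(cluster_genes, ann: AnnotationTable, universe, alpha: float = 0.05):
    """Hypergeometric over-representation of annotation terms in a cluster.

    The universe is the annotated portion of the ordering; ``p`` is the
    probability of drawing at least the observed overlap when sampling
    ``len(cluster_genes)`` genes from it without replacement.  Terms with
    BH-adjusted p <= ``alpha`` are returned sorted by adjusted p (ties by
    term id).
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty annotation universe")
    cluster_genes = set(cluster_genes)
    stray = cluster_genes - universe
    if stray:
        raise ValueError(f"cluster gene(s) outside universe: {sorted(stray)[:5]}")
    term_sets = {t: gs for t, gs in ann.term_genes(universe=universe).items() if gs}
    if not term_sets:
        return []
    names = ann.term_names()
    m = len(universe)
    k = len(cluster_genes)
    terms = sorted(term_sets)
    pvals = np.empty(len(terms))
    overlaps = []
    for i, t in enumerate(terms):
        gs = term_sets[t]
        ov = len(gs & cluster_genes)
        overlaps.append(ov)
        # upper tail P(X >= ov); ov = 0 gives 1
        pvals[i] = stats.hypergeom.sf(ov - 1, m, len(gs), k)
    from .profiles import adjust_bh
    padj = adjust_bh(np.clip(pvals, 0.0, 1.0))

    kept = []
    for i, t in enumerate(terms):
        if padj[i] <= alpha:
            size = len(term_sets[t])
            kept.append(EnrichedTerm(term=t, name=names.get(t, ""), term_size=size,
                                     overlap=overlaps[i], p=float(pvals[i]),
                                     padj=float(padj[i]),
                                     occupation=overlaps[i] / size,
                                     occupation_norm=np.nan))
    if kept:
        max_occ = max(e.occupation for e in kept)
        for e in kept:
            e.occupation_norm = e.occupation / max_occ if max_occ > 0 else 0.0
    kept.sort(key=lambda e: (e.padj, e.term))
    return kept


# ---------------------------------------------------------------------------
# Term similarity
# ---------------------------------------------------------------------------


def jaccard_matrix(terms, ann: AnnotationTable, universe=None) -> pd.DataFrame:
    """All-against-all Jaccard index of the enriched terms' gene sets."""
    if len(terms) < 2:
        raise ValueError("need >= 2 terms for a similarity matrix")
    ids = [e.term if isinstance(e, EnrichedTerm) else e for e in terms]
    sets = ann.term_genes(universe=universe)
    gene_sets = []
    for t in ids:
        gs = sets.get(t, frozenset())
        if not gs:
            raise ValueError(f"term {t!r} has an empty gene set")
        gene_sets.append(gs)
    n = len(ids)
    J = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            a, b = gene_sets[i], gene_sets[j]
            J[i, j] = J[j, i] = len(a & b) / len(a | b)
    return pd.DataFrame(J, index=ids, columns=ids)


def term_dendrogram(J: pd.DataFrame, cutoff: float = 0.25,
                    enriched=None) -> TermTree:
    """Average-linkage dendrogram on distance 1 - J, grouped at 1 - cutoff."""
    if isinstance(J, pd.DataFrame):
        ids = [str(t) for t in J.index]
        mat = J.to_numpy(dtype=float)
    else:
        mat = np.asarray(J, dtype=float)
        ids = [str(i) for i in range(mat.shape[0])]
    if mat.shape[0] != mat.shape[1] or not np.allclose(mat, mat.T):
        raise ValueError("Jaccard matrix must be symmetric")
    if not np.allclose(np.diag(mat), 1.0):
        raise ValueError("Jaccard matrix must have unit diagonal")

    attr = _attribute_frame(ids, enriched)
    if len(ids) < 2:
        return TermTree(terms=ids, linkage=np.empty((0, 4)), cutoff=cutoff,
                        groups={t: 1 for t in ids}, attributes=attr)
    # sort leaves by term id so linkage tie-breaks are reproducible
    order = sorted(range(len(ids)), key=lambda i: ids[i])
    ids = [ids[i] for i in order]
    mat = mat[np.ix_(order, order)]
    attr = _attribute_frame(ids, enriched)

    dist = 1.0 - mat
    np.fill_diagonal(dist, 0.0)
    z = hierarchy.linkage(squareform(dist, checks=False), method="average")
    z[:, 2] = np.clip(z[:, 2], 0.0, None)
    labels = hierarchy.fcluster(z, t=1.0 - cutoff, criterion="distance")
    groups = {t: int(g) for t, g in zip(ids, labels)}
    return TermTree(terms=ids, linkage=z, cutoff=cutoff, groups=groups,
                    attributes=attr)


def _attribute_frame(ids, enriched) -> pd.DataFrame:
    by_id = {e.term: e for e in enriched} if enriched else {}
    rows = []
    for t in ids:
        e = by_id.get(t)
        rows.append((t,
                     e.term_size if e else np.nan,
                     e.occupation if e else np.nan,
                     e.occupation_norm if e else np.nan))
    return pd.DataFrame(rows, columns=["term", "term_size", "occupation",
                                       "occupation_norm"])


# ---------------------------------------------------------------------------
# Output
# ---------------------------------------------------------------------------


def enrichment_table(enriched) -> pd.DataFrame:
    return pd.DataFrame(
        [(e.term, e.name, e.term_size, e.overlap, e.p, e.padj, e.occupation,
          e.occupation_norm) for e in enriched],
        columns=["term", "name", "term_size", "overlap", "p", "padj",
                 "occupation", "occupation_norm"],
    )


def to_newick(tree: TermTree) -> str:
    """Newick string with branch lengths derived from merge heights."""
    if len(tree.terms) == 1:
        return f"{tree.terms[0]}:0;"
    root = hierarchy.to_tree(tree.linkage)

    def render(node, parent_height):
        if node.is_leaf():
            name = tree.terms[node.id]
            return f"{name}:{parent_height - 0.0:.6g}"
        left = render(node.left, node.dist)
        right = render(node.right, node.dist)
        return f"({left},{right}):{parent_height - node.dist:.6g}"

    body = render(root, root.dist)
    # strip the root's zero-length branch
    idx = body.rfind(":")
    return body[:idx] + ";"
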