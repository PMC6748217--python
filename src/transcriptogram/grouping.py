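"""Sample grouping by PCA + hierarchical clustering, and marker-gene tests.

Samples (observations) are projected on the principal components of the
gene-centered expression matrix; the smallest number of components reaching
the cumulative-variance target (default 95%) is retained.  Ward-linkage
hierarchical clustering on the retained scores then partitions the samples,
with the number of groups chosen automatically as the cut where the relative
loss of within-group inertia between consecutive cuts is largest -- the
criterion used for automatic cluster detection after a PCA.  No k-means
consolidation is applied after the tree cut, keeping the procedure fully
deterministic.

Marker progression across groups is assessed by pairwise t-tests with the
variance pooled across all groups (the classical pairwise.t.test default),
BH-FDR corrected within each marker across its group pairs, significant at
adjusted p <= 0.01.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from sklearn.decomposition import PCA

from .dataio import ExpressionMatrix
from .profiles import adjust_bh

logger = logging.getLogger("transcriptogram")

# Default marker panels for neural-progenitor differentiation experiments.
NPC_MARKERS = ("MSI1", "NES", "NOTCH1", "SOX1")
NEURONAL_MARKERS = ("TH", "NEUROD6", "DCX", "RBFOX3", "GAD1", "GAD2")


@dataclass
class SampleGroups:
    scores: pd.DataFrame          # sample x retained component
    cumvar: np.ndarray            # cumulative explained-variance fractions
    k_components: int
    assignment: dict = field(default_factory=dict)  # sample -> group id
    k_groups: int = 0


@dataclass
class MarkerTestResult:
    gene: str
    group_a: str
    group_b: str
    t: float
    p: float
    padj: float
    significant: bool


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------


def pca_samples(expr: ExpressionMatrix, variance_target: float = 0.95) -> SampleGroups:
    """Project samples on gene-centered principal components.

    Retains the smallest k whose cumulative explained variance reaches the
    target.  Genes are centered, not scaled.
    """
    if not 0 < variance_target <= 1:
        raise ValueError("variance_target must lie in (0, 1]")
    x = expr.values.to_numpy(dtype=float).T  # samples x genes
    if x.shape[0] < 2:
        raise ValueError("need >= 2 samples for PCA")
    if np.allclose(x.var(axis=0).sum(), 0.0):
        raise ValueError("expression matrix has no variance across samples")
    pca = PCA(n_components=None, svd_solver="full")
    scores = pca.fit_transform(x)
    cumvar = np.cumsum(pca.explained_variance_ratio_)
    cumvar = np.minimum(cumvar, 1.0)
    k = int(np.searchsorted(cumvar, variance_target - 1e-12) + 1)
    k = min(k, scores.shape[1])
    frame = pd.DataFrame(scores[:, :k], index=expr.values.columns,
                         columns=[f"PC{i + 1}" for i in range(k)])
    return SampleGroups(scores=frame, cumvar=cumvar, k_components=k)


# ---------------------------------------------------------------------------
# Automatic hierarchical clustering
# ---------------------------------------------------------------------------


def _within_inertia(x: np.ndarray, labels: np.ndarray) -> float:
    total = 0.0
    for g in np.unique(labels):
        block = x[labels == g]
        total += ((block - block.mean(axis=0)) ** 2).sum()
    return float(total)


def cluster_samples(groups: SampleGroups, k_max: int = 10) -> SampleGroups:
    """Ward clustering on the retained scores with automatic choice of k.

    k in [2, k_max] maximising the relative within-inertia loss
    (W(k-1) - W(k)) / (W(k) - W(k+1)) between consecutive cuts.
    """
    if k_max < 2:
        raise ValueError("k_max must be >= 2")
    x = groups.scores.to_numpy(dtype=float)
    n = x.shape[0]
    if n < 3:
        raise ValueError("need >= 3 samples to cluster")
    total = ((x - x.mean(axis=0)) ** 2).sum()
    samples = list(groups.scores.index)
    if np.isclose(total, 0.0):
        logger.warning("all samples identical: returning a single group")
        groups.assignment = {s: 1 for s in samples}
        groups.k_groups = 1
        return groups

    z = hierarchy.linkage(x, method="ward")
    k_hi = min(k_max, n - 1)
    w = {1: float(total)}
    for k in range(2, k_hi + 2):
        labels = hierarchy.fcluster(z, t=k, criterion="maxclust")
        w[k] = _within_inertia(x, labels)

    best_k, best_q = 2, -np.inf
    for k in range(2, k_hi + 1):
        num = w[k - 1] - w[k]
        den = w[k] - w[k + 1]
        q = np.inf if den <= 1e-12 else num / den
        if q > best_q + 1e-12:  # ties keep the smaller k
            best_k, best_q = k, q
    labels = hierarchy.fcluster(z, t=best_k, criterion="maxclust")
    # renumber groups 1..k in order of first appearance for determinism
    remap: dict = {}
    assignment = {}
    for s, lab in zip(samples, labels):
        if lab not in remap:
            remap[lab] = len(remap) + 1
        assignment[s] = remap[lab]
    groups.assignment = assignment
    groups.k_groups = best_k
    return groups


# ---------------------------------------------------------------------------
# Marker tests
# ---------------------------------------------------------------------------


def _normalize_assignment(assignment, allow_shared: bool):
    """Accept sample->group or group->samples; return group -> sample list."""
    first_val = next(iter(assignment.values()))
    if isinstance(first_val, (list, tuple, set, frozenset)):
        by_group = {str(g): sorted(map(str, ss)) for g, ss in assignment.items()}
        if not allow_shared:
            seen: dict = {}
            for g, ss in by_group.items():
                for s in ss:
                    if s in seen:
                        raise ValueError(
                            f"sample {s!r} listed in groups {seen[s]!r} and {g!r}; "
                            "pass allow_shared=True to permit this")
                    seen[s] = g
        return by_group
    by_group = {}
    for s, g in assignment.items():
        by_group.setdefault(str(g), []).append(str(s))
    return {g: sorted(ss) for g, ss in by_group.items()}


def marker_tests(expr: ExpressionMatrix, assignment, markers,
                 alpha: float = 0.01, allow_shared: bool = False):
    """All pairwise group comparisons per marker gene.

    Uses a variance pooled across *all* groups (df = N - k); BH correction is
    applied within each marker across its group pairs.
    """
    by_group = _normalize_assignment(assignment, allow_shared)
    if len(by_group) < 2:
        raise ValueError("need >= 2 groups for pairwise tests")
    missing = [m for m in markers if m not in expr.values.index]
    if missing:
        raise ValueError(f"marker(s) absent from expression matrix: {missing}")

    group_ids = sorted(by_group)
    results = []
    for gene in markers:
        row = expr.values.loc[gene]
        means, counts, rss = {}, {}, 0.0
        n_total = 0
        for g in group_ids:
            vals = row[by_group[g]].to_numpy(dtype=float)
            means[g] = vals.mean()
            counts[g] = len(vals)
            rss += ((vals - vals.mean()) ** 2).sum()
            n_total += len(vals)
        df = n_total - len(group_ids)
        if df <= 0:
            raise ValueError("not enough samples to pool a variance")
        pooled_var = rss / df
        pairs = list(itertools.combinations(group_ids, 2))
        tvals, pvals = [], []
        for ga, gb in pairs:
            se = np.sqrt(pooled_var * (1 / counts[ga] + 1 / counts[gb]))
            t = (means[ga] - means[gb]) / se if se > 0 else 0.0
            p = 2 * stats.t.sf(abs(t), df) if se > 0 else 1.0
            tvals.append(t)
            pvals.append(p)
        padj = adjust_bh(pvals)
        for (ga, gb), t, p, q in zip(pairs, tvals, pvals, padj):
            results.append(MarkerTestResult(gene=gene, group_a=ga, group_b=gb,
                                            t=float(t), p=float(p), padj=float(q),
                                            significant=bool(q <= alpha)))
    return results


def marker_table(results) -> pd.DataFrame:
    return pd.DataFrame(
        [(r.gene, r.group_a, r.group_b, r.t, r.p, r.padj, r.significant)
         for r in results],
        columns=["gene", "group_a", "group_b", "t", "p", "padj", "significant"],
    )


def scree_table(groups: SampleGroups) -> pd.DataFrame:
    frac = np.diff(np.concatenate([[0.0], groups.cumvar]))
    return pd.DataFrame({
        "component": np.arange(1, len(groups.cumvar) + 1),
        "variance_fraction": frac,
        "cumulative": groups.cumvar,
    })
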