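"""Sliding-window expression projection and position-level differential testing.

Expression is projected along the gene ordering: the profile value at position
``i`` for sample ``s`` is the arithmetic mean of the expression of the genes
whose positions fall in the truncated window ``[max(1, i-r), min(N, i+r)]``
(the ordering is a line, not a circle; a wrap-around mode exists behind a
flag).  Each position is then tested case vs control with an empirical-Bayes
moderated t-statistic: per-position residual variances are shrunk toward a
common prior fitted by moment matching on the scaled-F distribution of the
observed variances, exactly the squeeze applied by the limma family of
methods.  Positions significant after Benjamini-Hochberg adjustment are
grouped into maximal contiguous, direction-consistent runs: the
differentially expressed clusters.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import digamma, polygamma

from .dataio import ExpressionMatrix
from .ordering import GeneOrdering

logger = logging.getLogger("transcriptogram")


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class TranscriptogramProfile:
    """Position x sample matrix of windowed mean expression at a given radius."""

    radius: int
    values: pd.DataFrame          # index: positions 1..N; columns: samples
    gene_by_position: list        # gene occupying each position, left to right

    @property
    def positions(self) -> np.ndarray:
        return self.values.index.to_numpy()


@dataclass
class PositionTest:
    position: int
    t: float
    p: float
    padj: float
    direction: str                # 'up' | 'down' | 'zero', sign of case - control
    lfc: float = 0.0              # mean(case) - mean(control), log scale


@dataclass
class DECluster:
    """A maximal run of significant positions with a consistent direction."""

    label: str
    start: int
    end: int
    direction: str
    genes: frozenset
    min_padj: float

    @property
    def interval(self):
        return (self.start, self.end)

    @property
    def n_positions(self) -> int:
        return self.end - self.start + 1


# ---------------------------------------------------------------------------
# Window projection
# ---------------------------------------------------------------------------


def window_average(expr: ExpressionMatrix, order: GeneOrdering, radius: int,
                   wrap: bool = False) -> TranscriptogramProfile:
    """Mean expression over the sliding window at every ordering position.

    With radius 0 the profile equals the reordered expression matrix; with a
    window covering the whole list every position equals the per-sample
    global mean.
    """
    if radius < 0:
        raise ValueError("radius must be >= 0")
    genes = order.genes_in_order
    missing = [g for g in genes if g not in expr.values.index]
    if missing:
        raise ValueError(f"ordering gene(s) absent from expression: {missing[:5]}")
    n = len(genes)
    if radius >= n:
        logger.warning("window radius %d >= %d genes: every window is the whole "
                       "list", radius, n)
    mat = expr.values.loc[genes].to_numpy(dtype=float)  # positions x samples
    if wrap:
        from scipy.ndimage import uniform_filter1d
        out = uniform_filter1d(mat, size=min(2 * radius + 1, n), axis=0,
                               mode="wrap")
    else:
        # per-position slice means: exact (no cumulative-sum rounding drift)
        out = np.empty_like(mat)
        for i in range(n):
            lo = max(0, i - radius)
            hi = min(n - 1, i + radius)
            out[i] = mat[lo:hi + 1].mean(axis=0)
    values = pd.DataFrame(out, index=pd.RangeIndex(1, n + 1, name="position"),
                          columns=expr.values.columns)
    return TranscriptogramProfile(radius=radius, values=values,
                                  gene_by_position=genes)


def relative_profile(profile: TranscriptogramProfile,
                     metadata: pd.DataFrame) -> pd.Series:
    """Per-position mean(case) - mean(control), on the log scale."""
    case, ctrl = _condition_columns(profile, metadata)
    rel = profile.values[case].mean(axis=1) - profile.values[ctrl].mean(axis=1)
    rel.name = "relative_expression"
    return rel


def _condition_columns(profile, metadata):
    cols = list(profile.values.columns)
    cond = metadata.loc[cols, "condition"]
    case = [s for s in cols if cond[s] == "case"]
    ctrl = [s for s in cols if cond[s] == "control"]
    if not case or not ctrl:
        raise ValueError("both case and control samples are required")
    return case, ctrl


# ---------------------------------------------------------------------------
# Moderated t  (empirical-Bayes variance shrinkage)
# ---------------------------------------------------------------------------


def trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y by Newton iteration."""
    if y <= 0:
        return math.inf
    if y > 1e7:
        return 1.0 / math.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = polygamma(1, x)
        dif = tri * (1.0 - tri / y) / polygamma(2, x)
        x += dif
        if -dif / x < 1e-8:
            break
    return float(x)


def fit_f_dist(s2: np.ndarray, df: float):
    """Fit a scaled-F prior (d0, s0^2) to observed variances by moment
    matching on the log scale."""
    s2 = np.maximum(np.asarray(s2, dtype=float), 0.0)
    if np.all(s2 <= 0):
        raise ValueError("all residual variances are zero: degenerate input")
    m = float(np.median(s2))
    if m == 0.0:
        logger.warning("more than half of the residual variances are zero; "
                       "variance prior is unreliable")
        m = 1.0
    s2 = np.maximum(s2, 1e-5 * m)  # offset exact zeros, as the limma fit does
    z = np.log(s2)
    e = z - digamma(df / 2.0) + math.log(df / 2.0)
    emean = float(np.mean(e))
    if e.size < 2:
        return math.inf, float(np.exp(emean))
    evar = float(np.var(e, ddof=1)) - float(polygamma(1, df / 2.0))
    if evar > 0:
        d0 = 2.0 * trigamma_inverse(evar)
        s20 = float(np.exp(emean + digamma(d0 / 2.0) - math.log(d0 / 2.0)))
    else:
        d0 = math.inf
        s20 = float(np.mean(s2))
    return d0, s20


def moderated_t(profile: TranscriptogramProfile, metadata: pd.DataFrame,
                d0: float = None, s20: float = None):
    """Two-group moderated t-test at every window position.

    Residual variances are squeezed toward the fitted prior: the posterior
    variance is ``(d0*s20 + d*s2) / (d0 + d)`` on ``d0 + d`` degrees of
    freedom.  ``d0 = 0`` reduces to the ordinary pooled-variance t;
    ``d0 = inf`` gives every position the shared prior variance.  Pass
    explicit ``d0``/``s20`` to override the fit.  Returns a list of
    :class:`PositionTest` with BH-adjusted p-values filled in.
    """
    case, ctrl = _condition_columns(profile, metadata)
    n1, n2 = len(case), len(ctrl)
    if n1 < 2 or n2 < 2:
        raise ValueError("need >= 2 samples per condition for the moderated t")
    x1 = profile.values[case].to_numpy(dtype=float)
    x2 = profile.values[ctrl].to_numpy(dtype=float)
    m1 = x1.mean(axis=1)
    m2 = x2.mean(axis=1)
    d = n1 + n2 - 2
    rss = ((x1 - m1[:, None]) ** 2).sum(axis=1) + ((x2 - m2[:, None]) ** 2).sum(axis=1)
    s2 = rss / d

    if d0 is None or s20 is None:
        fit_d0, fit_s20 = fit_f_dist(s2, d)
        d0 = fit_d0 if d0 is None else d0
        s20 = fit_s20 if s20 is None else s20

    if math.isinf(d0):
        s2_post = np.full_like(s2, s20)
        df_total = math.inf
    else:
        s2_post = (d0 * s20 + d * s2) / (d0 + d)
        df_total = d0 + d
    if np.all(s2_post <= 0):
        raise ValueError("zero residual variance at every position")

    se = np.sqrt(s2_post * (1.0 / n1 + 1.0 / n2))
    diff = m1 - m2
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, diff / se, 0.0)
    p = 2.0 * stats.t.sf(np.abs(t), df_total)
    padj = adjust_bh(p)

    tests = []
    for i, pos in enumerate(profile.positions):
        direction = "up" if diff[i] > 0 else ("down" if diff[i] < 0 else "zero")
        tests.append(PositionTest(position=int(pos), t=float(t[i]), p=float(p[i]),
                                  padj=float(padj[i]), direction=direction,
                                  lfc=float(diff[i])))
    return tests


# ---------------------------------------------------------------------------
# Benjamini-Hochberg
# ---------------------------------------------------------------------------


def adjust_bh(p) -> np.ndarray:
    """BH step-up adjusted p-values, order-preserving with the input."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    n = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * n / np.arange(1, n + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    out = np.empty(n)
    out[order] = adj
    return out


# ---------------------------------------------------------------------------
# Cluster calling
# ---------------------------------------------------------------------------


def call_clusters(tests, alpha: float = 0.001, gap: int = 0,
                  order: GeneOrdering = None):
    """Maximal runs of significant, direction-consistent positions.

    Runs of the same direction separated by at most ``gap`` non-significant
    positions (with no opposing significant position in between) are merged.
    Labels are assigned left to right: "1", "2", ...  Member genes are the
    genes whose ordering position falls inside the interval (the window
    half-width is not added back).
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    if gap < 0:
        raise ValueError("gap must be >= 0")
    sig = [t for t in sorted(tests, key=lambda t: t.position)
           if t.padj <= alpha and t.direction != "zero"]
    runs = []  # (start, end, direction, min_padj)
    for t in sig:
        if runs and t.position == runs[-1][1] + 1 and t.direction == runs[-1][2]:
            runs[-1][1] = t.position
            runs[-1][3] = min(runs[-1][3], t.padj)
        else:
            runs.append([t.position, t.position, t.direction, t.padj])
    # merge same-direction neighbours across small non-significant gaps
    merged = []
    for run in runs:
        if (merged and run[2] == merged[-1][2]
                and run[0] - merged[-1][1] - 1 <= gap):
            merged[-1][1] = run[1]
            merged[-1][3] = min(merged[-1][3], run[3])
        else:
            merged.append(run)

    pos_to_gene = {}
    if order is not None:
        pos_to_gene = {pos: g for g, pos in order.position.items()}
    clusters = []
    for i, (start, end, direction, min_padj) in enumerate(merged, 1):
        genes = frozenset(pos_to_gene[p] for p in range(start, end + 1)
                          if p in pos_to_gene)
        clusters.append(DECluster(label=str(i), start=start, end=end,
                                  direction=direction, genes=genes,
                                  min_padj=min_padj))
    return clusters


# ---------------------------------------------------------------------------
# Plotting (plain summary figure)
# ---------------------------------------------------------------------------


def plot_transcriptogram(profile: TranscriptogramProfile, metadata: pd.DataFrame,
                         clusters=None, path=None):
    """Control mean and case-relative-to-control curves along the ordering."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    case, ctrl = _condition_columns(profile, metadata)
    pos = profile.positions
    ctrl_mean = profile.values[ctrl].mean(axis=1)
    rel = relative_profile(profile, metadata)
    fig, ax = plt.subplots(figsize=(10, 4))
    ax.plot(pos, ctrl_mean, color="black", lw=1, label="control mean")
    ax.plot(pos, ctrl_mean + rel, color="gray", lw=1, label="case (relative)")
    for c in clusters or []:
        color = "firebrick" if c.direction == "up" else "steelblue"
        ax.axvspan(c.start, c.end, alpha=0.25, color=color)
    ax.set_xlabel("ordering position")
    ax.set_ylabel("windowed mean log-CPM")
    ax.legend(frameon=False)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
        return None
    return fig
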