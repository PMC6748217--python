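# Methods

This note records the model assumptions, parameter choices, numerical
details and known limitations of the package. It documents what the code
does and why; every number quoted here is computed by the test suite or the
acceptance script, not asserted from memory.

## Seriation

The ordering objective is the unit-weight minimum linear arrangement:
cost(π) = Σ over edges |π(u) − π(v)|. The transcriptogram literature states
the *goal* of its ordering — interacting genes at nearby positions — without
publishing a closed objective, so the package defines its own: the linear
arrangement cost is well defined, brute-force checkable on small graphs, and
drives exactly the qualitative behaviour the projection needs. The cost
interface is pluggable (`ordering.COST_FUNCTIONS`); a windowed-neighbourhood
cost (count of edges longer than a radius) ships as an alternative for
evaluation.

The optimiser is simulated annealing over pairwise position swaps:

- **start**: Fiedler-vector (spectral) order per connected component; a
  seeded random start is available. Components are laid out largest-first in
  contiguous blocks and annealed independently (no edge crosses blocks).
- **budget**: 200·n·ln n swap proposals per component; overridable.
- **temperature**: initial T chosen so that about half of the uphill moves
  in a 100-swap probe would be accepted (T₀ = median uphill Δ / ln 2);
  geometric cooling by 0.995 every n swaps.
- **result**: the best-cost permutation visited, never worse than the start.
- **determinism**: all tie-breaks are lexicographic on gene identifier and
  all randomness flows from one seed.

Swap deltas are evaluated incrementally over the two genes' incident edges,
so a 300-gene planted-module network orders in about a second on one CPU.
The annealer attains the enumerated optimum on the exhaustive battery of
small connected graphs (the acceptance suite measures the rate; the
criterion is ≥ 90% over 5 seeds per graph).

## Window projection

The profile value at position i for sample s is the arithmetic mean of
expression over positions [max(1, i−r), min(N, i+r)]. Windows truncate at
the ends of the list: the ordering is a line, not a circle, and truncation
preserves the exact radius-0 identity (profile = reordered matrix). A
wrap-around mode exists behind a flag for users who prefer the circular
convention. Window means are computed as per-position slice means rather
than by cumulative sums, trading a little speed for exact agreement with the
direct definition (no floating-point drift along the list).

## Position-level testing

Each position is tested case vs control with the empirical-Bayes moderated
t-statistic. Residual variances s² with d = n₁ + n₂ − 2 df are assumed
exchangeable draws from a scaled inverse-chi-square prior (d₀, s₀²); the
prior is fitted by moment matching of log s² against the log scaled-F
distribution (digamma/trigamma moments, with the trigamma inverse solved by
Newton iteration), zero variances offset to 1e-5 times the median, and the
infinite-d₀ branch falling back to the arithmetic mean of the variances.
This is the same squeeze the limma family applies, and the test suite
verifies agreement with Bioconductor limma's `lmFit`/`eBayes` to 1e-10 on a
shared fixture, plus the two analytic limits (d₀ → 0 gives the ordinary
pooled t; d₀ → ∞ gives one shared variance).

The source methodology is described in places as limma-based and in places
as a Fisher test; those cannot both hold for a two-group comparison, and the
moderated-t route is what the named implementation computes, so this package
implements only the moderated t and notes the ambiguity here rather than
guessing at a Fisher combination.

P-values are adjusted by Benjamini–Hochberg step-up (implemented in-package,
cross-checked against statsmodels and an exhaustive oracle). The 0.001
calling threshold applies to the *adjusted* values, reading the source
convention "BH adjustment (p ≤ 0.001)" as a threshold on what BH produces.

## Cluster calling

Clusters are maximal runs of positions with adjusted p ≤ α and a constant
sign of (mean case − mean control). Runs of the same direction separated by
at most `gap` non-significant positions merge (default gap 0); opposing
significant runs never merge. Labels are integers assigned left to right.
Member genes are exactly the genes positioned inside [start, end]; the
window half-width is *not* added back, because whether the original pipeline
extends cluster membership by the radius is unstated and the narrower set is
the conservative choice. Mixed-direction successors in a comparison are kept
as separate clusters and documented by the match table rather than merged.

## Network statistics

"Connections" are edges counted once, not endpoint incidences: an isolated
triangle cluster has inner = 3, outer = 0 and ⟨k⟩ = 1.0, and a one-gene hub
with three outside neighbours has ⟨k⟩ = 3.0. These two toys pin the
semantics of the ambiguous phrase "number of cluster protein connections".
Coverage is the union of cluster gene sets over the network nodes.
Cross-analysis matching uses positional overlap (mirroring the coloured
position bars of the original figures), ties resolved toward the leftmost
earlier cluster; later clusters that overlap nothing, or whose best
antecedent is already claimed, receive capital letters left to right.

## Enrichment

Over-representation is the upper-tail hypergeometric test with universe =
annotated genes present in the ordering (not the whole genome); the universe
choice is logged. Annotations are used exactly as given — no GO-DAG
propagation — so pre-propagated input is expected if ancestry should count.
BH across tested terms, keep adjusted p ≤ 0.05 (the source's enrichment
cutoff is unprinted; 0.05 is the field default and configurable). The
Jaccard dendrogram uses average linkage on 1 − J (no linkage is named in the
source; average linkage is the symmetric, outlier-robust default), leaves
pre-sorted by term id so ties resolve reproducibly, and groups are read at
height 1 − 0.25. Occupation rate = overlap / term size, normalised by the
cluster maximum so at least one term per cluster scores 1.0.

## Sample grouping and markers

Samples are observations; genes are centred, unscaled variables. The
smallest k principal components reaching 95% cumulative variance are
retained. Ward-linkage clustering on the retained scores chooses k ∈
[2, k_max] where the relative loss of within-group inertia between
consecutive cuts, (W(k−1) − W(k)) / (W(k) − W(k+1)), is largest — the
criterion used by automatic PCA-clustering pipelines. No k-means
consolidation follows the cut; consolidation would trade determinism for a
marginal inertia gain. Marker tests pool the variance across *all* groups
(df = N − k, the classical pairwise-t default) and apply BH within each
marker across its group pairs — the smallest defensible correction family,
since each marker's pairs are one question. Significance is adjusted
p ≤ 0.01. A sample may appear in two groups only via `allow_shared=True`
(off by default), accommodating designs that reuse a single baseline sample
in two intervals.

## Synthetic data

The generators emulate the structure the pipeline assumes, not raw RNA-seq:

- **network**: planted-partition graph; within-module pairs connect with
  probability p_in (score 999), between-module pairs with p_out (score 701),
  both above the default 700 score filter by construction.
- **expression**: Gaussian noise on the log-CPM scale around per-gene
  baselines (Normal(6, 2) across genes, the typical spread of filtered
  log-CPM values), sd 0.5 per sample; case samples add each DE module's
  signed shift. Count-level features — mean–variance coupling, library-size
  effects, negative-binomial dispersion — are deliberately absent, so
  passing recovery tests demonstrates the statistical chain, not robustness
  to count noise.
- **annotations**: one term per module plus optional random terms;
  `noise_frac` reassigns that fraction of annotations to random genes
  (1.0 is the negative control for enrichment recovery).
- **time course**: per-gene drift directions fixed once, block j shifted by
  j·drift along them; drift 0 leaves exchangeable samples.

The default demo scenario is 6 modules × 50 genes, p_in 0.25, p_out 0.01,
two DE modules at +1.0 and −1.0, sd 0.5, 6 vs 6 samples. Its analysis radius
is 4: the window diameter (9) must be small relative to the planted module
size (50) for cluster boundaries to track module boundaries, mirroring the
full-scale setting where the 161-position window is small relative to the
interactome. The full-scale defaults (score ≥ 700, radius 80, position
α 0.001, enrichment α 0.05, Jaccard cutoff 0.25, variance target 0.95,
marker α 0.01) are the study conventions and load automatically.

Every generator is a pure function of parameters + seed; identical config
and seed reproduce every tabular output byte for byte (verified in the
suite).

## Problem sizes used in the tests

The suite validates at desk scale: 300-gene planted networks (10 seeds) for
recovery, 600-position null profiles (50 seeds) for the false-positive
control, the exhaustive ≤ 6-node connected-graph battery plus sampled
7-node graphs for seriation optimality, and 18-sample 3-block time courses
for grouping. Full-scale reproduction of a published human-interactome
analysis additionally requires the external expression matrix, the STRING
dump and a GO release, and is supported by the same pipeline via the config
paths and the ordering-import hook (`ordering_path`), but is out of scope
for the tests.

## Known limitations

- The seriation objective is this package's own formalisation; published
  orderings of the human interactome will not be reproduced move for move
  (an external ordering TSV can be imported verbatim instead).
- The moderated t assumes approximate normality of windowed means and
  exchangeable variances across positions; windowed means are strongly
  autocorrelated along the ordering, which the per-position test ignores
  (the BH step is on correlated p-values — conservative under positive
  dependence).
- Enrichment treats annotations as flat sets; no information-content or
  ontology-aware similarity.
- Cluster membership ignores genes pulled into a window from outside
  [start, end]; sensitivity near cluster edges is correspondingly
  conservative.
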