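"""End-to-end orchestration: config, staged execution, manifest, run comparison.

A run directory contains, per stage:

* ``ordering.tsv`` / ``ordering.json`` -- the seriation and its metadata
* ``positions.tsv`` -- per-position gene, moderated t, p, BH-adjusted p, direction
* ``clusters.tsv`` / ``cluster_genes.tsv`` -- called DE clusters and members
* ``connectivity.tsv`` and ``cluster_<label>_edges.tsv`` -- subnetwork stats
* ``enrichment_<label>.tsv``, ``dendrogram_<label>.nwk``,
  ``term_attributes_<label>.tsv`` -- per-cluster term enrichment
* ``groups.tsv``, ``scree.tsv``, ``markers.tsv`` -- sample grouping (when the
  metadata carries a usable time course)
* ``summary.json`` and ``manifest.json`` -- headline numbers, parameters,
  seeds and input checksums

Identical config + seed reproduces every tabular output byte for byte.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
import yaml

from ._version import __version__ as _version
from .dataio import (
    file_checksum,
    intersect_inputs,
    read_annotations,
    read_expression,
    read_ppi_edges,
    read_sample_metadata,
)
from .enrichment import enrichment_table, jaccard_matrix, ora, term_dendrogram, to_newick
from .grouping import (
    NEURONAL_MARKERS,
    NPC_MARKERS,
    cluster_samples,
    marker_table,
    marker_tests,
    pca_samples,
    scree_table,
)
from .netstats import (
    connectivity,
    connectivity_table,
    interactome_coverage,
    match_clusters,
    match_table,
    write_cluster_edges,
)
from .ordering import order_genes, read_ordering, write_ordering
from .profiles import call_clusters, moderated_t, plot_transcriptogram, window_average

logger = logging.getLogger("transcriptogram")

FLOAT_FMT = "%.10g"


@dataclass
class RunConfig:
    """All pipeline parameters; defaults are the study's printed values."""

    ppi_path: str = ""
    expression_path: str = ""
    metadata_path: str = ""
    annotation_path: str = ""
    mapping_path: str = None
    ordering_path: str = None      # import a precomputed ordering verbatim
    out_dir: str = "run"

    score_min: int = 700
    radius: int = 80
    alpha_positions: float = 0.001
    alpha_enrichment: float = 0.05
    jaccard_cutoff: float = 0.25
    variance_target: float = 0.95
    marker_alpha: float = 0.01
    gap: int = 0
    wrap: bool = False             # boundary mode: truncate (default) or wrap
    seed: int = 0
    n_steps: int = None            # annealing budget override
    k_max: int = 10
    markers: tuple = NPC_MARKERS + NEURONAL_MARKERS
    plot: bool = False

    def validate(self) -> None:
        if not 0 <= self.score_min <= 1000:
            raise ValueError("score_min must lie in [0, 1000]")
        if self.radius < 0:
            raise ValueError("radius must be >= 0")
        for name in ("alpha_positions", "alpha_enrichment", "marker_alpha"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must lie in (0, 1)")
        if not 0 <= self.jaccard_cutoff <= 1:
            raise ValueError("jaccard_cutoff must lie in [0, 1]")
        if not 0 < self.variance_target <= 1:
            raise ValueError("variance_target must lie in (0, 1]")
        if self.gap < 0:
            raise ValueError("gap must be >= 0")

    @classmethod
    def from_yaml(cls, path, **overrides) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        raw.update({k: v for k, v in overrides.items() if v is not None})
        cfg = cls(**raw)
        if isinstance(cfg.markers, list):
            cfg.markers = tuple(cfg.markers)
        return cfg

    def to_yaml(self, path) -> None:
        data = dataclasses.asdict(self)
        data["markers"] = list(data["markers"])
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)


def _write_df(df: pd.DataFrame, path, index=False) -> None:
    df.to_csv(path, sep="\t", index=index, float_format=FLOAT_FMT)


def run_pipeline(config: RunConfig) -> Path:
    """Execute every stage and return the run directory."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stages = []

    def stage(name, **info):
        logger.info("stage %s: %s", name, info)
        stages.append({"stage": name, **info})

    # --- dataio ------------------------------------------------------------
    net = read_ppi_edges(config.ppi_path, score_min=config.score_min,
                         mapping=config.mapping_path)
    meta = read_sample_metadata(config.metadata_path)
    expr = read_expression(config.expression_path, meta,
                           mapping=config.mapping_path)
    ann = read_annotations(config.annotation_path) if config.annotation_path else None
    net, expr = intersect_inputs(net, expr)
    stage("dataio", n_genes=net.n_nodes, n_edges=net.n_edges,
          n_samples=len(expr.samples))

    # --- ordering ----------------------------------------------------------
    if config.ordering_path:
        order = read_ordering(config.ordering_path, net=net)
        stage("ordering", imported=str(config.ordering_path), cost=order.cost)
    else:
        order = order_genes(net, seed=config.seed, n_steps=config.n_steps)
        stage("ordering", cost=order.cost, n_steps=order.n_steps)
    write_ordering(order, out / "ordering.tsv", out / "ordering.json")

    # --- transcriptogram ---------------------------------------------------
    profile = window_average(expr, order, config.radius, wrap=config.wrap)
    tests = moderated_t(profile, expr.metadata)
    pos_df = pd.DataFrame(
        [(t.position, profile.gene_by_position[t.position - 1], t.t, t.p,
          t.padj, t.direction, t.lfc) for t in tests],
        columns=["position", "gene", "t", "p", "padj", "direction", "lfc"],
    )
    _write_df(pos_df, out / "positions.tsv")
    clusters = call_clusters(tests, alpha=config.alpha_positions,
                             gap=config.gap, order=order)
    clus_df = pd.DataFrame(
        [(c.label, c.start, c.end, c.direction, c.min_padj, len(c.genes))
         for c in clusters],
        columns=["label", "start", "end", "direction", "min_padj", "n_genes"],
    )
    _write_df(clus_df, out / "clusters.tsv")
    genes_df = pd.DataFrame(
        [(c.label, g) for c in clusters for g in sorted(c.genes)],
        columns=["label", "gene"],
    )
    _write_df(genes_df, out / "cluster_genes.tsv")
    stage("transcriptogram", radius=config.radius, n_clusters=len(clusters))
    if config.plot:
        plot_transcriptogram(profile, expr.metadata, clusters,
                             out / "transcriptogram.png")

    # --- netstats ----------------------------------------------------------
    stats = [connectivity(c, net) for c in clusters]
    _write_df(connectivity_table(stats), out / "connectivity.tsv")
    for c in clusters:
        write_cluster_edges(c, net, out / f"cluster_{c.label}_edges.tsv")
    coverage = interactome_coverage(clusters, net)
    stage("netstats", interactome_coverage=coverage)

    # --- enrichment --------------------------------------------------------
    n_enriched = {}
    if ann is not None:
        universe = ann.genes & set(order.position)
        if universe:
            for c in clusters:
                cluster_universe_genes = c.genes & universe
                enriched = ora(cluster_universe_genes, ann, universe,
                               alpha=config.alpha_enrichment)
                _write_df(enrichment_table(enriched),
                          out / f"enrichment_{c.label}.tsv")
                n_enriched[c.label] = len(enriched)
                if len(enriched) >= 1:
                    if len(enriched) >= 2:
                        jac = jaccard_matrix(enriched, ann, universe=universe)
                        tree = term_dendrogram(jac, cutoff=config.jaccard_cutoff,
                                               enriched=enriched)
                    else:
                        tree = term_dendrogram(
                            pd.DataFrame([[1.0]], index=[enriched[0].term],
                                         columns=[enriched[0].term]),
                            cutoff=config.jaccard_cutoff, enriched=enriched)
                    with open(out / f"dendrogram_{c.label}.nwk", "w") as fh:
                        fh.write(to_newick(tree) + "\n")
                    _write_df(tree.attributes,
                              out / f"term_attributes_{c.label}.tsv")
            stage("enrichment", universe=len(universe),
                  n_enriched=n_enriched)
        else:
            logger.warning("no annotated genes in the ordering; enrichment skipped")

    # --- grouping (when the metadata carries a time course) -----------------
    sample_meta = expr.metadata.loc[expr.samples]
    if sample_meta["day"].nunique() > 1 and len(expr.samples) >= 3:
        groups = pca_samples(expr, variance_target=config.variance_target)
        groups = cluster_samples(groups, k_max=config.k_max)
        groups_df = pd.DataFrame(
            sorted(groups.assignment.items()), columns=["sample", "group"])
        _write_df(groups_df, out / "groups.tsv")
        _write_df(scree_table(groups), out / "scree.tsv")
        present = [m for m in config.markers if m in expr.values.index]
        if present and groups.k_groups >= 2:
            results = marker_tests(expr, groups.assignment, present,
                                   alpha=config.marker_alpha)
            _write_df(marker_table(results), out / "markers.tsv")
        stage("grouping", k_components=groups.k_components,
              k_groups=groups.k_groups, n_markers_tested=len(present))

    # --- summary & manifest -------------------------------------------------
    summary = {
        "n_genes": net.n_nodes,
        "n_edges": net.n_edges,
        "n_clusters": len(clusters),
        "interactome_coverage": coverage,
        "clusters": [
            {"label": c.label, "start": c.start, "end": c.end,
             "direction": c.direction, "n_genes": len(c.genes),
             "min_padj": c.min_padj,
             "n_enriched_terms": n_enriched.get(c.label)}
            for c in clusters
        ],
    }
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")

    checksums = {}
    for name in ("ppi_path", "expression_path", "metadata_path",
                 "annotation_path", "mapping_path", "ordering_path"):
        p = getattr(config, name)
        if p:
            checksums[name] = file_checksum(p)
    cfg = dataclasses.asdict(config)
    cfg["markers"] = list(cfg["markers"])
    manifest = {
        "version": _version,
        "seed": config.seed,
        "parameters": cfg,
        "input_checksums": checksums,
        "ordering_checksum": order.checksum(),
        "stages": stages,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return out


# ---------------------------------------------------------------------------
# Run comparison (cluster evolution across analyses)
# ---------------------------------------------------------------------------


def _load_run_clusters(run_dir: Path):
    from .profiles import DECluster

    run_dir = Path(run_dir)
    clus = pd.read_csv(run_dir / "clusters.tsv", sep="\t",
                       dtype={"label": str})
    member = pd.read_csv(run_dir / "cluster_genes.tsv", sep="\t",
                         dtype={"label": str, "gene": str})
    by_label = {lab: frozenset(df["gene"]) for lab, df in member.groupby("label")}
    clusters = [
        DECluster(label=row.label, start=int(row.start), end=int(row.end),
                  direction=row.direction, genes=by_label.get(row.label, frozenset()),
                  min_padj=float(row.min_padj))
        for row in clus.itertuples()
    ]
    with open(run_dir / "manifest.json") as fh:
        manifest = json.load(fh)
    conn = pd.read_csv(run_dir / "connectivity.tsv", sep="\t", dtype={"label": str})
    return clusters, manifest["ordering_checksum"], conn


def compare_runs(run_a, run_b, out_dir=None):
    """Match B's clusters to A's by positional overlap; tabulate the evolution
    of node counts and average connectivity.  Both runs must share the same
    ordering (verified via the manifest checksum)."""
    a, ck_a, conn_a = _load_run_clusters(run_a)
    b, ck_b, conn_b = _load_run_clusters(run_b)
    if ck_a != ck_b:
        raise ValueError("runs used different orderings (checksum mismatch)")
    match = match_clusters(a, b, checksum_a=ck_a, checksum_b=ck_b)

    conn_a = conn_a.set_index("label")
    conn_b = conn_b.set_index("label")
    dir_a = {c.label: c.direction for c in a}
    dir_b = {c.label: c.direction for c in b}
    inherited = {new: old_b for old_b, new in match.relabel.items()}
    matched_a = {lab for lab, _, _ in match.pairs}
    rows = []
    for new_label in sorted(match.relabel.values(),
                            key=lambda s: (len(s), s) if s.isalpha() else (0, s.zfill(6))):
        b_label = inherited[new_label]
        a_label = new_label if new_label in matched_a else None
        rows.append({
            "label": new_label,
            "direction_a": dir_a.get(a_label, "absent"),
            "direction_b": dir_b[b_label],
            "n_nodes_a": int(conn_a.at[a_label, "n_nodes"]) if a_label else 0,
            "n_nodes_b": int(conn_b.at[b_label, "n_nodes"]),
            "avg_k_a": float(conn_a.at[a_label, "avg_k"]) if a_label else 0.0,
            "avg_k_b": float(conn_b.at[b_label, "avg_k"]),
        })
    for c in a:  # clusters with no successor in B
        if c.label not in matched_a:
            rows.append({
                "label": c.label, "direction_a": c.direction,
                "direction_b": "absent",
                "n_nodes_a": int(conn_a.at[c.label, "n_nodes"]), "n_nodes_b": 0,
                "avg_k_a": float(conn_a.at[c.label, "avg_k"]), "avg_k_b": 0.0,
            })
    evolution = pd.DataFrame(rows)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        _write_df(match_table(match), out_dir / "match.tsv")
        _write_df(evolution, out_dir / "evolution.tsv")
    return match, evolution
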