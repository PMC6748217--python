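"""Input parsing, validation and tabular output for the transcriptogram pipeline.

Three standard inputs are consumed:

* a protein-protein interaction edge list in the STRING ``protein.links``
  dialect (``protein1 protein2 combined_score``, scores on the 0-1000 scale),
* a gene x sample expression matrix in log2-counts-per-million (log-CPM),
* a gene-to-term annotation table (plain 2-3 column TSV or GAF 2.x),

plus a sample-metadata table assigning each sample a condition
(case/control) and an experiment day.

One shared identifier namespace is assumed: the gene identifiers of the
expression matrix are the node identifiers of the network.  An optional
two-column mapping table can be applied at load time to translate one
namespace into the other.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger("transcriptogram")

CONDITIONS = ("case", "control")


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class InteractionNetwork:
    """Undirected scored gene graph -- the interactome all statistics refer to.

    Wraps a :class:`networkx.Graph` whose edges carry an integer ``score``
    attribute in [0, 1000].  Self-loops are forbidden and at most one edge may
    join a pair of genes.
    """

    graph: nx.Graph = field(default_factory=nx.Graph)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for u, v, d in self.graph.edges(data=True):
            if u == v:
                raise ValueError(f"self-loop on node {u!r}")
            score = d.get("score")
            if not isinstance(score, (int, np.integer)):
                raise ValueError(f"edge {u!r}-{v!r} has non-integer score {score!r}")
            if not 0 <= score <= 1000:
                raise ValueError(f"edge {u!r}-{v!r} score {score} outside [0, 1000]")

    @property
    def nodes(self) -> set:
        return set(self.graph.nodes)

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def subgraph(self, genes) -> "InteractionNetwork":
        return InteractionNetwork(self.graph.subgraph(genes).copy())

    def __eq__(self, other) -> bool:
        if not isinstance(other, InteractionNetwork):
            return NotImplemented
        return (
            self.nodes == other.nodes
            and {frozenset(e): d["score"] for *e, d in self.graph.edges(data=True)}
            == {frozenset(e): d["score"] for *e, d in other.graph.edges(data=True)}
        )


@dataclass
class ExpressionMatrix:
    """Gene x sample log-CPM matrix with per-sample condition/day metadata."""

    values: pd.DataFrame  # genes x samples, float
    metadata: pd.DataFrame  # indexed by sample; columns: condition, day

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        v = self.values
        if v.index.has_duplicates:
            dups = v.index[v.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene identifiers: {dups}")
        if v.columns.has_duplicates:
            dups = v.columns[v.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample identifiers: {dups}")
        arr = v.to_numpy(dtype=float)
        if not np.all(np.isfinite(arr)):
            raise ValueError("expression matrix contains non-finite values")
        if "condition" not in self.metadata.columns:
            raise ValueError("sample metadata lacks a 'condition' column")
        missing = [s for s in v.columns if s not in self.metadata.index]
        if missing:
            raise ValueError(f"samples missing from metadata: {missing}")
        bad = set(self.metadata.loc[list(v.columns), "condition"]) - set(CONDITIONS)
        if bad:
            raise ValueError(f"unknown conditions {sorted(bad)}; expected {CONDITIONS}")
        if "day" not in self.metadata.columns:
            self.metadata = self.metadata.assign(day=0)

    @property
    def genes(self) -> list:
        return list(self.values.index)

    @property
    def samples(self) -> list:
        return list(self.values.columns)

    def samples_of(self, condition: str) -> list:
        meta = self.metadata.loc[list(self.values.columns)]
        return [s for s in self.values.columns if meta.at[s, "condition"] == condition]

    def subset_genes(self, genes) -> "ExpressionMatrix":
        keep = [g for g in self.values.index if g in set(genes)]
        return ExpressionMatrix(self.values.loc[keep].copy(), self.metadata)


@dataclass
class AnnotationTable:
    """Gene-to-term annotation records (optionally carrying a term name)."""

    records: pd.DataFrame  # columns: gene, term, name

    def __post_init__(self) -> None:
        df = self.records
        for col in ("gene", "term"):
            if col not in df.columns:
                raise ValueError(f"annotation table lacks a {col!r} column")
        if "name" not in df.columns:
            df = df.assign(name="")
        if df.duplicated(subset=["gene", "term"]).any():
            dup = df[df.duplicated(subset=["gene", "term"])].iloc[0]
            raise ValueError(f"duplicate annotation ({dup['gene']}, {dup['term']})")
        self.records = df.reset_index(drop=True)

    def term_genes(self, universe=None) -> dict:
        """Mapping term -> frozenset of annotated genes, optionally universe-restricted."""
        df = self.records
        if universe is not None:
            df = df[df["gene"].isin(set(universe))]
        return {t: frozenset(g["gene"]) for t, g in df.groupby("term", sort=True)}

    def term_names(self) -> dict:
        df = self.records[self.records["name"].astype(str) != ""]
        return dict(zip(df["term"], df["name"]))

    @property
    def genes(self) -> set:
        return set(self.records["gene"])


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------


def _load_mapping(path) -> dict:
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    if df.shape[1] < 2:
        raise ValueError(f"mapping file {path} needs two columns")
    mapping: dict = {}
    skipped = 0
    seen_targets: set = set()
    for src, dst in zip(df.iloc[:, 0], df.iloc[:, 1]):
        if src in mapping or dst in seen_targets:
            skipped += 1  # many-to-one: first occurrence wins
            continue
        mapping[src] = dst
        seen_targets.add(dst)
    if skipped:
        logger.info("identifier mapping: kept first occurrence, skipped %d rows", skipped)
    return mapping


def read_ppi_edges(path, score_min: int = 700, mapping=None) -> InteractionNetwork:
    """Read a STRING-dialect edge list, keeping edges with score >= ``score_min``.

    Duplicate and reversed records collapse to one undirected edge keeping the
    maximum score; self-loops are dropped (a count is logged).  The threshold
    is inclusive, matching the "combined score >= 700" construction.
    """
    if not 0 <= score_min <= 1000:
        raise ValueError(f"score_min {score_min} outside [0, 1000]")
    path = Path(path)
    idmap = _load_mapping(mapping) if mapping is not None else None

    best: dict = {}
    self_loops = 0
    n_records = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            parts = line.split()
            if not parts or line.startswith("#"):
                continue
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: expected >= 3 columns")
            u, v, raw = parts[0], parts[1], parts[2]
            try:
                score = int(raw)
            except ValueError:
                if lineno == 1:  # header row
                    continue
                raise ValueError(f"{path}:{lineno}: non-integer score {raw!r}") from None
            n_records += 1
            if idmap is not None:
                u = idmap.get(u, u)
                v = idmap.get(v, v)
            if u == v:
                self_loops += 1
                continue
            key = (u, v) if u <= v else (v, u)
            if score > best.get(key, -1):
                best[key] = score
    if self_loops:
        logger.info("read_ppi_edges: dropped %d self-loop records", self_loops)

    g = nx.Graph()
    for (u, v), score in best.items():
        if score >= score_min:
            g.add_edge(u, v, score=score)
    if n_records and g.number_of_edges() == 0:
        raise ValueError(
            f"no edges left after filtering at combined score >= {score_min} "
            f"({n_records} records read): threshold too strict?"
        )
    logger.info(
        "read_ppi_edges: %d nodes, %d edges at score >= %d",
        g.number_of_nodes(), g.number_of_edges(), score_min,
    )
    return InteractionNetwork(g)


def read_sample_metadata(path) -> pd.DataFrame:
    """Read a sample metadata TSV (columns: sample, condition, day)."""
    df = pd.read_csv(path, sep="\t", dtype={"sample": str, "condition": str})
    for col in ("sample", "condition"):
        if col not in df.columns:
            raise ValueError(f"metadata {path} lacks a {col!r} column")
    if "day" not in df.columns:
        df["day"] = 0
    df["day"] = df["day"].astype(int)
    if (df["day"] < 0).any():
        raise ValueError("metadata contains negative days")
    if df["sample"].duplicated().any():
        dups = df.loc[df["sample"].duplicated(), "sample"].tolist()
        raise ValueError(f"duplicate samples in metadata: {dups}")
    return df.set_index("sample")


def read_expression(path, metadata, mapping=None) -> ExpressionMatrix:
    """Read a genes x samples log-CPM TSV and join sample metadata.

    ``metadata`` is a path to a metadata TSV or an already-loaded frame as
    returned by :func:`read_sample_metadata`.
    """
    values = pd.read_csv(path, sep="\t", index_col=0)
    values.index = values.index.astype(str)
    if values.index.has_duplicates:
        dup = values.index[values.index.duplicated()].unique().tolist()
        raise ValueError(f"{path}: duplicate gene identifier(s) {dup}")
    try:
        values = values.astype(float)
    except ValueError as exc:
        raise ValueError(f"{path}: non-numeric expression value ({exc})") from None
    if mapping is not None:
        idmap = _load_mapping(mapping)
        new_index = [idmap.get(g, g) for g in values.index]
        dup_mask = pd.Index(new_index).duplicated()
        if dup_mask.any():
            logger.info("read_expression: mapping collapsed %d genes; keeping first",
                        int(dup_mask.sum()))
            values = values.loc[~dup_mask]
            new_index = [g for g, d in zip(new_index, dup_mask) if not d]
        values.index = new_index
    meta = metadata if isinstance(metadata, pd.DataFrame) else read_sample_metadata(metadata)
    missing = [s for s in values.columns if s not in meta.index]
    if missing:
        raise ValueError(f"sample(s) {missing} present in matrix but absent from metadata")
    return ExpressionMatrix(values, meta)


def read_annotations(path, mapping=None) -> AnnotationTable:
    """Read gene-to-term annotations from a 2-3 column TSV or a GAF 2.x file.

    GAF rows with a NOT qualifier are skipped; columns 2 (object id) and
    5 (term id) are used.
    """
    path = Path(path)
    first = ""
    with open(path) as fh:
        for line in fh:
            first = line
            break
    if first.startswith("!gaf-version") or first.startswith("!"):
        rows = []
        with open(path) as fh:
            for line in fh:
                if line.startswith("!") or not line.strip():
                    continue
                cols = line.rstrip("\n").split("\t")
                if len(cols) < 5:
                    raise ValueError(f"{path}: GAF row with < 5 columns")
                if "NOT" in cols[3].split("|"):
                    continue
                rows.append((cols[1], cols[4]))
        df = pd.DataFrame(rows, columns=["gene", "term"]).drop_duplicates()
        df["name"] = ""
    else:
        header = first.rstrip("\n").split("\t")
        has_header = header[:2] == ["gene", "term"]
        df = pd.read_csv(path, sep="\t", dtype=str,
                         header=0 if has_header else None)
        if not has_header:
            names = ["gene", "term", "name"][: df.shape[1]]
            df.columns = names
        if "name" not in df.columns:
            df["name"] = ""
        df = df[["gene", "term", "name"]].fillna({"name": ""}).drop_duplicates(
            subset=["gene", "term"])
    if mapping is not None:
        idmap = _load_mapping(mapping)
        df = df.assign(gene=[idmap.get(g, g) for g in df["gene"]])
        df = df.drop_duplicates(subset=["gene", "term"])
    return AnnotationTable(df.reset_index(drop=True))


# ---------------------------------------------------------------------------
# Intersection
# ---------------------------------------------------------------------------


def intersect_inputs(net: InteractionNetwork, expr: ExpressionMatrix):
    """Restrict network and expression matrix to their common gene set.

    Downstream, "the interactome" always means the restricted network.  Genes
    found on only one side are dropped and counted in the log.
    """
    net_genes = net.nodes
    expr_genes = set(expr.genes)
    common = net_genes & expr_genes
    if not common:
        raise ValueError("network and expression matrix share no genes")
    dropped_net = len(net_genes - common)
    dropped_expr = len(expr_genes - common)
    if dropped_net or dropped_expr:
        logger.info(
            "intersect_inputs: dropped %d network-only and %d expression-only genes",
            dropped_net, dropped_expr,
        )
    if not dropped_net and not dropped_expr:
        return net, expr
    return net.subgraph(common), expr.subset_genes(common)


# ---------------------------------------------------------------------------
# Writers (round-trip exact with the readers above)
# ---------------------------------------------------------------------------


def write_network(net: InteractionNetwork, path) -> None:
    rows = sorted(
        (min(u, v), max(u, v), d["score"]) for u, v, d in net.graph.edges(data=True)
    )
    with open(path, "w") as fh:
        fh.write("protein1 protein2 combined_score\n")
        for u, v, s in rows:
            fh.write(f"{u} {v} {s}\n")


def write_expression(expr: ExpressionMatrix, values_path, metadata_path=None) -> None:
    df = expr.values.copy()
    df.index.name = "gene"
    df.to_csv(values_path, sep="\t", float_format="%.10g")
    if metadata_path is not None:
        meta = expr.metadata.loc[list(expr.values.columns)].copy()
        meta.index.name = "sample"
        meta.to_csv(metadata_path, sep="\t")


def write_annotations(ann: AnnotationTable, path) -> None:
    ann.records.to_csv(path, sep="\t", index=False)


def file_checksum(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()
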