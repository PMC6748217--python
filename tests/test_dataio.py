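import networkx as nx
import numpy as np
import pandas as pd
import pytest

from transcriptogram import (
    AnnotationTable,
    ExpressionMatrix,
    intersect_inputs,
    read_annotations,
    read_expression,
    read_ppi_edges,
    read_sample_metadata,
)
from transcriptogram.dataio import (
    write_annotations,
    write_expression,
    write_network,
)

from conftest import make_network


def write_ppi(tmp_path, rows, header=True):
    path = tmp_path / "links.txt"
    lines = ["protein1 protein2 combined_score"] if header else []
    lines += [f"{u} {v} {s}" for u, v, s in rows]
    path.write_text("\n".join(lines) + "\n")
    return path


class TestReadPPI:
    def test_inclusive_threshold(self, tmp_path):
        path = write_ppi(tmp_path, [("a", "b", 900), ("b", "c", 700), ("c", "d", 699)])
        net = read_ppi_edges(path, score_min=700)
        assert net.n_edges == 2
        assert net.graph.edges["b", "c"]["score"] == 700

    def test_reversed_records_collapse_keeping_max(self, tmp_path):
        path = write_ppi(tmp_path, [("a", "b", 800), ("b", "a", 850)])
        net = read_ppi_edges(path, score_min=700)
        assert net.n_edges == 1
        assert net.graph.edges["a", "b"]["score"] == 850

    def test_self_loops_dropped(self, tmp_path, caplog):
        path = write_ppi(tmp_path, [("a", "a", 900), ("a", "b", 900)])
        with caplog.at_level("INFO", logger="transcriptogram"):
            net = read_ppi_edges(path, score_min=700)
        assert net.n_edges == 1
        assert "1 self-loop" in caplog.text

    def test_headerless_file(self, tmp_path):
        path = write_ppi(tmp_path, [("a", "b", 800)], header=False)
        assert read_ppi_edges(path, score_min=700).n_edges == 1

    def test_non_integer_score_rejected(self, tmp_path):
        path = tmp_path / "bad.txt"
        path.write_text("a b 800\nb c eight\n")
        with pytest.raises(ValueError, match="non-integer score"):
            read_ppi_edges(path, score_min=0)

    def test_empty_after_filter_rejected(self, tmp_path):
        path = write_ppi(tmp_path, [("a", "b", 500)])
        with pytest.raises(ValueError, match="threshold too strict"):
            read_ppi_edges(path, score_min=700)

    def test_filter_monotone_in_threshold(self, tmp_path):
        rng = np.random.default_rng(0)
        rows = [(f"g{i}", f"g{j}", int(rng.integers(0, 1001)))
                for i in range(12) for j in range(i + 1, 12)]
        path = write_ppi(tmp_path, rows)
        counts = [read_ppi_edges(path, score_min=t).n_edges
                  for t in (0, 200, 400, 600, 800)]
        assert counts == sorted(counts, reverse=True)

    def test_identifier_mapping_applied(self, tmp_path):
        path = write_ppi(tmp_path, [("ENSP1", "ENSP2", 900)])
        mapping = tmp_path / "map.tsv"
        mapping.write_text("ENSP1\tGENE1\nENSP2\tGENE2\n")
        net = read_ppi_edges(path, score_min=700, mapping=mapping)
        assert net.nodes == {"GENE1", "GENE2"}


def write_expr(tmp_path, values, genes, samples, meta_rows=None):
    expr_path = tmp_path / "expr.tsv"
    df = pd.DataFrame(values, index=genes, columns=samples)
    df.index.name = "gene"
    df.to_csv(expr_path, sep="\t")
    meta_path = tmp_path / "meta.tsv"
    rows = meta_rows or [(s, "case" if i % 2 == 0 else "control", 0)
                         for i, s in enumerate(samples)]
    meta_path.write_text("sample\tcondition\tday\n"
                         + "\n".join(f"{s}\t{c}\t{d}" for s, c, d in rows) + "\n")
    return expr_path, meta_path


class TestReadExpression:
    def test_well_formed(self, tmp_path):
        ep, mp = write_expr(tmp_path, [[1.0, 2.0, 3.0], [4.0, 5.0, 6.0]],
                            ["g1", "g2"], ["s1", "s2", "s3"])
        expr = read_expression(ep, mp)
        assert expr.genes == ["g1", "g2"]
        assert expr.samples == ["s1", "s2", "s3"]
        assert expr.values.loc["g2", "s3"] == 6.0

    def test_duplicate_gene_named_in_error(self, tmp_path):
        ep, mp = write_expr(tmp_path, [[1.0], [2.0]], ["gX", "gX"], ["s1"])
        with pytest.raises(ValueError, match="gX"):
            read_expression(ep, mp)

    def test_missing_sample_named_in_error(self, tmp_path):
        ep, mp = write_expr(tmp_path, [[1.0, 2.0]], ["g1"], ["s1", "S9"],
                            meta_rows=[("s1", "case", 0)])
        with pytest.raises(ValueError, match="S9"):
            read_expression(ep, mp)

    def test_non_numeric_cell_rejected(self, tmp_path):
        ep = tmp_path / "e.tsv"
        ep.write_text("gene\ts1\ng1\tlow\n")
        mp = tmp_path / "m.tsv"
        mp.write_text("sample\tcondition\tday\ns1\tcase\t0\n")
        with pytest.raises(ValueError, match="non-numeric"):
            read_expression(ep, mp)

    def test_negative_day_rejected(self, tmp_path):
        mp = tmp_path / "m.tsv"
        mp.write_text("sample\tcondition\tday\ns1\tcase\t-1\n")
        with pytest.raises(ValueError, match="negative"):
            read_sample_metadata(mp)


class TestAnnotations:
    def test_plain_tsv(self, tmp_path):
        p = tmp_path / "ann.tsv"
        p.write_text("g1\tGO:1\tthing\ng2\tGO:1\tthing\ng1\tGO:2\tother\n")
        ann = read_annotations(p)
        assert ann.term_genes() == {"GO:1": {"g1", "g2"}, "GO:2": {"g1"}}
        assert ann.term_names()["GO:2"] == "other"

    def test_gaf_not_qualifier_skipped(self, tmp_path):
        p = tmp_path / "ann.gaf"
        p.write_text(
            "!gaf-version: 2.2\n"
            "DB\tg1\tG1\tinvolved_in\tGO:1\tref\tIEA\n"
            "DB\tg2\tG2\tNOT|involved_in\tGO:1\tref\tIEA\n"
            "DB\tg2\tG2\tinvolved_in\tGO:2\tref\tIEA\n"
        )
        ann = read_annotations(p)
        assert ann.term_genes() == {"GO:1": {"g1"}, "GO:2": {"g2"}}

    def test_duplicate_pair_rejected(self):
        df = pd.DataFrame({"gene": ["g1", "g1"], "term": ["GO:1", "GO:1"]})
        with pytest.raises(ValueError, match="duplicate"):
            AnnotationTable(df)


class TestIntersect:
    def _expr(self, genes):
        vals = pd.DataFrame(np.ones((len(genes), 2)), index=genes,
                            columns=["s1", "s2"])
        meta = pd.DataFrame({"condition": ["case", "control"], "day": 0},
                            index=["s1", "s2"])
        return ExpressionMatrix(vals, meta)

    def test_restricts_both_sides(self):
        net = make_network([("a", "b"), ("b", "c")])
        net2, expr2 = intersect_inputs(net, self._expr(["b", "c", "d"]))
        assert net2.nodes == {"b", "c"}
        assert expr2.genes == ["b", "c"]

    def test_identity_when_equal(self):
        net = make_network([("a", "b")])
        expr = self._expr(["a", "b"])
        net2, expr2 = intersect_inputs(net, expr)
        assert net2 is net and expr2 is expr

    def test_disjoint_rejected(self):
        net = make_network([("a", "b")])
        with pytest.raises(ValueError, match="no genes"):
            intersect_inputs(net, self._expr(["x", "y"]))


class TestRoundTrip:
    def test_network(self, tmp_path):
        net = make_network([("a", "b", 900), ("b", "c", 701)])
        path = tmp_path / "net.tsv"
        write_network(net, path)
        assert read_ppi_edges(path, score_min=0) == net

    def test_expression(self, tmp_path):
        rng = np.random.default_rng(1)
        genes = [f"g{i}" for i in range(5)]
        vals = pd.DataFrame(rng.normal(6, 2, (5, 4)), index=genes,
                            columns=["c1", "c2", "k1", "k2"])
        meta = pd.DataFrame({"condition": ["case", "case", "control", "control"],
                             "day": [1, 2, 1, 2]}, index=vals.columns)
        expr = ExpressionMatrix(vals, meta)
        ep, mp = tmp_path / "e.tsv", tmp_path / "m.tsv"
        write_expression(expr, ep, mp)
        back = read_expression(ep, mp)
        pd.testing.assert_frame_equal(back.values, expr.values,
                                      check_names=False)
        assert list(back.metadata.loc[back.samples, "day"]) == [1, 2, 1, 2]

    def test_annotations(self, tmp_path):
        ann = AnnotationTable(pd.DataFrame(
            {"gene": ["g1", "g2"], "term": ["GO:1", "GO:1"], "name": ["t", "t"]}))
        path = tmp_path / "ann.tsv"
        write_annotations(ann, path)
        assert read_annotations(path).term_genes() == ann.term_genes()


class TestNetworkInvariants:
    def test_self_loop_rejected(self):
        g = nx.Graph()
        g.add_edge("a", "a", score=10)
        with pytest.raises(ValueError, match="self-loop"):
            from transcriptogram import InteractionNetwork
            InteractionNetwork(g)

    def test_score_range_enforced(self):
        with pytest.raises(ValueError, match="outside"):
            make_network([("a", "b", 1500)])
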