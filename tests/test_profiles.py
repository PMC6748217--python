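import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from transcriptogram import (
    GeneOrdering,
    adjust_bh,
    call_clusters,
    moderated_t,
    relative_profile,
    window_average,
)
from transcriptogram.profiles import PositionTest, fit_f_dist, trigamma_inverse
from transcriptogram.synthetic import SyntheticTruth
from transcriptogram import gen_expression

from conftest import make_metadata, make_profile
from oracles import moderated_t_direct, pooled_t_two_group, window_mean_direct, bh_step_up


def expr_and_order(n_genes, n_case=3, n_control=3, seed=0):
    truth = SyntheticTruth(
        module_of={f"g{i:03d}": 1 for i in range(n_genes)},
        de_effects={}, noise_sd=0.5, seed=seed)
    expr = gen_expression(truth, n_case=n_case, n_control=n_control, seed=seed)
    order = GeneOrdering({g: i + 1 for i, g in enumerate(sorted(truth.module_of))}, 0.0)
    return expr, order


class TestWindowAverage:
    def test_radius_zero_is_identity(self):
        expr, order = expr_and_order(20)
        profile = window_average(expr, order, 0)
        np.testing.assert_array_equal(
            profile.values.to_numpy(),
            expr.values.loc[profile.gene_by_position].to_numpy())

    def test_small_window_arithmetic(self):
        expr, order = expr_and_order(4)
        expr.values.iloc[:, 0] = [1.0, 2.0, 3.0, 4.0]
        profile = window_average(expr, order, 1)
        assert profile.values.iloc[1, 0] == pytest.approx((1 + 2 + 3) / 3)
        assert profile.values.iloc[0, 0] == pytest.approx((1 + 2) / 2)  # truncated
        assert profile.values.iloc[3, 0] == pytest.approx((3 + 4) / 2)

    def test_full_window_equals_global_mean(self):
        expr, order = expr_and_order(10)
        profile = window_average(expr, order, 9)
        expected = expr.values.loc[profile.gene_by_position].mean(axis=0)
        for i in range(10):
            np.testing.assert_allclose(profile.values.iloc[i].to_numpy(),
                                       expected.to_numpy())

    def test_radius_beyond_length_warns_but_computes(self, caplog):
        expr, order = expr_and_order(5)
        with caplog.at_level("WARNING", logger="transcriptogram"):
            profile = window_average(expr, order, 50)
        assert "whole" in caplog.text
        assert profile.values.shape == (5, expr.values.shape[1])

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_direct_per_position_mean(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 40))
        radius = int(rng.integers(0, n + 2))
        expr, order = expr_and_order(n, seed=seed)
        profile = window_average(expr, order, radius)
        direct = window_mean_direct(
            expr.values.loc[profile.gene_by_position].to_numpy(), radius)
        np.testing.assert_array_equal(profile.values.to_numpy(), direct)

    def test_wrap_mode_uses_circular_windows(self):
        expr, order = expr_and_order(6)
        mat = expr.values.loc[sorted(expr.genes)].to_numpy()
        profile = window_average(expr, order, 1, wrap=True)
        expected_first = (mat[-1] + mat[0] + mat[1]) / 3
        np.testing.assert_allclose(profile.values.iloc[0].to_numpy(), expected_first)

    def test_negative_radius_rejected(self):
        expr, order = expr_and_order(4)
        with pytest.raises(ValueError):
            window_average(expr, order, -1)


class TestRelativeProfile:
    def test_identical_conditions_give_zero(self):
        vals = np.tile(np.arange(5, dtype=float)[:, None], (1, 4))
        profile = make_profile(vals)
        meta = make_metadata(["s0", "s1"], ["s2", "s3"])
        assert relative_profile(profile, meta).abs().max() == 0

    def test_constant_offset_recovered(self):
        base = np.random.default_rng(0).normal(size=(8, 2))
        vals = np.hstack([base + 0.7, base])
        profile = make_profile(vals)
        meta = make_metadata(["s0", "s1"], ["s2", "s3"])
        np.testing.assert_allclose(relative_profile(profile, meta), 0.7)

    def test_single_sample_each_is_pointwise_difference(self):
        vals = np.array([[3.0, 1.0], [5.0, 9.0]])
        profile = make_profile(vals)
        meta = make_metadata(["s0"], ["s1"])
        np.testing.assert_allclose(relative_profile(profile, meta), [2.0, -4.0])

    def test_missing_condition_rejected(self):
        profile = make_profile(np.ones((3, 2)))
        meta = make_metadata(["s0", "s1"], [])
        with pytest.raises(ValueError, match="case and control"):
            relative_profile(profile, meta)


class TestModeratedT:
    def _profile(self, seed=0, n_pos=30, n1=4, n2=4, het=True):
        rng = np.random.default_rng(seed)
        x = rng.normal(5, 1, size=(n_pos, n1 + n2))
        if het:
            x *= rng.uniform(0.4, 2.5, size=(n_pos, 1))
        samples = [f"c{i}" for i in range(n1)] + [f"k{i}" for i in range(n2)]
        return make_profile(x, samples), make_metadata(samples[:n1], samples[n1:]), x

    def test_d0_zero_reduces_to_pooled_t(self):
        profile, meta, x = self._profile()
        tests = moderated_t(profile, meta, d0=0.0, s20=1.0)
        for i, tt in enumerate(tests):
            t_ref, p_ref = pooled_t_two_group(x[i, :4], x[i, 4:])
            assert tt.t == pytest.approx(t_ref)
            assert tt.p == pytest.approx(p_ref)

    def test_d0_infinite_shares_one_variance(self):
        profile, meta, x = self._profile()
        tests = moderated_t(profile, meta, d0=math.inf, s20=0.9)
        diffs = x[:, :4].mean(axis=1) - x[:, 4:].mean(axis=1)
        se = math.sqrt(0.9 * (1 / 4 + 1 / 4))
        np.testing.assert_allclose([t.t for t in tests], diffs / se)

    def test_matches_direct_formula_with_fitted_prior(self):
        """4v4 toy profile vs an independent closed-form computation."""
        profile, meta, x = self._profile(seed=3)
        d = 4 + 4 - 2
        s2 = (((x[:, :4] - x[:, :4].mean(1, keepdims=True)) ** 2).sum(1)
              + ((x[:, 4:] - x[:, 4:].mean(1, keepdims=True)) ** 2).sum(1)) / d
        d0, s20 = fit_f_dist(s2, d)
        t_ref, p_ref = moderated_t_direct(x[:, :4], x[:, 4:], d0, s20)
        tests = moderated_t(profile, meta)
        np.testing.assert_allclose([t.t for t in tests], t_ref, rtol=1e-12)
        np.testing.assert_allclose([t.p for t in tests], p_ref, rtol=1e-12)

    def test_matches_bioconductor_limma(self, tmp_path):
        """Cross-check t and p against limma's lmFit + eBayes via Rscript."""
        import subprocess

        profile, meta, x = self._profile(seed=11, n_pos=25)
        df = pd.DataFrame(x, index=[f"p{i}" for i in range(25)],
                          columns=profile.values.columns)
        df.to_csv(tmp_path / "mat.tsv", sep="\t")
        script = tmp_path / "limma_check.R"
        script.write_text(
            'suppressMessages(library(limma))\n'
            f'x <- as.matrix(read.delim("{tmp_path / "mat.tsv"}", row.names=1))\n'
            'design <- cbind(Intercept=1, case=c(rep(1,4), rep(0,4)))\n'
            'fit <- eBayes(lmFit(x, design))\n'
            'write.csv(data.frame(t=fit$t[,"case"], p=fit$p.value[,"case"]),\n'
            f'          "{tmp_path / "out.csv"}")\n'
        )
        res = subprocess.run(["Rscript", str(script)], capture_output=True, text=True)
        assert res.returncode == 0, res.stderr
        ref = pd.read_csv(tmp_path / "out.csv", index_col=0)
        tests = moderated_t(profile, meta)
        np.testing.assert_allclose([t.t for t in tests], ref["t"], atol=1e-10)
        np.testing.assert_allclose([t.p for t in tests], ref["p"], atol=1e-10)

    def test_direction_follows_case_minus_control(self):
        vals = np.array([[2.0, 2.1, 1.0, 1.1], [0.0, 0.1, 3.0, 3.1],
                         [1.0, 1.1, 1.0, 1.1]])
        profile = make_profile(vals, samples=["c1", "c2", "k1", "k2"])
        meta = make_metadata(["c1", "c2"], ["k1", "k2"])
        tests = moderated_t(profile, meta)
        assert [t.direction for t in tests] == ["up", "down", "zero"]

    def test_too_few_samples_rejected(self):
        profile = make_profile(np.ones((3, 3)), samples=["c1", "k1", "k2"])
        meta = make_metadata(["c1"], ["k1", "k2"])
        with pytest.raises(ValueError, match=">= 2 samples"):
            moderated_t(profile, meta)

    def test_all_zero_variance_rejected(self):
        profile = make_profile(np.ones((4, 4)), samples=["c1", "c2", "k1", "k2"])
        meta = make_metadata(["c1", "c2"], ["k1", "k2"])
        with pytest.raises(ValueError, match="zero"):
            moderated_t(profile, meta)

    def test_trigamma_inverse_inverts_trigamma(self):
        from scipy.special import polygamma
        for x in (0.1, 0.9, 3.7, 42.0):
            assert trigamma_inverse(float(polygamma(1, x))) == pytest.approx(x, rel=1e-6)


class TestAdjustBH:
    def test_hand_computed_step_up(self):
        np.testing.assert_allclose(adjust_bh([0.01, 0.02, 0.03]),
                                   [0.03, 0.03, 0.03])

    def test_single_p_unchanged(self):
        np.testing.assert_allclose(adjust_bh([0.2]), [0.2])

    def test_all_ones_stay_ones(self):
        np.testing.assert_allclose(adjust_bh([1.0, 1.0, 1.0]), 1.0)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            adjust_bh([0.5, 1.5])

    @settings(derandomize=True, max_examples=50)
    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=30))
    def test_matches_statsmodels_and_oracle(self, pvals):
        from statsmodels.stats.multitest import multipletests

        mine = adjust_bh(pvals)
        _, sm_adj, _, _ = multipletests(pvals, method="fdr_bh")
        np.testing.assert_allclose(mine, sm_adj, atol=1e-12)
        np.testing.assert_allclose(mine, bh_step_up(pvals), atol=1e-12)

    @settings(derandomize=True, max_examples=50)
    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=20))
    def test_adjusted_never_below_raw(self, pvals):
        adj = adjust_bh(pvals)
        assert np.all(adj >= np.asarray(pvals) - 1e-15)


def position_tests(runs):
    """runs: list of (padj, direction) per consecutive position."""
    return [PositionTest(position=i + 1, t=0.0, p=p, padj=p, direction=d)
            for i, (p, d) in enumerate(runs)]


class TestCallClusters:
    def test_single_run(self):
        runs = [(1.0, "up")] * 9 + [(1e-5, "up")] * 11 + [(1.0, "up")] * 5
        clusters = call_clusters(position_tests(runs), alpha=0.001)
        assert len(clusters) == 1
        assert clusters[0].interval == (10, 20)
        assert clusters[0].direction == "up"

    def test_nothing_significant(self):
        assert call_clusters(position_tests([(0.5, "up")] * 10), alpha=0.001) == []

    def test_gap_rule(self):
        runs = ([(1e-5, "up")] * 4 + [(0.9, "up")] * 3 + [(1e-5, "up")] * 4)
        assert len(call_clusters(position_tests(runs), alpha=0.001, gap=0)) == 2
        assert len(call_clusters(position_tests(runs), alpha=0.001, gap=5)) == 1

    def test_opposing_directions_never_merge(self):
        runs = [(1e-5, "up")] * 3 + [(1e-5, "down")] * 3
        clusters = call_clusters(position_tests(runs), alpha=0.001, gap=10)
        assert [c.direction for c in clusters] == ["up", "down"]

    def test_labels_enumerate_left_to_right(self):
        runs = ([(1e-5, "up")] * 2 + [(0.9, "up")] * 2 + [(1e-5, "down")] * 2
                + [(0.9, "up")] * 2 + [(1e-5, "up")] * 2)
        clusters = call_clusters(position_tests(runs), alpha=0.001)
        assert [c.label for c in clusters] == ["1", "2", "3"]
        assert clusters[0].start < clusters[1].start < clusters[2].start

    def test_member_genes_positioned_inside_interval(self):
        order = GeneOrdering({g: i + 1 for i, g in enumerate("abcdef")}, 0.0)
        runs = [(1.0, "up")] * 2 + [(1e-5, "up")] * 3 + [(1.0, "up")]
        clusters = call_clusters(position_tests(runs), alpha=0.001, order=order)
        assert clusters[0].genes == {"c", "d", "e"}

    def test_min_padj_tracked(self):
        runs = [(1e-4, "up"), (1e-7, "up"), (5e-4, "up")]
        clusters = call_clusters(position_tests(runs), alpha=0.001)
        assert clusters[0].min_padj == 1e-7

    def test_bad_alpha_rejected(self):
        with pytest.raises(ValueError):
            call_clusters([], alpha=0.0)
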