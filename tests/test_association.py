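import numpy as np
import pandas as pd
import pytest

from hmcscan.association import (
    cluster_expression_summary,
    cluster_genes,
    coverage_expression_correlation,
    group_ttest,
    marked_vs_unmarked_test,
    one_way_anova,
    sample_similarity,
    set_membership,
    two_way_anova_tukey,
)
from oracles import ranksum_exact_p, spearman_by_definition, welch_t


class TestSampleSimilarity:
    def test_duplicated_columns_have_unit_offdiagonal(self):
        rng = np.random.default_rng(0)
        col = rng.random(30)
        cov = pd.DataFrame({"a": col, "b": col, "c": rng.random(30)})
        sim = sample_similarity(cov)
        assert sim.loc["a", "b"] == pytest.approx(1.0)
        assert np.allclose(np.diag(sim), 1.0)
        assert np.allclose(sim, sim.T)

    def test_reversed_ranks(self):
        cov = pd.DataFrame({"a": [1, 2, 3, 4.0], "b": [4, 3, 2, 1.0]})
        assert sample_similarity(cov).loc["a", "b"] == pytest.approx(-1.0)

    def test_matches_rank_then_pearson_oracle(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            x = rng.random(20)
            y = rng.random(20)
            cov = pd.DataFrame({"a": x, "b": y})
            got = sample_similarity(cov).loc["a", "b"]
            assert got == pytest.approx(spearman_by_definition(x, y), abs=1e-12)

    def test_requires_minimum_shape(self):
        with pytest.raises(ValueError):
            sample_similarity(pd.DataFrame({"a": [1, 2.0]}))


class TestWilcoxon:
    def test_fully_separated_small_groups(self):
        # {1,2,3} vs {4,5,6}: 1/20 one-sided arrangements -> two-sided 0.1
        vals = pd.Series([1, 2, 3, 4, 5, 6.0],
                         index=[f"g{i}" for i in range(6)])
        marked = pd.Series([True] * 3 + [False] * 3, index=vals.index)
        out = marked_vs_unmarked_test(vals, marked)
        assert out.loc["all", "p_value"] == pytest.approx(0.1)
        assert ranksum_exact_p([1, 2, 3], [4, 5, 6]) == pytest.approx(0.1)

    def test_identical_groups_null(self):
        vals = pd.Series(np.tile([1.0, 2.0, 3.0, 4.0], 2),
                         index=[f"g{i}" for i in range(8)])
        marked = pd.Series([True] * 4 + [False] * 4, index=vals.index)
        out = marked_vs_unmarked_test(vals, marked)
        assert out.loc["all", "p_value"] >= 0.99

    def test_matches_enumeration_oracle_small_samples(self):
        rng = np.random.default_rng(8)
        for _ in range(15):
            n1, n2 = int(rng.integers(2, 6)), int(rng.integers(2, 6))
            x = rng.normal(size=n1).round(2)
            y = rng.normal(size=n2).round(2)
            vals = pd.Series(np.concatenate([x, y]),
                             index=[f"g{i}" for i in range(n1 + n2)])
            marked = pd.Series([True] * n1 + [False] * n2, index=vals.index)
            got = marked_vs_unmarked_test(vals, marked).loc["all", "p_value"]
            # exact path engaged for n1+n2 <= 12; ties absent after rounding
            if len(np.unique(vals)) == len(vals):
                assert got == pytest.approx(ranksum_exact_p(x, y), abs=1e-9)

    def test_small_group_reported_untestable(self):
        vals = pd.Series([1.0, 2.0, 3.0], index=list("abc"))
        marked = pd.Series([True, False, False], index=vals.index)
        out = marked_vs_unmarked_test(vals, marked)
        assert not out.loc["all", "testable"]
        assert np.isnan(out.loc["all", "p_value"])


class TestClusterGenes:
    def test_separable_point_masses(self):
        lo = np.zeros((10, 8))
        hi = np.ones((12, 8))
        profiles = pd.DataFrame(np.vstack([hi, lo]),
                                index=[f"g{i}" for i in range(22)])
        ca = cluster_genes(profiles, k=2)
        # relabeled by ascending coverage: zeros -> C1, ones -> C2
        assert set(ca.labels.iloc[:12]) == {"C2"}
        assert set(ca.labels.iloc[12:]) == {"C1"}

    def test_deterministic_repeat(self):
        rng = np.random.default_rng(6)
        profiles = pd.DataFrame(rng.random((60, 10)),
                                index=[f"g{i}" for i in range(60)])
        a = cluster_genes(profiles, k=5).labels
        b = cluster_genes(profiles, k=5).labels
        assert (a == b).all()

    def test_planted_five_groups_recovered(self):
        rng = np.random.default_rng(12)
        means = [0.0, 0.2, 0.4, 0.7, 0.95]
        blocks, truth = [], []
        for ci, m in enumerate(means):
            block = np.clip(rng.normal(m, 0.03, size=(40, 12)), 0, 1)
            blocks.append(block)
            truth += [f"C{ci + 1}"] * 40
        profiles = pd.DataFrame(np.vstack(blocks),
                                index=[f"g{i}" for i in range(200)])
        ca = cluster_genes(profiles, k=5)
        agreement = (ca.labels.to_numpy() == np.array(truth)).mean()
        assert agreement >= 0.95

    def test_mean_coverage_strictly_increasing(self):
        rng = np.random.default_rng(77)
        profiles = pd.DataFrame(rng.random((100, 6)),
                                index=[f"g{i}" for i in range(100)])
        ca = cluster_genes(profiles, k=5)
        assert (ca.mean_coverage.loc[[f"C{i}" for i in range(1, 6)]]
                .diff().dropna() > 0).all()

    def test_k_exceeding_genes_errors(self):
        profiles = pd.DataFrame(np.ones((3, 4)))
        with pytest.raises(ValueError):
            cluster_genes(profiles, k=5)


class TestClusterExpressionSummary:
    def build_assignment(self, labels):
        from hmcscan.association import ClusterAssignment
        lab = pd.Series(labels)
        return ClusterAssignment(lab, lab.value_counts().sort_index(),
                                 pd.Series(dtype=float), pd.DataFrame())

    def test_flat_expression_zero_trend(self):
        labels = {f"g{i}": f"C{i % 5 + 1}" for i in range(50)}
        expr = pd.DataFrame({"s": np.ones(50)}, index=list(labels))
        out = cluster_expression_summary(self.build_assignment(labels), expr)
        assert out["trend_rho"] == pytest.approx(0.0, abs=1e-12) or \
            np.isnan(out["trend_rho"])

    def test_expression_equal_to_cluster_index(self):
        labels = {f"g{i}": f"C{i % 5 + 1}" for i in range(50)}
        expr = pd.DataFrame(
            {"s": [int(labels[g][1]) for g in labels]}, index=list(labels))
        out = cluster_expression_summary(self.build_assignment(labels), expr)
        assert out["trend_rho"] == pytest.approx(1.0)

    def test_trend_matches_definition_oracle(self):
        rng = np.random.default_rng(15)
        labels = {f"g{i}": f"C{rng.integers(1, 6)}" for i in range(80)}
        expr = pd.DataFrame(
            {"s": [int(labels[g][1]) * 0.5 + rng.normal(0, 1) for g in labels]},
            index=list(labels))
        out = cluster_expression_summary(self.build_assignment(labels), expr)
        want = spearman_by_definition(
            [int(labels[g][1]) for g in labels], expr["s"].to_list())
        assert out["trend_rho"] == pytest.approx(want, abs=0.1)


class TestSetMembership:
    def test_mitochondrial_brain_arithmetic(self):
        labels = {f"g{i}": ("C1" if i < 294 else "C3") for i in range(540)}
        st = set_membership(labels, list(labels), {"C1", "C2"})
        assert (st.count, st.size, st.percentage) == (294, 540, 54)

    def test_ribosomal_brain_arithmetic(self):
        labels = {f"g{i}": ("C2" if i < 78 else "C4") for i in range(126)}
        st = set_membership(labels, list(labels), {"C1", "C2"})
        assert (st.count, st.size, st.percentage) == (78, 126, 62)

    def test_empty_set(self):
        st = set_membership({}, [], {"C1"})
        assert (st.count, st.size, st.percentage) == (0, 0, 0)

    def test_partition_percentages_sum_to_about_100(self):
        rng = np.random.default_rng(10)
        labels = {f"g{i}": f"C{rng.integers(1, 6)}" for i in range(137)}
        pcts = [set_membership(labels, list(labels), {f"C{k}"}).percentage
                for k in range(1, 6)]
        assert abs(sum(pcts) - 100) <= 3  # rounding slack


class TestAnova:
    def test_two_groups_equals_squared_t(self):
        rng = np.random.default_rng(2)
        x, y = rng.normal(0, 1, 10), rng.normal(0.5, 1, 12)
        f, p_f = one_way_anova(x, y)
        from scipy.stats import ttest_ind
        t, p_t = ttest_ind(x, y, equal_var=True)
        assert f == pytest.approx(t ** 2)
        assert p_f == pytest.approx(p_t)

    def test_hand_computed_f(self):
        f, _ = one_way_anova([1, 2, 3], [2, 3, 4], [3, 4, 5])
        assert f == pytest.approx(3.0)

    def test_two_way_balanced_closed_form(self):
        # 2x2 balanced with pure additive effects: interaction SS ~ 0
        a = ["x"] * 4 + ["y"] * 4
        b = (["u"] * 2 + ["v"] * 2) * 2
        base = {"x": 0.0, "y": 2.0}
        add = {"u": 0.0, "v": 1.0}
        vals = [base[ai] + add[bi] + eps
                for ai, bi, eps in zip(a, b, [0.1, -0.1] * 4)]
        out = two_way_anova_tukey(vals, a, b)
        table = out["anova"]
        # main-effect sums of squares from marginal means: n/2 * diff^2 / 2
        assert table.loc["C(A)", "sum_sq"] == pytest.approx(8 * (2.0 / 2) ** 2)
        assert table.loc["C(B)", "sum_sq"] == pytest.approx(8 * (1.0 / 2) ** 2)
        assert table.loc["C(A):C(B)", "sum_sq"] == pytest.approx(0.0, abs=1e-12)
        assert len(out["tukey"]) == 6  # all cell pairs

    def test_requires_group_sizes(self):
        with pytest.raises(ValueError):
            one_way_anova([1.0], [2.0, 3.0])


class TestGroupTtest:
    def test_identical_groups(self):
        out = group_ttest([1, 2, 3.0], [1, 2, 3.0])
        assert out["t"] == pytest.approx(0.0)
        assert out["p_value"] == pytest.approx(1.0)

    def test_degenerate_variance_flagged(self):
        out = group_ttest([0, 0, 0, 0.0], [1, 1, 1, 1.0])
        assert out["degenerate"]
        assert out["p_value"] <= 1e-12

    def test_matches_welch_formula_oracle(self):
        rng = np.random.default_rng(44)
        for _ in range(20):
            x = rng.normal(0, 1, int(rng.integers(3, 20)))
            y = rng.normal(0.3, 2, int(rng.integers(3, 20)))
            out = group_ttest(x, y)
            t, p = welch_t(x, y)
            assert out["t"] == pytest.approx(t, abs=1e-10)
            assert out["p_value"] == pytest.approx(p, abs=1e-10)


def test_coverage_expression_correlation_perfect_link():
    rng = np.random.default_rng(3)
    cov = pd.DataFrame({"s1": rng.random(40)}, index=[f"g{i}" for i in range(40)])
    expr = pd.DataFrame({"s1_r1": 2 * cov["s1"] + 1, "s1_r2": 2 * cov["s1"] + 1})
    rho = coverage_expression_correlation(cov, expr, {"s1": ["s1_r1", "s1_r2"]})
    assert rho["s1"] == pytest.approx(1.0)
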