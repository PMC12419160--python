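"""Replicate-mean statistics: worked examples, closed forms, null behavior."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats as sps

import translocq as tq


def sample_from(rows):
    return tq.HierarchicalSample(
        pd.DataFrame(rows, columns=["group", "replicate", "cell", "value"])
    )


class TestReplicateSummaries:
    def test_replicate_means_worked_example(self):
        h = sample_from(
            [("a", 0, 0, 1.0), ("a", 0, 1, 3.0), ("a", 1, 0, 5.0)]
        )
        reps = tq.replicate_means(h)
        assert reps["mean"].tolist() == [2.0, 5.0]

    def test_single_cell_replicates_are_identity(self):
        h = sample_from([("a", 0, 0, 1.5), ("a", 1, 0, 2.5)])
        assert tq.replicate_means(h)["mean"].tolist() == [1.5, 2.5]

    def test_grand_mean_sem_worked_example(self):
        # replicate means {2, 4}: grand 3, sd = sqrt(2), sem = 1
        h = sample_from([("a", 0, 0, 2.0), ("a", 1, 0, 4.0)])
        out = tq.grand_mean_sem(h)
        assert out.loc[0, "grand_mean"] == pytest.approx(3.0)
        assert out.loc[0, "sem"] == pytest.approx(1.0)
        assert out.loc[0, "n_reps"] == 2

    def test_identical_replicates_have_zero_sem(self):
        h = sample_from([("a", 0, 0, 2.0), ("a", 1, 0, 2.0)])
        assert tq.grand_mean_sem(h).loc[0, "sem"] == 0.0

    def test_single_replicate_sem_undefined(self):
        h = sample_from([("a", 0, 0, 2.0)])
        with pytest.raises(ValueError, match="SEM"):
            tq.grand_mean_sem(h)


class TestTTests:
    def test_one_sample_symmetric_null(self):
        t, df, p = tq.one_sample_t([-1.0, 0.0, 1.0], 0.0)
        assert t == 0.0 and df == 2 and p == 1.0

    def test_one_sample_worked_example(self):
        t, df, p = tq.one_sample_t([1.0, 2.0, 3.0], 0.0)
        assert t == pytest.approx(2 * np.sqrt(3), rel=1e-12)
        assert df == 2
        assert p == pytest.approx(0.0742, abs=2e-4)

    def test_one_sample_degenerate_inputs(self):
        with pytest.raises(ValueError):
            tq.one_sample_t([1.0], 0.0)
        with pytest.raises(ValueError):
            tq.one_sample_t([2.0, 2.0, 2.0], 0.0)

    def test_one_sample_matches_scipy_to_high_precision(self):
        rng = np.random.default_rng(1)
        v = rng.normal(0.3, 1.0, 12)
        t, df, p = tq.one_sample_t(v, 0.1)
        ref = sps.ttest_1samp(v, 0.1)
        assert t == pytest.approx(ref.statistic, abs=1e-10)
        assert p == pytest.approx(ref.pvalue, abs=1e-10)

    def test_two_sample_worked_example_and_antisymmetry(self):
        t, df, p = tq.two_sample_t([1, 2, 3], [2, 3, 4])
        assert t == pytest.approx(-1.2247, abs=1e-4)
        assert df == 4
        t2, _, p2 = tq.two_sample_t([2, 3, 4], [1, 2, 3])
        assert t2 == pytest.approx(-t) and p2 == pytest.approx(p)

    def test_identical_groups_give_unit_p(self):
        t, _, p = tq.two_sample_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == 0.0 and p == 1.0

    def test_two_sample_matches_scipy(self):
        rng = np.random.default_rng(2)
        a, b = rng.normal(0, 1, 8), rng.normal(0.5, 2, 11)
        for welch in (False, True):
            t, _, p = tq.two_sample_t(a, b, welch=welch)
            ref = sps.ttest_ind(a, b, equal_var=not welch)
            assert t == pytest.approx(ref.statistic, abs=1e-10)
            assert p == pytest.approx(ref.pvalue, abs=1e-10)


class TestOneWayAnova:
    def test_identical_groups_give_zero_f(self):
        f, *_ = tq.one_way_anova([[1.0, 2.0], [1.0, 2.0], [1.0, 2.0]])
        assert f == 0.0

    def test_hand_computed_example(self):
        f, dfb, dfw, p, r2 = tq.one_way_anova([[1.0, 2.0], [4.0, 5.0]])
        assert f == pytest.approx(18.0)
        assert (dfb, dfw) == (1, 2)
        assert r2 == pytest.approx(9.0 / 10.0)

    def test_two_groups_reduce_to_t_squared(self):
        rng = np.random.default_rng(3)
        a, b = rng.normal(0, 1, 6), rng.normal(1, 1, 9)
        f, _, dfw, p_f, _ = tq.one_way_anova([a, b])
        t, df_t, p_t = tq.two_sample_t(a, b)
        assert f == pytest.approx(t**2, abs=1e-10)
        assert p_f == pytest.approx(p_t, abs=1e-10)

    def test_matches_scipy_f_oneway(self):
        rng = np.random.default_rng(4)
        groups = [rng.normal(m, 1, 7) for m in (0.0, 0.4, 1.0)]
        f, dfb, dfw, p, _ = tq.one_way_anova(groups)
        ref = sps.f_oneway(*groups)
        assert f == pytest.approx(ref.statistic, abs=1e-10)
        assert p == pytest.approx(ref.pvalue, abs=1e-10)

    def test_input_validation(self):
        with pytest.raises(ValueError):
            tq.one_way_anova([[1.0, 2.0]])
        with pytest.raises(ValueError):
            tq.one_way_anova([[1.0], []])


class TestSidak:
    def test_single_comparison_is_identity(self):
        assert tq.sidak_adjust([0.123], m=1)[0] == pytest.approx(0.123)

    def test_worked_example(self):
        assert tq.sidak_adjust([0.01], m=3)[0] == pytest.approx(0.029701, abs=1e-9)

    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=6))
    def test_bounds_and_monotonicity(self, ps):
        adj = tq.sidak_adjust(ps)
        ps = np.asarray(ps)
        assert np.all(adj >= ps - 1e-15)
        assert np.all(adj <= np.minimum(len(ps) * ps, 1.0) + 1e-12)
        order = np.argsort(ps)
        assert np.all(np.diff(adj[order]) >= -1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            tq.sidak_adjust([1.2])


class TestManyToOne:
    def test_reference_vs_itself_excluded_and_null_group_near_one(self):
        groups = [[1.0, 2.0, 3.0], [1.0, 2.0, 3.0], [10.0, 11.0, 12.0]]
        out = tq.many_to_one_comparisons(groups, reference_index=0)
        assert len(out) == 2
        assert out.loc[out["group"] == "group1", "p_adj"].iloc[0] > 0.95

    def test_single_comparison_reduces_to_pooled_t(self):
        a, b = [1.0, 2.0, 3.0], [2.0, 3.0, 4.0]
        out = tq.many_to_one_comparisons([a, b], reference_index=0)
        t_ref, _, p_ref = tq.two_sample_t(b, a)
        assert out["t"].iloc[0] == pytest.approx(t_ref, abs=1e-12)
        assert out["p_adj"].iloc[0] == pytest.approx(p_ref, abs=1e-12)

    def test_familywise_error_controlled_under_null(self):
        rng = np.random.default_rng(5)
        n_sims, hits = 2000, 0
        for _ in range(n_sims):
            groups = rng.normal(0.0, 1.0, size=(4, 4))
            out = tq.many_to_one_comparisons(list(groups), reference_index=0)
            hits += (out["p_adj"] < 0.05).any()
        rate = hits / n_sims
        assert rate <= 0.05 + 3 * np.sqrt(0.05 * 0.95 / n_sims)


class TestTwoWayAnova:
    @staticmethod
    def crossed(cell_means, sd, n, seed=0):
        rng = np.random.default_rng(seed)
        rows = []
        for i, a in enumerate(("a1", "a2")):
            for j, b in enumerate(("b1", "b2")):
                for v in cell_means[i][j] + rng.normal(0, sd, n):
                    rows.append((a, b, v))
        return pd.DataFrame(rows, columns=["factor_a", "factor_b", "value"])

    def test_no_effects_give_zero_f(self):
        table = self.crossed([[1.0, 1.0], [1.0, 1.0]], 0.0, 3)
        out = tq.two_way_anova_balanced(table)
        assert (out.loc[out["effect"] != "error", "F"] == 0.0).all()

    def test_pure_main_effect_without_noise_is_degenerate(self):
        table = self.crossed([[0.0, 0.0], [1.0, 1.0]], 0.0, 3)
        out = tq.two_way_anova_balanced(table).set_index("effect")
        assert np.isinf(out.loc["A", "F"])
        assert out.loc["B", "F"] == 0.0

    def test_matches_brute_force_sums_of_squares(self):
        table = self.crossed([[0.0, 0.5], [1.0, 2.5]], 1.0, 5, seed=6)
        out = tq.two_way_anova_balanced(table).set_index("effect")

        # brute force from cell/marginal means
        v = table.pivot_table(
            index="factor_a", columns="factor_b", values="value", aggfunc=list
        )
        cells = np.array([[np.array(v.iloc[i, j]) for j in range(2)] for i in range(2)])
        grand = cells.mean()
        a_m = cells.mean(axis=(1, 2))
        b_m = cells.mean(axis=(0, 2))
        c_m = cells.mean(axis=2)
        n = cells.shape[2]
        ss_a = n * 2 * ((a_m - grand) ** 2).sum()
        ss_b = n * 2 * ((b_m - grand) ** 2).sum()
        ss_ab = n * ((c_m - a_m[:, None] - b_m[None, :] + grand) ** 2).sum()
        ss_err = ((cells - c_m[:, :, None]) ** 2).sum()
        assert out.loc["A", "ss"] == pytest.approx(ss_a, rel=1e-10)
        assert out.loc["B", "ss"] == pytest.approx(ss_b, rel=1e-10)
        assert out.loc["AxB", "ss"] == pytest.approx(ss_ab, rel=1e-10)
        f_a = (ss_a / 1) / (ss_err / (4 * (n - 1)))
        assert out.loc["A", "F"] == pytest.approx(f_a, rel=1e-10)

    def test_unbalanced_design_rejected(self):
        table = self.crossed([[0.0, 0.0], [1.0, 1.0]], 1.0, 3)
        with pytest.raises(ValueError, match="balanced"):
            tq.two_way_anova_balanced(table.iloc[:-1])


class TestWilcoxon:
    def test_matches_scipy_exact(self):
        v = [1.2, -0.4, 2.3, 0.7, -1.1, 0.9, 1.5]
        w, p = tq.wilcoxon_signed_rank(v, 0.0)
        ref = sps.wilcoxon(v, mode="exact")
        assert w == ref.statistic and p == pytest.approx(ref.pvalue)

    def test_all_equal_to_mu0_rejected(self):
        with pytest.raises(ValueError):
            tq.wilcoxon_signed_rank([0.5, 0.5], 0.5)


def test_null_rejection_rate_seeded_and_sane():
    r1 = tq.anova_null_rejection_rate(4, 4, 10, 1.0, 2.0, n_sims=2000, seed=8)
    r2 = tq.anova_null_rejection_rate(4, 4, 10, 1.0, 2.0, n_sims=2000, seed=8)
    assert r1 == r2
    assert 0.03 < r1 < 0.07
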