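from itertools import combinations

import numpy as np
import pytest
from scipy import stats as sps

from nucleiquant import (
    GroupSamples,
    kruskal_wallis_dunn,
    mann_whitney_u,
    summarize_boxplot,
)
from nucleiquant.stack_model import PipelineError


def enumeration_oracle(x, y):
    """Exact two-sided Mann-Whitney p by brute force over label assignments.

    U is computed by directly counting pairs (x_i, y_j) with x_i > y_j —
    deliberately not the rank-sum formula used by the implementation.
    """

    def u_stat(a, b):
        return sum(1 for ai in a for bj in b if ai > bj)

    u_obs = min(u_stat(x, y), u_stat(y, x))
    pooled = list(x) + list(y)
    n1 = len(x)
    hits = total = 0
    for idx in combinations(range(len(pooled)), n1):
        a = [pooled[i] for i in idx]
        b = [pooled[i] for i in range(len(pooled)) if i not in idx]
        if min(u_stat(a, b), u_stat(b, a)) <= u_obs:
            hits += 1
        total += 1
    return u_obs, hits / total


class TestMannWhitney:
    def test_fully_separated_toy_groups(self):
        res = mann_whitney_u(GroupSamples("x", (1, 2, 3)), GroupSamples("y", (4, 5, 6)))
        assert res.u == 0
        assert res.method == "exact"
        assert res.p_value == pytest.approx(0.1)  # 2 of C(6,3)=20 assignments

    def test_interleaved_groups_match_enumeration(self):
        x, y = (1, 3, 5), (2, 4, 6)
        res = mann_whitney_u(GroupSamples("x", x), GroupSamples("y", y))
        u_oracle, p_oracle = enumeration_oracle(x, y)
        assert res.u == u_oracle
        assert res.p_value == pytest.approx(p_oracle)

    def test_identical_groups_give_p_one(self):
        g = GroupSamples("x", (3, 1, 4, 1, 5))
        res = mann_whitney_u(g, GroupSamples("y", (3, 1, 4, 1, 5)))
        assert res.p_value == pytest.approx(1.0)

    def test_symmetry_under_group_swap(self):
        x = GroupSamples("x", (1, 4, 6, 9))
        y = GroupSamples("y", (2, 3, 8))
        a = mann_whitney_u(x, y)
        b = mann_whitney_u(y, x)
        assert a.p_value == b.p_value
        assert (a.u1, a.u2) == (b.u2, b.u1)

    def test_exact_branch_matches_scipy(self):
        rng = np.random.default_rng(11)
        for _ in range(10):
            vals = rng.choice(1000, size=12, replace=False)
            x, y = vals[:6], vals[6:]
            res = mann_whitney_u(GroupSamples("x", x), GroupSamples("y", y))
            ref = sps.mannwhitneyu(x, y, alternative="two-sided", method="exact")
            assert res.p_value == pytest.approx(ref.pvalue)

    def test_approximation_close_to_exact_for_n8(self):
        rng = np.random.default_rng(5)
        worst = 0.0
        for _ in range(20):
            vals = rng.choice(10_000, size=16, replace=False)
            x, y = vals[:8], vals[8:]
            exact = mann_whitney_u(GroupSamples("x", x), GroupSamples("y", y))
            assert exact.method == "exact"
            approx = sps.mannwhitneyu(
                x, y, alternative="two-sided", method="asymptotic"
            )
            worst = max(worst, abs(exact.p_value - approx.pvalue))
        assert worst < 0.05

    def test_empty_group_rejected(self):
        with pytest.raises(PipelineError):
            GroupSamples("empty", ())


def kruskal_h_oracle(groups):
    """H from the rank formula, no tie correction (inputs must be tie-free)."""
    pooled = np.concatenate(groups)
    ranks = sps.rankdata(pooled)
    n = len(pooled)
    offset, h = 0, 0.0
    for g in groups:
        r = ranks[offset : offset + len(g)]
        h += r.sum() ** 2 / len(g)
        offset += len(g)
    return 12.0 / (n * (n + 1)) * h - 3 * (n + 1)


class TestKruskalWallisDunn:
    def test_identical_groups_h_zero_p_one(self):
        groups = [GroupSamples(str(i), (5, 5, 5)) for i in range(3)]
        res = kruskal_wallis_dunn(groups)
        assert res.h_statistic == pytest.approx(0.0)
        assert (res.pairwise["p_adjusted"] == 1.0).all()

    def test_fully_separated_groups_match_rank_formula(self):
        samples = [(1, 2, 3), (11, 12, 13), (21, 22, 23)]
        groups = [GroupSamples(str(i), s) for i, s in enumerate(samples)]
        res = kruskal_wallis_dunn(groups)
        assert res.h_statistic == pytest.approx(kruskal_h_oracle(samples))

    def test_two_groups_redirected_to_mann_whitney(self):
        with pytest.raises(PipelineError, match="mann_whitney"):
            kruskal_wallis_dunn(
                [GroupSamples("a", (1, 2)), GroupSamples("b", (3, 4))]
            )

    def test_bonferroni_scales_raw_p(self):
        rng = np.random.default_rng(3)
        groups = [
            GroupSamples(str(i), tuple(rng.normal(i, 1, size=6))) for i in range(3)
        ]
        res = kruskal_wallis_dunn(groups, adjustment="bonferroni")
        raw = kruskal_wallis_dunn(groups, adjustment="none").pairwise["p_raw"]
        expected = np.minimum(1.0, raw * len(res.pairwise))
        assert np.allclose(res.pairwise["p_adjusted"], expected)

    def test_monotone_with_mann_whitney_on_two_of_the_groups(self):
        # the Dunn z for a pair orders like the Mann-Whitney evidence
        a, b = (1, 2, 3, 4), (6, 7, 8, 9)
        c = (20, 21, 22, 23)
        res = kruskal_wallis_dunn(
            [GroupSamples("a", a), GroupSamples("b", b), GroupSamples("c", c)]
        )
        mw_ab = mann_whitney_u(GroupSamples("a", a), GroupSamples("b", b))
        mw_ac = mann_whitney_u(GroupSamples("a", a), GroupSamples("c", c))
        table = res.pairwise.set_index(["group_a", "group_b"])
        z_ab = abs(table.loc[("a", "b"), "z"])
        z_ac = abs(table.loc[("a", "c"), "z"])
        assert (z_ac > z_ab) == (mw_ac.u < mw_ab.u or mw_ac.p_value <= mw_ab.p_value)


class TestBoxplotSummary:
    def test_simple_group_quartiles(self):
        table = summarize_boxplot([GroupSamples("g", (1, 2, 3, 4, 5))])
        row = table.iloc[0]
        assert row["median"] == 3 and row["mean"] == 3
        assert row["q1"] == 2 and row["q3"] == 4  # linear interpolation
        assert row["lower_whisker"] == 1 and row["upper_whisker"] == 5

    def test_single_value_group_zero_width_box(self):
        row = summarize_boxplot([GroupSamples("g", (7,))]).iloc[0]
        assert row["median"] == row["mean"] == 7
        assert row["iqr"] == 0

    def test_outliers_beyond_tukey_whiskers(self):
        row = summarize_boxplot([GroupSamples("g", (1, 2, 3, 4, 100))]).iloc[0]
        assert row["n_outliers"] == 1
        assert row["upper_whisker"] == 4

    def test_figure_and_table_written(self, tmp_path):
        out = tmp_path / "box.png"
        table = summarize_boxplot(
            [GroupSamples("a", (1, 2, 3)), GroupSamples("b", (4, 5, 6))], out
        )
        assert out.exists() and len(table) == 2
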