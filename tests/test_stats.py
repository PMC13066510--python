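"""Routed comparisons, exact categorical tests, bootstrap, Dunn post hoc."""

import itertools
import math

import numpy as np
import pytest
from scipy import stats as sps

from airway4d.stats import (StatsError, bootstrap_ci, comparison_tables,
                            delta_d_correlation, fisher_exact_rxc, kruskal_dunn,
                            route_and_compare)


# --------------------------------------------------------------------------
# independent brute-force oracle for the exact r x c test
# --------------------------------------------------------------------------

def _brute_force_fisher(table):
    """Exhaustive enumeration via direct product over cell ranges."""
    t = np.asarray(table, dtype=int)
    rows, cols = t.sum(axis=1), t.sum(axis=0)
    n = t.sum()

    def log_prob(m):
        lp = sum(math.lgamma(r + 1) for r in rows)
        lp += sum(math.lgamma(c + 1) for c in cols)
        lp -= math.lgamma(n + 1)
        lp -= sum(math.lgamma(v + 1) for v in m.ravel())
        return lp

    obs = log_prob(t)
    free = [(i, j) for i in range(t.shape[0] - 1) for j in range(t.shape[1] - 1)]
    ranges = [range(min(rows[i], cols[j]) + 1) for i, j in free]
    total = 0.0
    for combo in itertools.product(*ranges):
        m = np.zeros_like(t)
        for (i, j), v in zip(free, combo):
            m[i, j] = v
        m[:-1, -1] = rows[:-1] - m[:-1, :-1].sum(axis=1)
        m[-1, :] = cols - m[:-1, :].sum(axis=0)
        if (m >= 0).all():
            lp = log_prob(m)
            if lp <= obs + 1e-12:
                total += math.exp(lp)
    return min(total, 1.0)


class TestFisherExact:
    def test_2x2_matches_scipy(self):
        table = [[3, 1], [1, 3]]
        p = fisher_exact_rxc(table)
        assert p == pytest.approx(sps.fisher_exact(table)[1], abs=1e-12)
        assert p == pytest.approx(0.485714285714, abs=1e-9)

    def test_random_2x2_tables_match_scipy(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            table = rng.integers(0, 8, size=(2, 2))
            if table.sum() == 0:
                continue
            assert fisher_exact_rxc(table) == pytest.approx(
                sps.fisher_exact(table)[1], abs=1e-10)

    @pytest.mark.parametrize("table", [
        [[2, 3, 1], [4, 0, 2]],
        [[5, 1], [2, 4], [0, 3]],
        [[1, 2, 3], [3, 2, 1], [2, 2, 2]],
    ])
    def test_rxc_matches_brute_force(self, table):
        assert fisher_exact_rxc(table) == pytest.approx(
            _brute_force_fisher(table), abs=1e-10)

    def test_independent_table_p_one(self):
        assert fisher_exact_rxc([[2, 2], [2, 2]]) == pytest.approx(1.0)

    def test_monte_carlo_agrees_with_enumeration(self):
        table = [[8, 3, 2], [4, 6, 5]]
        exact = fisher_exact_rxc(table)
        approx = fisher_exact_rxc(table, max_tables=1, monte_carlo=True,
                                  n_draws=20_000, seed=0)
        assert approx == pytest.approx(exact, abs=0.01)

    def test_enumeration_limit_raises_without_flag(self):
        big = (np.ones((4, 4), dtype=int) * 40).tolist()
        with pytest.raises(StatsError, match="enumeration limit"):
            fisher_exact_rxc(big, max_tables=10)

    def test_input_validation(self):
        with pytest.raises(StatsError):
            fisher_exact_rxc([[1, -2], [3, 4]])
        with pytest.raises(StatsError, match="empty"):
            fisher_exact_rxc([[0, 0], [0, 0]])


class TestRouting:
    def test_normal_equal_variance_student_t(self):
        rng = np.random.default_rng(2)
        x, y = rng.normal(0, 1, 30), rng.normal(0.5, 1, 30)
        res = route_and_compare(x, y, paired=False)
        assert res.test_name == "student_t"
        assert res.p_value == pytest.approx(sps.ttest_ind(x, y).pvalue)
        assert res.ci_method == "t_based"
        assert res.ci95[0] <= res.effect <= res.ci95[1]

    def test_normal_unequal_variance_welch(self):
        rng = np.random.default_rng(2)
        x, y = rng.normal(0, 0.3, 40), rng.normal(0, 4.0, 40)
        res = route_and_compare(x, y, paired=False)
        assert res.test_name == "welch_t"
        assert res.routing_trace.equal_variance is False

    def test_non_normal_mann_whitney(self):
        rng = np.random.default_rng(3)
        x, y = rng.exponential(1.0, 40), rng.exponential(2.0, 40)
        res = route_and_compare(x, y, paired=False)
        assert res.test_name == "mann_whitney_u"
        assert res.p_value == pytest.approx(
            sps.mannwhitneyu(x, y, alternative="two-sided").pvalue)
        assert res.ci_method == "percentile_bootstrap"

    def test_paired_normal_t(self):
        rng = np.random.default_rng(4)
        x = rng.normal(0, 1, 25)
        y = x + rng.normal(0.3, 0.2, 25)
        res = route_and_compare(x, y, paired=True)
        assert res.test_name == "paired_t"
        assert res.p_value == pytest.approx(sps.ttest_rel(x, y).pvalue)
        assert res.effect == pytest.approx(float(np.mean(x - y)))

    def test_paired_non_normal_wilcoxon(self):
        rng = np.random.default_rng(5)
        x = rng.normal(0, 1, 40)
        y = x + rng.exponential(0.5, 40) ** 3
        res = route_and_compare(x, y, paired=True)
        assert res.test_name == "wilcoxon_signed_rank"
        assert "Wilcoxon" in res.routing_trace.note

    def test_constant_difference_degenerate(self):
        x = np.arange(10.0)
        res = route_and_compare(x, x + 1.0, paired=True)
        assert res.p_value == 1.0 and res.effect == pytest.approx(-1.0)

    def test_sample_size_guards(self):
        with pytest.raises(StatsError):
            route_and_compare([1, 2], [3, 4, 5], paired=False)
        with pytest.raises(StatsError, match="equal length"):
            route_and_compare([1, 2, 3], [1, 2, 3, 4], paired=True)


class TestBootstrap:
    def test_deterministic_given_seed(self):
        x = np.random.default_rng(0).normal(size=30)
        a = bootstrap_ci(x, np.mean, seed=7, n_resamples=500)
        b = bootstrap_ci(x, np.mean, seed=7, n_resamples=500)
        assert a == b
        c = bootstrap_ci(x, np.mean, seed=8, n_resamples=500)
        assert a != c

    def test_shift_equivariance(self):
        x = np.random.default_rng(1).normal(size=40)
        lo, hi = bootstrap_ci(x, np.mean, seed=0, n_resamples=2000)
        lo2, hi2 = bootstrap_ci(x + 10.0, np.mean, seed=0, n_resamples=2000)
        assert lo2 == pytest.approx(lo + 10.0, abs=1e-9)
        assert hi2 == pytest.approx(hi + 10.0, abs=1e-9)

    def test_paired_mode_keeps_pairs(self):
        x = np.arange(20.0)
        y = x - 2.0                       # constant pairwise difference
        lo, hi = bootstrap_ci(x, lambda a, b, axis=-1: np.median(a - b, axis=axis),
                              y=y, mode="paired", seed=0, n_resamples=200)
        assert lo == pytest.approx(2.0) and hi == pytest.approx(2.0)

    def test_mode_and_input_guards(self):
        x = np.arange(10.0)
        with pytest.raises(StatsError):
            bootstrap_ci(x, np.mean, mode="bogus")
        with pytest.raises(StatsError):
            bootstrap_ci(np.array([1.0]), np.mean)
        with pytest.raises(StatsError):
            bootstrap_ci(x, np.mean, y=np.arange(5.0), mode="paired")


class TestKruskalDunn:
    def test_matches_scipy_kw(self):
        groups = [[1, 2, 3, 4], [2, 3, 4, 5], [8, 9, 10, 11]]
        kw_p, _ = kruskal_dunn(groups)
        assert kw_p == pytest.approx(sps.kruskal(*groups).pvalue)

    def test_hand_computed_dunn_oracle(self):
        # groups [1,2], [3,4], [5,6]: mean ranks 1.5/3.5/5.5, no ties,
        # se = sqrt((6*7/12)*(1/2+1/2)) = sqrt(3.5); pair (0,2): z = -4/se
        _, pairs = kruskal_dunn([[1, 2], [3, 4], [5, 6]])
        z = 4.0 / math.sqrt(3.5)
        expected = min(1.0, 3 * 2 * sps.norm.sf(z))
        assert pairs[(0, 2)] == pytest.approx(expected)

    def test_identical_groups_adjusted_to_one(self):
        _, pairs = kruskal_dunn([[1, 2, 3]] * 3)
        assert all(p == 1.0 for p in pairs.values())

    def test_group_guards(self):
        with pytest.raises(StatsError, match=">= 3"):
            kruskal_dunn([[1, 2], [3, 4]])
        with pytest.raises(StatsError, match="two observations"):
            kruskal_dunn([[1], [2, 3], [4, 5]])


class TestCorrelation:
    def test_pearson_on_linear_normal(self):
        rng = np.random.default_rng(6)
        x = rng.normal(17, 4, 60)
        y = 0.5 * x + rng.normal(0, 0.8, 60)
        res = delta_d_correlation(x, y)
        assert res.method == "pearson"
        r, p = sps.pearsonr(x, y)
        assert res.coefficient == pytest.approx(r)
        assert res.ci95[0] <= res.coefficient <= res.ci95[1]

    def test_spearman_on_non_normal_monotone(self):
        rng = np.random.default_rng(7)
        x = rng.exponential(1.0, 50)
        y = np.exp(x)
        res = delta_d_correlation(x, y, n_resamples=500)
        assert res.method == "spearman"
        assert res.coefficient == pytest.approx(1.0)

    def test_constant_input_undefined(self):
        res = delta_d_correlation([1.0] * 10, np.arange(10.0))
        assert res.undefined and math.isnan(res.coefficient)

    def test_length_guards(self):
        with pytest.raises(StatsError):
            delta_d_correlation([1, 2, 3], [1, 2, 3, 4])
        with pytest.raises(StatsError, match="four"):
            delta_d_correlation([1, 2, 3], [1, 2, 3])


class TestComparisonTables:
    def test_battery_layout_and_paired_effect_sign(self):
        import pandas as pd
        rng = np.random.default_rng(8)
        n = 24
        rows = []
        for i in range(n):
            sex = "male" if i < 8 else "female"
            sympt = i % 2 == 0
            base = rng.normal(7.0, 0.5)
            for pos in ("closed", "open"):
                length = base + (0.5 if pos == "open" else 0.0) + rng.normal(0, 0.1)
                row = {"participant": f"P{i:03d}", "position": pos, "sex": sex,
                       "symptomatic": sympt, "osa_excluded": False}
                for m in ("total_length_cm", "epiglottic_length_cm",
                          "total_volume_cm3", "epiglottic_volume_cm3",
                          "mean_csa_cm2", "retropalatal_csa_cm2",
                          "retroglossal_csa_cm2"):
                    row[m] = length if m == "total_length_cm" else rng.normal(3, 0.3)
                    row[f"{m}_cv"] = abs(rng.normal(0.05, 0.01))
                rows.append(row)
        df = pd.DataFrame(rows)
        out = comparison_tables(df, n_resamples=200, seed=0)
        assert set(out["contrast"]) == {"open_vs_closed", "male_vs_female",
                                        "symptomatic_vs_asymptomatic"}
        # 12 metrics x (1 paired + 2 contrasts x 2 positions)
        assert len(out) == 12 * 5
        paired = out[(out["metric"] == "total_length_cm")
                     & (out["contrast"] == "open_vs_closed")].iloc[0]
        assert paired["effect"] > 0 and paired["p_value"] < 0.05
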