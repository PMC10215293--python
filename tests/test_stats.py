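"""Group-delta statistical framework: deltas, tests, corrections, power."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as spstats

from nfx.stats import (
    anova_connectivity,
    baseline_homogeneity,
    bonferroni_adjust,
    compute_deltas,
    correlation_matrix,
    delta_contrasts,
    effect_size_d,
    holm_adjust,
    mannwhitney_contrast,
    normality_gate,
    posthoc_power,
)
from conftest import brute_force_holm


def _tidy(entries):
    return pd.DataFrame(entries, columns=["subject_id", "group", "session", "variable", "value"])


class TestComputeDeltas:
    def test_post_minus_pre(self):
        table = _tidy([("s1", "EMS", "pre", "x", 10.0), ("s1", "EMS", "post", "x", 12.0)])
        deltas, missing = compute_deltas(table)
        assert deltas["delta"].iloc[0] == pytest.approx(2.0)
        assert missing == 0

    def test_equal_sessions_give_zero(self):
        table = _tidy([("s1", "EMS", "pre", "x", 5.0), ("s1", "EMS", "post", "x", 5.0)])
        assert compute_deltas(table)[0]["delta"].iloc[0] == 0.0

    def test_missing_session_logged_not_raised(self):
        table = _tidy([("s1", "EMS", "pre", "x", 5.0), ("s2", "EMS", "post", "x", 6.0)])
        deltas, missing = compute_deltas(table)
        assert deltas.empty
        assert missing == 2


class TestNormalityGate:
    def test_gaussian_sample_passes(self):
        # Oracle: scipy.shapiro on this fixed draw gives p > 0.05.
        values = np.random.default_rng(3).standard_normal(50)
        assert spstats.shapiro(values).pvalue > 0.05
        assert normality_gate(values)["normal"]

    def test_heavy_tailed_sample_fails(self):
        values = np.random.default_rng(4).standard_cauchy(50)
        assert spstats.shapiro(values).pvalue < 0.05
        assert not normality_gate(values)["normal"]

    def test_constant_vector_is_degenerate(self):
        out = normality_gate(np.full(10, 2.0))
        assert out["degenerate"] and not out["normal"]


class TestMannWhitney:
    def test_full_separation_attains_enumeration_minimum(self):
        # Exhaustive oracle: all C(6,3)=20 equally likely rank assignments;
        # U=0 occurs once per tail, so the two-sided exact p is 2/20.
        a, b = np.array([1.0, 2, 3]), np.array([10.0, 11, 12])
        ranks = list(range(6))
        u_obs = 0
        count_extreme = 0
        for combo in combinations(ranks, 3):
            u = sum(r for r in combo) - 3 * 2 / 2  # rank-sum minus min
            count_extreme += min(u, 9 - u) <= u_obs
        p_exact = count_extreme / 20
        p, direction, tie = mannwhitney_contrast(a, b)
        assert p == pytest.approx(p_exact)
        assert direction == -1 and not tie

    def test_identical_samples_give_p_one(self):
        p, direction, tie = mannwhitney_contrast(np.ones(5), np.ones(5))
        assert p == 1.0 and tie and direction == 0

    def test_large_shift_is_overwhelming(self, rng):
        a = rng.normal(10, 1, 15)
        b = rng.normal(0, 1, 14)
        p, direction, _ = mannwhitney_contrast(a, b)
        assert p < 0.001 and direction == 1

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_invariant_under_monotone_transforms(self, seed):
        r = np.random.default_rng(seed)
        a, b = r.normal(0, 1, 8), r.normal(0.5, 1, 9)
        p1, _, _ = mannwhitney_contrast(a, b)
        p2, _, _ = mannwhitney_contrast(np.exp(a), np.exp(b))
        assert p1 == pytest.approx(p2, rel=1e-12)


class TestHolm:
    def test_two_value_hand_example(self):
        assert holm_adjust([0.01, 0.04]) == pytest.approx([0.02, 0.04])

    def test_single_p_unchanged(self):
        assert holm_adjust([0.3]) == pytest.approx([0.3])

    def test_equal_halves_cap_at_one(self):
        assert holm_adjust([0.5, 0.5, 0.5]) == pytest.approx([1.0, 1.0, 1.0])

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=10))
    def test_matches_brute_force_and_is_sandwiched(self, ps):
        adj = holm_adjust(ps)
        assert adj == pytest.approx(brute_force_holm(ps), abs=1e-12)
        assert np.all(adj >= np.asarray(ps) - 1e-12)
        assert np.all(adj <= bonferroni_adjust(ps) + 1e-12)

    def test_matches_statsmodels(self, rng):
        from statsmodels.stats.multitest import multipletests

        ps = rng.uniform(size=8)
        assert holm_adjust(ps) == pytest.approx(multipletests(ps, method="holm")[1], abs=1e-12)

    def test_order_preserving(self, rng):
        ps = np.sort(rng.uniform(size=6))
        adj = holm_adjust(ps)
        assert np.all(np.diff(adj) >= -1e-12)


class TestEffectSizeAndPower:
    def test_unit_gap_unit_sd_gives_d_one(self):
        a = np.array([-1.0, 0.0, 1.0])
        b = a + 1.0
        d, flag = effect_size_d(a, b)
        assert d == pytest.approx(1.0)
        assert not flag

    def test_identical_samples_give_zero(self, rng):
        a = rng.normal(size=10)
        assert effect_size_d(a, a.copy())[0] == 0.0

    def test_matches_hand_formula(self, rng):
        a, b = rng.normal(0, 2, 12), rng.normal(1, 3, 9)
        sp = np.sqrt(((11) * a.var(ddof=1) + 8 * b.var(ddof=1)) / 19)
        assert effect_size_d(a, b)[0] == pytest.approx(abs(a.mean() - b.mean()) / sp, abs=1e-12)

    def test_matches_pingouin(self, rng):
        import pingouin as pg

        a, b = rng.normal(0, 1, 15), rng.normal(0.7, 1, 14)
        assert effect_size_d(a, b)[0] == pytest.approx(
            abs(pg.compute_effsize(a, b, eftype="cohen")), abs=1e-10
        )

    def test_zero_pooled_sd_flagged(self):
        d, flag = effect_size_d(np.ones(5), np.full(5, 2.0))
        assert np.isnan(d) and flag

    def test_null_power_equals_alpha(self):
        assert posthoc_power(0.0, 15, 14, 0.05) == pytest.approx(0.05, abs=1e-9)

    def test_huge_effect_power_saturates(self):
        assert posthoc_power(5.0, 15, 14) > 0.999

    def test_power_matches_monte_carlo_t_test(self, rng):
        d, n1, n2 = 1.0, 15, 14
        reps = 10_000
        a = rng.standard_normal((reps, n1)) + d
        b = rng.standard_normal((reps, n2))
        p = spstats.ttest_ind(a, b, axis=1).pvalue
        assert posthoc_power(d, n1, n2) == pytest.approx((p <= 0.05).mean(), abs=0.02)


class TestBaselineHomogeneity:
    @staticmethod
    def _table(groups):
        rows = []
        for gname, values in groups.items():
            for i, v in enumerate(values):
                rows.append((f"{gname}{i}", gname, "pre", "x", v))
        return _tidy(rows)

    def test_common_distribution_not_excluded(self, rng):
        table = self._table({g: rng.normal(0, 1, 15) for g in ("EMS", "hypoxia", "control")})
        assert not baseline_homogeneity(table, "x")["excluded"]

    def test_five_sigma_shift_excluded(self, rng):
        table = self._table({
            "EMS": rng.normal(5, 1, 15), "hypoxia": rng.normal(0, 1, 15),
            "control": rng.normal(0, 1, 15),
        })
        assert baseline_homogeneity(table, "x")["excluded"]

    def test_identical_constants_degenerate_but_not_excluded(self):
        table = self._table({g: np.full(5, 1.0) for g in ("EMS", "hypoxia", "control")})
        out = baseline_homogeneity(table, "x")
        assert out["degenerate"] and not out["excluded"]

    def test_small_group_is_insufficient(self, rng):
        table = self._table({"EMS": rng.normal(0, 1, 2), "hypoxia": rng.normal(0, 1, 5),
                             "control": rng.normal(0, 1, 5)})
        assert baseline_homogeneity(table, "x")["verdict"] == "insufficient"


class TestCorrelations:
    @staticmethod
    def _table_xy(x, y):
        rows = []
        for i, (a, b) in enumerate(zip(x, y)):
            rows.append((f"s{i}", "EMS", "pre", "x", a))
            rows.append((f"s{i}", "EMS", "pre", "y", b))
        return _tidy(rows)

    def test_monotone_identity(self, rng):
        x = rng.normal(size=20)
        out = correlation_matrix(self._table_xy(x, x + 1), ["x", "y"])
        row = out.query("var_a == 'x' and var_b == 'y'").iloc[0]
        assert row.spearman_rho == pytest.approx(1.0)
        assert row.kendall_tau == pytest.approx(1.0)

    def test_decreasing_cubic_is_rank_perfect(self, rng):
        x = rng.normal(size=20)
        out = correlation_matrix(self._table_xy(x, -(x**3)), ["x", "y"])
        assert out.query("var_a == 'x' and var_b == 'y'").spearman_rho.iloc[0] == pytest.approx(-1.0)

    def test_matches_rank_formula_oracle(self, rng):
        x, y = rng.normal(size=25), rng.normal(size=25)
        out = correlation_matrix(self._table_xy(x, y), ["x", "y"])
        rx = spstats.rankdata(x)
        ry = spstats.rankdata(y)
        rho_oracle = np.corrcoef(rx, ry)[0, 1]
        assert out.query("var_a == 'x' and var_b == 'y'").spearman_rho.iloc[0] == pytest.approx(
            rho_oracle, abs=1e-12
        )

    def test_constant_variable_flagged(self, rng):
        out = correlation_matrix(self._table_xy(np.ones(10), rng.normal(size=10)), ["x", "y"])
        assert out.query("var_a == 'x' and var_b == 'y'").degenerate.iloc[0]


class TestAnova:
    def test_shifted_group_detected(self, rng):
        groups = [rng.normal(0, 1, 15), rng.normal(0, 1, 15), rng.normal(3, 1, 15)]
        f, p, degen = anova_connectivity(groups)
        assert p < 0.01 and not degen

    def test_null_f_statistic_is_calibrated(self, rng):
        ps = [anova_connectivity([rng.normal(0, 1, 10) for _ in range(3)])[1] for _ in range(200)]
        assert 0.2 < np.mean(ps) < 0.8  # roughly uniform null p-values

    def test_distinct_constants_flag_infinite_f(self):
        f, p, degen = anova_connectivity([np.ones(5), np.full(5, 2.0)])
        assert np.isinf(f) and p == 0.0 and degen


class TestDeltaContrastPipeline:
    def test_planted_variable_flagged_and_nulls_quiet(self, rng):
        rows = []
        for v in range(6):
            shift = 2.0 if v == 0 else 0.0
            for i in range(15):
                rows.append((f"e{i}", "EMS", f"v{v}", rng.normal(shift, 1)))
            for i in range(14):
                rows.append((f"c{i}", "control", f"v{v}", rng.normal(0, 1)))
        deltas = pd.DataFrame(rows, columns=["subject_id", "group", "variable", "delta"])
        out = delta_contrasts(deltas)
        sig = out[out.significant]
        assert list(sig.variable) == ["v0"]
        assert sig.direction.iloc[0] == "Increase"
        assert (out.adjusted_p >= out.raw_p - 1e-12).all()
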