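import math

import numpy as np
import pandas as pd
import pytest
import sympy

from anclick import stats as anstats


# ---------------------------------------------------------------------------
# independent oracle: partitioned sums of squares by explicit enumeration

def oracle_rm2_F(y):
    """Two-way within ANOVA F values by brute-force enumeration: every SS is
    a plain Python sum over observations of squared deviations between nested
    cell means. Returns (F_A, F_B, F_AB)."""
    n, a, b = y.shape
    obs = [(i, j, k, y[i, j, k]) for i in range(n) for j in range(a) for k in range(b)]
    grand = sum(v for *_, v in obs) / len(obs)

    def mean(cond):
        vals = [v for i, j, k, v in obs if cond(i, j, k)]
        return sum(vals) / len(vals)

    ss_a = sum((mean(lambda i, jj, k, j=j: jj == j) - grand) ** 2 for j in range(a)) * n * b
    ss_b = sum((mean(lambda i, j, kk, k=k: kk == k) - grand) ** 2 for k in range(b)) * n * a
    ss_ab = sum(
        (
            mean(lambda i, jj, kk, j=j, k=k: jj == j and kk == k)
            - mean(lambda i, jj, kk, j=j: jj == j)
            - mean(lambda i, jj, kk, k=k: kk == k)
            + grand
        )
        ** 2
        for j in range(a)
        for k in range(b)
    ) * n
    ss_as = sum(
        (
            mean(lambda ii, jj, k, i=i, j=j: ii == i and jj == j)
            - mean(lambda ii, jj, k, i=i: ii == i)
            - mean(lambda i, jj, k, j=j: jj == j)
            + grand
        )
        ** 2
        for i in range(n)
        for j in range(a)
    ) * b
    ss_bs = sum(
        (
            mean(lambda ii, j, kk, i=i, k=k: ii == i and kk == k)
            - mean(lambda ii, j, kk, i=i: ii == i)
            - mean(lambda i, j, kk, k=k: kk == k)
            + grand
        )
        ** 2
        for i in range(n)
        for k in range(b)
    ) * a
    ss_abs = sum(
        (
            y[i, j, k]
            - mean(lambda ii, jj, kk, i=i, j=j: ii == i and jj == j)
            - mean(lambda ii, jj, kk, i=i, k=k: ii == i and kk == k)
            - mean(lambda ii, jj, kk, j=j, k=k: jj == j and kk == k)
            + mean(lambda ii, jj, kk, i=i: ii == i)
            + mean(lambda ii, jj, kk, j=j: jj == j)
            + mean(lambda ii, jj, kk, k=k: kk == k)
            - grand
        )
        ** 2
        for i in range(n)
        for j in range(a)
        for k in range(b)
    )
    F_A = (ss_a / (a - 1)) / (ss_as / ((a - 1) * (n - 1)))
    F_B = (ss_b / (b - 1)) / (ss_bs / ((b - 1) * (n - 1)))
    F_AB = (ss_ab / ((a - 1) * (b - 1))) / (ss_abs / ((a - 1) * (b - 1) * (n - 1)))
    return F_A, F_B, F_AB


def table_from_array(y):
    n, a, b = y.shape
    rows = [
        (f"s{i}", ["MM", "MC"][j % 2] if a == 2 else f"A{j}", k + 1, y[i, j, k])
        for i in range(n)
        for j in range(a)
        for k in range(b)
    ]
    return pd.DataFrame(rows, columns=["animal_id", "condition", "paired_session", "value"])


class TestRmAnova2Way:
    def test_matches_brute_force_oracle_on_random_tables(self):
        rng = np.random.default_rng(31)
        for _ in range(12):
            n = int(rng.integers(4, 11))
            b = int(rng.integers(3, 9))
            y = rng.normal(50, 10, (n, 2, b)) + rng.normal(0, 5, (n, 1, 1))
            mine = anstats.rm_anova_2way_array(y)
            oracle = oracle_rm2_F(y)
            for eff, Fo in zip(mine, oracle):
                assert eff.F == pytest.approx(Fo, abs=1e-8, rel=1e-8)

    def test_location_invariance(self):
        rng = np.random.default_rng(5)
        y = rng.normal(0, 1, (6, 2, 4))
        base = anstats.rm_anova_2way_array(y)
        shifted = anstats.rm_anova_2way_array(y + 123.4)
        for e1, e2 in zip(base, shifted):
            assert e1.F == pytest.approx(e2.F, rel=1e-9)

    def test_pure_condition_shift(self):
        # identical sessions, constant condition offset, tiny noise
        rng = np.random.default_rng(9)
        y = np.zeros((6, 2, 4)) + rng.normal(0, 1e-6, (6, 2, 4))
        y[:, 1, :] += 5.0
        eff = anstats.rm_anova_2way_array(y)
        assert eff[0].p < 1e-10          # Condition
        assert eff[1].F < 10             # Session ~ noise only
        assert eff[1].p > 0.001

    def test_matches_pingouin(self):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(77)
        y = rng.normal(10, 2, (8, 2, 5))
        df = table_from_array(y)
        mine = anstats.rm_anova_2way(df)
        aov = pg.rm_anova(data=df, dv="value", within=["condition", "paired_session"],
                          subject="animal_id", detailed=True)
        np.testing.assert_allclose(
            sorted(e.F for e in mine), sorted(aov["F"]), rtol=1e-9
        )

    def test_listwise_deletion_and_insufficient_data(self):
        y = np.random.default_rng(0).normal(0, 1, (3, 2, 3))
        df = table_from_array(y)
        df = df[~((df.animal_id == "s0") & (df.paired_session == 2))]
        # s0 incomplete -> dropped -> 2 subjects remain, still estimable
        eff = anstats.rm_anova_2way(df)
        assert eff[0].df_den == 1.0  # (a-1)(n-1) with n=2
        df2 = df[df.animal_id == "s1"]
        with pytest.raises(anstats.InsufficientDataError):
            anstats.rm_anova_2way(df2)


class TestGreenhouseGeisser:
    def test_compound_symmetry_gives_one(self):
        S = 0.3 * np.ones((6, 6)) + np.eye(6) * 1.7
        assert anstats.greenhouse_geisser_epsilon(S) == pytest.approx(1.0)

    def test_two_levels_give_one(self):
        S = np.array([[2.0, 0.3], [0.3, 0.9]])
        assert anstats.greenhouse_geisser_epsilon(S) == pytest.approx(1.0)

    def test_matches_symbolic_formula_on_random_covariance(self):
        rng = np.random.default_rng(123)
        A = rng.normal(0, 1, (8, 8))
        S = A @ A.T + np.eye(8)
        k = 8
        Sr = sympy.Matrix([[sympy.Rational(str(round(S[i, j], 6))) for j in range(k)] for i in range(k)])
        H = sympy.eye(k) - sympy.ones(k, k) / k
        M = H * Sr * H
        eps_sym = (M.trace() ** 2) / ((k - 1) * (M * M).trace())
        Sf = np.array([[round(S[i, j], 6) for j in range(k)] for i in range(k)])
        assert anstats.greenhouse_geisser_epsilon(Sf) == pytest.approx(float(eps_sym), rel=1e-10)

    def test_epsilon_bounds(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            k = int(rng.integers(3, 9))
            A = rng.normal(0, 1, (k, k + 2))
            S = A @ A.T
            eps = anstats.greenhouse_geisser_epsilon(S)
            assert 1.0 / (k - 1) - 1e-12 <= eps <= 1.0

    def test_degenerate_covariance_errors(self):
        with pytest.raises(ValueError):
            anstats.greenhouse_geisser_epsilon(np.zeros((4, 4)))

    def test_corrected_p_not_smaller_than_uncorrected(self):
        # conservativeness in the decision-relevant regime: the correction
        # can only raise p wherever the uncorrected term approaches
        # significance (for clearly null terms, p >~ 0.22, shrinking both df
        # can lower p slightly — it never creates a rejection)
        rng = np.random.default_rng(15)
        for rep in range(10):
            y = rng.normal(0, 1, (8, 2, 6)).cumsum(axis=2)  # non-spherical
            y[:, :, :] += np.linspace(0, rep * 0.3, 6)      # session trend
            raw = anstats.rm_anova_2way_array(y, gg=False)
            cor = anstats.rm_anova_2way_array(y, gg=True)
            for e_raw, e_cor in zip(raw, cor):
                if e_raw.p <= 0.1:
                    assert e_cor.p >= e_raw.p - 1e-12


class TestMixedAnova3Way:
    def test_epsilon_one_for_two_level_within(self):
        rng = np.random.default_rng(2)
        y = rng.normal(0, 1, (2, 2, 4, 2))
        eff = anstats.mixed_anova_3way_array(y)
        session_terms = [e for e in eff if e.epsilon is not None]
        assert all(e.epsilon == pytest.approx(1.0) for e in session_terms)

    def test_identical_groups_null_F(self):
        # groups simulated identically: between-effect F near its null mean
        rng = np.random.default_rng(8)
        reps = 300
        Fs = []
        for _ in range(reps):
            y = rng.normal(0, 1, (2, 2, 5, 4)) + rng.normal(0, 1, (2, 2, 5, 1))
            eff = anstats.mixed_anova_3way_array(y)
            Fs.append(eff[0].F)  # Diet
        df2 = 16  # N - G = 20 - 4
        expected = df2 / (df2 - 2)
        assert np.mean(Fs) == pytest.approx(expected, abs=0.35)

    def test_built_in_session_predictor_interaction_detected(self):
        # Session x Predictor effect present, no Diet effect: power simulation
        rng = np.random.default_rng(44)
        hits_int, hits_diet = 0, 0
        reps = 100
        k = 6
        slope = np.linspace(-1.0, 1.0, k)
        for _ in range(reps):
            y = rng.normal(0, 1, (2, 2, 5, k))
            y[:, 1, :, :] += slope  # predictor level 2 gets a session trend
            eff = anstats.mixed_anova_3way_array(y)
            terms = {e.term: e for e in eff}
            hits_int += terms["Session x Predictor"].p < 0.05
            hits_diet += terms["Diet"].p < 0.05
        assert hits_int >= 80
        assert hits_diet <= 15

    def test_reproduces_printed_df_pattern(self):
        # 40 subjects in 4 groups, 8 sessions: Session df 7*eps / 252*eps
        rng = np.random.default_rng(10)
        y = rng.normal(1, 0.2, (2, 2, 10, 8)).cumsum(axis=3)
        eff = anstats.mixed_anova_3way_array(y, gg="session-main")
        sess = [e for e in eff if e.term == "Session"][0]
        assert sess.df_num == pytest.approx(7 * sess.epsilon)
        assert sess.df_den == pytest.approx(252 * sess.epsilon)
        inter = [e for e in eff if e.term == "Session x Predictor"][0]
        assert (inter.df_num, inter.df_den) == (7, 252)

    def test_unbalanced_or_small_cells_rejected(self):
        rng = np.random.default_rng(1)
        y = rng.normal(0, 1, (2, 2, 1, 4))
        with pytest.raises(anstats.InsufficientDataError):
            anstats.mixed_anova_3way_array(y)


class TestTTests:
    def test_identical_groups(self):
        x = np.array([1.0, 2.0, 3.0])
        t, df, p = anstats.unpaired_t(x, x.copy())
        assert t == 0 and p == 1

    def test_textbook_pooled_variance_fixture(self):
        a = np.array([20.0, 22.0, 19.0, 20.0, 21.0])
        b = np.array([28.0, 26.0, 27.0, 25.0, 29.0])
        t, df, p = anstats.unpaired_t(a, b)
        # pooled-variance formula by hand
        sp2 = (a.var(ddof=1) * 4 + b.var(ddof=1) * 4) / 8
        t_hand = (a.mean() - b.mean()) / math.sqrt(sp2 * (1 / 5 + 1 / 5))
        assert t == pytest.approx(t_hand, rel=1e-12)
        assert df == 8

    def test_swapped_groups_negate_t(self):
        rng = np.random.default_rng(6)
        a, b = rng.normal(0, 1, 10), rng.normal(0.5, 1, 10)
        t1, _, p1 = anstats.unpaired_t(a, b)
        t2, _, p2 = anstats.unpaired_t(b, a)
        assert t1 == pytest.approx(-t2)
        assert p1 == pytest.approx(p2)

    def test_welch_differs_under_heteroscedasticity(self):
        rng = np.random.default_rng(12)
        a = rng.normal(0, 0.5, 5)
        b = rng.normal(1, 5.0, 20)
        _, df_pooled, _ = anstats.unpaired_t(a, b)
        _, df_welch, _ = anstats.unpaired_t(a, b, welch=True)
        assert df_pooled == 23
        assert df_welch != df_pooled

    def test_paired_t_zero_variance_convention(self):
        t, df, p = anstats.paired_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert (t, p) == (0.0, 1.0)

    def test_paired_t_matches_scipy(self):
        from scipy import stats as sps

        rng = np.random.default_rng(21)
        a, b = rng.normal(0, 1, 12), rng.normal(0.4, 1, 12)
        t, df, p = anstats.paired_t(a, b)
        ref = sps.ttest_rel(b, a)
        assert t == pytest.approx(ref.statistic)
        assert p == pytest.approx(ref.pvalue)


class TestPosthocAndEmergence:
    def make_table(self, diffs, n=8, noise=1.0, seed=0):
        rng = np.random.default_rng(seed)
        rows = []
        for s, d in enumerate(diffs, start=1):
            base = rng.normal(100, noise, n)
            for i in range(n):
                rows.append((f"s{i}", s, "MM", base[i]))
                rows.append((f"s{i}", s, "MC", base[i] + d + rng.normal(0, noise)))
        return pd.DataFrame(rows, columns=["animal_id", "paired_session", "condition", "value"])

    def test_bonferroni_arithmetic_and_cap(self):
        assert min(1.0, 8 * 0.004) == pytest.approx(0.032)
        table = self.make_table([0.0] * 8, noise=5.0, seed=4)
        rows = anstats.bonferroni_posthoc(table, m=8)
        assert all(r.p_bonferroni == min(1.0, 8 * r.p_raw) for r in rows)
        assert all(r.p_bonferroni <= 1.0 for r in rows)

    def test_identical_values_give_t0_p1(self):
        rows = []
        for i in range(6):
            rows += [(f"s{i}", 1, "MM", 10.0), (f"s{i}", 1, "MC", 10.0)]
        table = pd.DataFrame(rows, columns=["animal_id", "paired_session", "condition", "value"])
        r = anstats.bonferroni_posthoc(table, m=8)[0]
        assert r.t == 0.0 and r.p_bonferroni == 1.0 and not r.significant

    def test_bonferroni_dominance(self):
        table = self.make_table([0, 0, 3, 3, 0, 3, 0, 0], noise=2.0, seed=7)
        rows = anstats.bonferroni_posthoc(table)
        sig_corrected = {r.session for r in rows if r.significant}
        sig_raw = {r.session for r in rows if r.p_raw < 0.05}
        assert sig_corrected <= sig_raw

    def test_emergence_first_significant_session(self):
        table = self.make_table([0, 0, 8, 8, 8, 8, 8, 8], noise=1.0, seed=1)
        rows = anstats.bonferroni_posthoc(table)
        assert anstats.emergence_session(rows) == 3

    def test_emergence_none_when_nothing_significant(self):
        table = self.make_table([0.0] * 8, noise=5.0, seed=2)
        rows = anstats.bonferroni_posthoc(table)
        assert anstats.emergence_session(rows) is None

    def test_emergence_takes_first_regardless_of_gaps(self):
        rows = [
            anstats.PosthocRow(1, 1.0, 3.0, 0.001, 0.008, True, 8),
            anstats.PosthocRow(2, 0.0, 0.1, 0.9, 1.0, False, 8),
        ]
        assert anstats.emergence_session(rows) == 1

    def test_single_pair_session_flagged_untestable(self):
        rows = [("s0", 1, "MM", 1.0), ("s0", 1, "MC", 2.0)]
        table = pd.DataFrame(rows, columns=["animal_id", "paired_session", "condition", "value"])
        r = anstats.bonferroni_posthoc(table, m=8)[0]
        assert not r.testable
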