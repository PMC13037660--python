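"""Registered behavioural statistics: filters, MAD tagging, implicit
wanting, the 2x2 within ANOVA against a textbook sums-of-squares oracle
(and pingouin as an independent implementation), Bayes factors, the
effect-size gate, moderation, and the power calculator."""

import numpy as np
import pandas as pd
import pytest

from cravemod.errors import ConfigError, DataError
from cravemod.stats import (
    PowerSpec,
    adaptive_rtt,
    anova_2x2_within,
    bf01,
    cohens_d_gate,
    filter_ratings,
    filter_trials,
    gng_performance_exclusion,
    implicit_wanting,
    mad_flags,
    moderation_fit,
    paired_cohens_d,
    power_rm_anova,
    power_rm_anova_at,
)


class TestFilters:
    def test_rt_floor(self):
        df = pd.DataFrame({"subject": [0, 0, 0], "rt_ms": [150.0, 250.0, 199.0]})
        out, report = filter_trials(df)
        assert len(out) == 1 and out["rt_ms"].iloc[0] == 250.0
        assert report["n_removed"].iloc[0] == 2

    def test_empty_input(self):
        df = pd.DataFrame({"subject": [], "rt_ms": []})
        out, report = filter_trials(df)
        assert len(out) == 0 and len(report) == 0

    def test_zero_floor_is_identity(self):
        df = pd.DataFrame({"subject": [0, 1], "rt_ms": [10.0, 5000.0]})
        out, _ = filter_trials(df, rt_floor_ms=0.0)
        pd.testing.assert_frame_equal(out, df)

    def test_rating_floor_is_300(self):
        df = pd.DataFrame({"subject": [0, 0], "rt_ms": [299.0, 300.0]})
        out, _ = filter_ratings(df)
        assert out["rt_ms"].tolist() == [300.0]

    def test_idempotent(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame({"subject": np.zeros(100, dtype=int),
                           "rt_ms": rng.uniform(0, 1000, 100)})
        once, _ = filter_trials(df)
        twice, _ = filter_trials(once)
        pd.testing.assert_frame_equal(once, twice)


class TestMadFlags:
    def test_hand_computed_example(self):
        # median 12, MAD 1 -> only 100 lies beyond 2.5 MAD
        flags = mad_flags([10, 11, 12, 13, 100])
        assert flags.tolist() == [False, False, False, False, True]

    def test_all_equal_warns_and_flags_nothing(self):
        with pytest.warns(UserWarning, match="MAD is zero"):
            flags = mad_flags([5.0] * 6)
        assert not flags.any()

    def test_affine_equivariance(self, rng):
        x = rng.normal(size=50)
        a, b = 3.7, -12.0
        assert np.array_equal(mad_flags(x), mad_flags(a * x + b))

    def test_too_few_values(self):
        with pytest.raises(DataError):
            mad_flags([1.0, 2.0])


class TestImplicitWanting:
    def _src(self, away, toward):
        rows = [(0, "pre", "go", "away", v) for v in away]
        rows += [(0, "pre", "go", "toward", v) for v in toward]
        return pd.DataFrame(rows, columns=["subject", "session", "category",
                                           "direction", "rt_ms"])

    def test_difference_of_means(self):
        iw = implicit_wanting(self._src([600.0], [500.0]))
        assert iw["iw_ms"].iloc[0] == pytest.approx(100.0)

    def test_equal_means_give_zero(self):
        iw = implicit_wanting(self._src([500.0, 700.0], [600.0, 600.0]))
        assert iw["iw_ms"].iloc[0] == pytest.approx(0.0)

    def test_direction_swap_flips_sign(self):
        a = implicit_wanting(self._src([650.0], [450.0]))["iw_ms"].iloc[0]
        swapped = self._src([450.0], [650.0])
        b = implicit_wanting(swapped)["iw_ms"].iloc[0]
        assert a == pytest.approx(-b)

    def test_fast_trials_filtered_first(self):
        df = self._src([600.0, 150.0], [500.0])
        iw = implicit_wanting(df)
        assert iw["iw_ms"].iloc[0] == pytest.approx(100.0)

    def test_missing_direction_errors(self):
        df = self._src([600.0], [500.0])
        with pytest.raises(DataError):
            implicit_wanting(df[df["direction"] == "away"])


class TestAdaptiveRtt:
    @pytest.mark.parametrize("rts,expected", [
        ([400, 500, 600], 550.0),
        ([500], 550.0),
        ([400, 600], 550.0),        # even count: mean of the middle pair
    ])
    def test_threshold(self, rts, expected):
        assert adaptive_rtt(rts) == pytest.approx(expected)

    def test_empty_errors(self):
        with pytest.raises(DataError):
            adaptive_rtt([])


class TestGngExclusion:
    @pytest.mark.parametrize("fa,miss,expected", [
        (0.71, 0.05, True),
        (0.70, 0.20, False),        # boundary: strict inequality keeps
        (0.10, 0.21, True),
    ])
    def test_rule(self, fa, miss, expected):
        assert gng_performance_exclusion(fa, miss) is expected


# ---------------------------------------------------------------------------
# ANOVA
# ---------------------------------------------------------------------------


def _ss_oracle_interaction(cells: np.ndarray):
    """Textbook sums-of-squares for the 2x2 within design.

    ``cells`` columns: (pre,go), (pre,nogo), (post,go), (post,nogo).
    Returns (F, df1, df2) for the session x category interaction.
    """
    n = cells.shape[0]
    y = cells.reshape(n, 2, 2)                  # subject x session x category
    gm = y.mean()
    m_ab = y.mean(axis=0)                       # 2x2 cell means
    m_a = y.mean(axis=(0, 2))                   # session means
    m_b = y.mean(axis=(0, 1))                   # category means
    m_s = y.mean(axis=(1, 2))                   # subject means
    m_sa = y.mean(axis=2)                       # subject x session
    m_sb = y.mean(axis=1)                       # subject x category
    ss_ab = n * ((m_ab - m_a[:, None] - m_b[None, :] + gm) ** 2).sum()
    resid = (
        y
        - m_ab[None, :, :]
        - m_sa[:, :, None]
        - m_sb[:, None, :]
        + m_a[None, :, None]
        + m_b[None, None, :]
        + m_s[:, None, None]
        - gm
    )
    ss_err = (resid**2).sum()
    df1, df2 = 1, n - 1
    return (ss_ab / df1) / (ss_err / df2), df1, df2


def _cells_to_long(cells):
    rows = []
    labels = [("pre", "go"), ("pre", "nogo"), ("post", "go"), ("post", "nogo")]
    for s in range(cells.shape[0]):
        for j, (sess, cat) in enumerate(labels):
            rows.append((s, sess, cat, cells[s, j]))
    return pd.DataFrame(rows, columns=["subject", "session", "category", "value"])


class TestAnova2x2Within:
    def test_matches_ss_oracle_on_toy_table(self, toy_cell_table):
        cells = (
            toy_cell_table.pivot_table(index="subject",
                                       columns=["session", "category"],
                                       values="value")
            [[("pre", "go"), ("pre", "nogo"), ("post", "go"), ("post", "nogo")]]
            .to_numpy()
        )
        f_oracle, df1, df2 = _ss_oracle_interaction(cells)
        res = anova_2x2_within(toy_cell_table)
        assert res.F == pytest.approx(f_oracle, abs=1e-8)
        assert (res.df1, res.df2) == (df1, df2)
        assert res.partial_f == pytest.approx(np.sqrt(res.F / res.df2), abs=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_ss_oracle_on_random_tables(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 12))
        cells = rng.normal(50, 10, size=(n, 4))
        res = anova_2x2_within(_cells_to_long(cells), compute_bf=False)
        f_oracle, _, _ = _ss_oracle_interaction(cells)
        assert res.F == pytest.approx(f_oracle, abs=1e-8)

    def test_matches_pingouin(self, toy_cell_table):
        pg = pytest.importorskip("pingouin")
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            table = pg.rm_anova(data=toy_cell_table, dv="value",
                                within=["session", "category"], subject="subject")
        row = table[table["Source"].str.contains(r"\*")].iloc[0]
        res = anova_2x2_within(toy_cell_table)
        assert res.F == pytest.approx(float(row["F"]), rel=1e-9)
        assert res.p == pytest.approx(float(row["p_unc"]), rel=1e-9)

    def test_zero_interaction_contrast_gives_f_zero(self):
        base = np.array([[50.0, 55.0, 45.0, 50.0]])
        cells = np.repeat(base, 6, axis=0) + np.arange(6)[:, None]
        res = anova_2x2_within(_cells_to_long(cells), compute_bf=False)
        assert res.F == 0.0

    def test_type_i_rate_calibrated(self):
        hits = 0
        n_rep, n = 400, 20
        for rep in range(n_rep):
            rng = np.random.default_rng(10_000 + rep)
            cells = rng.normal(0, 1, size=(n, 4))
            res = anova_2x2_within(_cells_to_long(cells), compute_bf=False)
            hits += res.p < 0.02
        rate = hits / n_rep
        assert rate == pytest.approx(0.02, abs=2.5 * np.sqrt(0.02 * 0.98 / n_rep))

    def test_incomplete_cells_error(self, toy_cell_table):
        broken = toy_cell_table.iloc[:-1]
        with pytest.raises(DataError, match="incomplete"):
            anova_2x2_within(broken)


class TestBf01:
    def test_identical_bics_give_one(self):
        assert bf01(12.3, 12.3) == pytest.approx(1.0)

    def test_delta_two_in_favour_of_null(self):
        assert bf01(10.0, 8.0) == pytest.approx(np.e)

    def test_strong_effect_gives_small_bf01(self):
        rng = np.random.default_rng(3)
        cells = rng.normal(50, 2, size=(30, 4))
        cells[:, 3] += 10.0          # strong interaction
        res = anova_2x2_within(_cells_to_long(cells))
        assert res.bf01 < 0.1

    def test_non_nested_models_rejected(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(4)
        y = rng.normal(size=30)
        x = sm.add_constant(rng.normal(size=(30, 2)))
        small = sm.OLS(y, x[:, :2]).fit()
        big = sm.OLS(y, x).fit()
        with pytest.raises(DataError):
            bf01(small, big)


class TestCohensD:
    def test_identical_vectors(self):
        d, ok = cohens_d_gate([4.0, 5.0, 6.0], [4.0, 5.0, 6.0])
        assert d == 0.0 and not ok

    def test_constant_shift_undefined(self):
        with pytest.raises(DataError):
            paired_cohens_d([5.0, 6.0, 7.0], [4.0, 5.0, 6.0])

    def test_simulated_d_recovered(self):
        rng = np.random.default_rng(5)
        n = 2000
        diff = rng.normal(0.78, 1.0, n)
        post = rng.normal(60, 10, n)
        d = paired_cohens_d(post + diff, post)
        assert d == pytest.approx(0.78, abs=3.0 / np.sqrt(n))


class TestModeration:
    def test_exact_linear_relation(self, rng):
        bias = rng.normal(size=30)
        baseline = rng.normal(size=30)
        res = moderation_fit(2.0 * bias, bias, baseline)
        assert res.beta == pytest.approx(2.0, abs=1e-9)
        assert res.r2 == pytest.approx(1.0, abs=1e-9)
        assert res.df == 27          # n - 3

    def test_null_p_uniformity(self):
        ps = []
        for rep in range(300):
            rng = np.random.default_rng(20_000 + rep)
            delta = rng.normal(size=25)
            bias = rng.normal(size=25)
            baseline = rng.normal(size=25)
            ps.append(moderation_fit(delta, bias, baseline).p)
        ps = np.sort(ps)
        # Kolmogorov-Smirnov distance against Uniform(0, 1)
        ks = np.max(np.abs(ps - (np.arange(1, 301)) / 300))
        assert ks < 1.63 / np.sqrt(300)     # 1% critical value

    def test_slope_within_two_se_of_truth(self):
        rng = np.random.default_rng(6)
        bias = rng.normal(0, 1, 200)
        baseline = rng.normal(0, 1, 200)
        delta = 1.5 * bias + 0.5 * baseline + rng.normal(0, 1, 200)
        res = moderation_fit(delta, bias, baseline)
        assert abs(res.beta - 1.5) < 2 * res.se

    def test_matches_normal_equations(self, rng):
        bias = rng.normal(size=40)
        baseline = rng.normal(size=40)
        delta = rng.normal(size=40)
        x = np.column_stack([np.ones(40), bias, baseline])
        beta_hat = np.linalg.solve(x.T @ x, x.T @ delta)
        res = moderation_fit(delta, bias, baseline)
        assert res.beta == pytest.approx(beta_hat[1], abs=1e-8)

    def test_collinearity_warns(self, rng):
        bias = rng.normal(size=20)
        with pytest.warns(UserWarning, match="collinear"):
            moderation_fit(rng.normal(size=20), bias, 2.0 * bias)

    def test_too_small_n(self):
        with pytest.raises(DataError):
            moderation_fit([1.0, 2.0, 3.0], [1.0, 2.0, 3.0], [0.0, 1.0, 0.0])


class TestPower:
    def test_printed_design_n(self):
        spec = PowerSpec(effect_size_f=0.25, alpha=0.02, power=0.90,
                         n_levels=2, rho=0.5, epsilon=1.0)
        assert power_rm_anova(spec) == 56

    def test_returned_n_brackets_target(self):
        spec = PowerSpec(effect_size_f=0.25)
        n = power_rm_anova(spec)
        assert power_rm_anova_at(n, spec) >= 0.90 > power_rm_anova_at(n - 1, spec)

    def test_monotone_in_effect_size(self):
        small = power_rm_anova(PowerSpec(effect_size_f=0.25))
        large = power_rm_anova(PowerSpec(effect_size_f=0.50))
        assert large < small

    def test_monotone_in_alpha(self):
        strict = power_rm_anova(PowerSpec(effect_size_f=0.25, alpha=0.02))
        lax = power_rm_anova(PowerSpec(effect_size_f=0.25, alpha=0.05))
        assert lax < strict

    def test_monotone_in_rho(self):
        low = power_rm_anova(PowerSpec(effect_size_f=0.25, rho=0.3))
        high = power_rm_anova(PowerSpec(effect_size_f=0.25, rho=0.7))
        assert high < low

    def test_unreachable_power_errors(self):
        with pytest.raises(ConfigError):
            power_rm_anova(PowerSpec(effect_size_f=0.01, n_max=20))
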