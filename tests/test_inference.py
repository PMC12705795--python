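import numpy as np
import pandas as pd
import pingouin as pg
import pytest
from scipy import stats

from newssdt import (
    DEFAULT_RSCALE,
    anova_bf_approx,
    jzs_bf_paired,
    mean_ratings_tests,
    mixed_anova_2x2,
    paired_t,
    power_paired_t,
    simulate_study,
)
from newssdt.exceptions import ConfigurationError, DegenerateDataError
from newssdt.inference import _split_plot_ss
from newssdt.synthetic import SimulationConfig

from conftest import make_table


class TestPairedT:
    def test_hand_computed_statistic(self):
        # differences {1,2,3,4}: mean 2.5, SD sqrt(5/3), t = 2.5/(SD/2)
        pre = np.zeros(4)
        post = np.array([1.0, 2.0, 3.0, 4.0])
        res = paired_t(pre, post, compute_bf=False)
        assert res.t == pytest.approx(2.5 / (np.sqrt(5 / 3) / 2), abs=1e-9)
        assert res.df == 3
        assert res.dz == pytest.approx(2.5 / np.sqrt(5 / 3))

    def test_identical_samples_guarded(self):
        x = np.array([1.0, 2.0, 3.0])
        with pytest.warns(RuntimeWarning, match="identical paired samples"):
            res = paired_t(x, x)
        assert (res.t, res.p, res.dz) == (0.0, 1.0, 0.0)
        assert res.bf10 > 0

    def test_constant_nonzero_difference_is_degenerate(self):
        x = np.array([1.0, 2.0, 3.0])
        with pytest.raises(DegenerateDataError):
            paired_t(x, x + 1.0)

    def test_p_matches_central_t_survival_function(self, rng):
        """Two-tailed p equals 2*SF of the central t on n-1 df, to 1e-10."""
        for n in (5, 20, 150):
            pre = rng.normal(0, 1, n)
            post = pre + rng.normal(0.1, 1, n)
            res = paired_t(pre, post, compute_bf=False)
            assert res.p == pytest.approx(2 * stats.t.sf(abs(res.t), n - 1), abs=1e-10)
            assert res.dz == pytest.approx(res.t / np.sqrt(n), abs=1e-10)


class TestJZSBayesFactor:
    def test_independent_fixed_grid_quadrature_oracle(self):
        """Agree with a brute-force trapezoid over the Cauchy prior.

        Substituting delta = r*tan(theta) makes the Cauchy prior uniform on
        (-pi/2, pi/2); a dense fixed grid then integrates the noncentral-t
        likelihood directly.
        """
        theta = np.linspace(-np.pi / 2, np.pi / 2, 1_000_001)[1:-1]
        for t, n in [(0.0, 10), (1.0, 10), (2.5, 150), (0.49, 150)]:
            df = n - 1
            deltas = DEFAULT_RSCALE * np.tan(theta)
            like = stats.nct.pdf(t, df, deltas * np.sqrt(n))
            numerator = np.trapezoid(like, theta) / np.pi
            oracle = numerator / stats.t.pdf(t, df)
            assert jzs_bf_paired(t, n) == pytest.approx(oracle, rel=1e-4)

    def test_monotone_in_absolute_t_with_minimum_at_zero(self):
        for n in (5, 30, 150):
            grid = [jzs_bf_paired(t, n) for t in np.linspace(0, 5, 21)]
            assert np.all(np.diff(grid) > 0)
            assert jzs_bf_paired(-2.0, n) == pytest.approx(jzs_bf_paired(2.0, n), rel=1e-8)
            assert grid[0] < 1  # BF at t=0 favours the null for all these n

    def test_reciprocal_identity(self):
        bf10 = jzs_bf_paired(1.3, 40)
        assert bf10 * (1.0 / bf10) == pytest.approx(1.0)

    def test_input_validation(self):
        with pytest.raises(ConfigurationError):
            jzs_bf_paired(np.inf, 10)
        with pytest.raises(ConfigurationError):
            jzs_bf_paired(1.0, 10, rscale=0.0)


class TestPowerPairedT:
    def test_study_sample_size(self):
        spec = power_paired_t(dz=0.30, alpha=0.05, power=0.95, tails=2)
        assert spec.n_required == 147
        assert spec.achieved_power >= 0.95
        # minimality: one participant fewer does not reach the target
        from newssdt.inference import _paired_t_power

        assert _paired_t_power(0.30, 146, 0.05, 2) < 0.95

    def test_power_non_decreasing_in_n(self):
        from newssdt.inference import _paired_t_power

        powers = [_paired_t_power(0.3, n, 0.05, 2) for n in range(10, 400, 13)]
        assert np.all(np.diff(powers) > 0)

    def test_against_statsmodels_solver(self):
        from statsmodels.stats.power import TTestPower

        for dz, power in [(0.30, 0.95), (0.5, 0.8), (0.2, 0.9)]:
            n_sm = TTestPower().solve_power(effect_size=dz, alpha=0.05, power=power)
            assert power_paired_t(dz, 0.05, power, 2).n_required == int(np.ceil(n_sm))

    def test_one_tailed_needs_fewer(self):
        assert power_paired_t(0.3, tails=1).n_required < power_paired_t(0.3, tails=2).n_required


def _long_frame(pre, post, group):
    n = len(pre)
    return pd.DataFrame({
        "subj": np.tile([f"s{i}" for i in range(n)], 2),
        "grp": np.tile(group, 2),
        "phase": np.repeat(["pre", "post"], n),
        "y": np.concatenate([pre, post]),
    })


class TestMixedAnova:
    def test_all_identical_values(self):
        pre = np.full(8, 3.0)
        res = mixed_anova_2x2(pre, pre, np.array(["A", "B"] * 4))
        assert (res.table["F"] == 0).all()
        assert (res.table["ges"] == 0).all()
        assert (res.table["p"] == 1).all()

    def test_pure_between_offset_isolated_to_condition_effect(self):
        base = np.array([1.0, 2.0, 3.0, 4.0])
        pre = np.concatenate([base, base + 5])
        group = np.repeat(["A", "B"], 4)
        res = mixed_anova_2x2(pre, pre.copy(), group)
        assert res.table.loc["test", "F"] == 0
        assert res.table.loc["interaction", "F"] == 0
        assert res.table.loc["condition", "F"] > 10

    def test_six_participant_hand_decomposition(self):
        """Frozen oracle: sums of squares derived by hand from cell means.

        Group A (n=3): pre (2,3,4), post (4,5,6); group B (n=3): pre (3,3,3),
        post (2,3,4).  Subject means m and difference scores d give
        SS_cond = 2*sum(n_j*(m_j - m)^2) = 2*(3*(4-3.5)^2 + 3*(3-3.5)^2) = 3,
        SS_test = (w/2)*((2-0)/2)^2 = 3 with w = 4/(1/3+1/3) = 6,
        SS_inter = (w/2)*((2-0)/2)^2 = 3,
        SS_errW = (sum((d-2)^2) + sum((d-0)^2))/2 = (0 + 2)/2 = 1,
        SS_errB = 2*(sum over A (m - 4)^2 + sum over B (m - 3)^2) = 2*(2+0.5) = 5.
        """
        pre = np.array([2.0, 3.0, 4.0, 3.0, 3.0, 3.0])
        post = np.array([4.0, 5.0, 6.0, 2.0, 3.0, 4.0])
        group = np.repeat(["A", "B"], 3)
        ss = _split_plot_ss(pre, post, group)
        assert ss["condition"] == pytest.approx(3.0)
        assert ss["test"] == pytest.approx(3.0)
        assert ss["interaction"] == pytest.approx(3.0)
        assert ss["error_within"] == pytest.approx(1.0)
        assert ss["error_between"] == pytest.approx(5.0)
        res = mixed_anova_2x2(pre, post, group)
        assert res.table.loc["test", "F"] == pytest.approx(3.0 / (1.0 / 4))
        assert res.table.loc["condition", "F"] == pytest.approx(3.0 / (5.0 / 4))

    @pytest.mark.parametrize("n_groups", [(10, 10), (7, 12)])
    def test_against_pingouin(self, rng, n_groups):
        n1, n2 = n_groups
        pre = rng.normal(0, 1, n1 + n2)
        post = 0.6 * pre + rng.normal(0.3, 1, n1 + n2)
        group = np.array(["A"] * n1 + ["B"] * n2)
        res = mixed_anova_2x2(pre, post, group)
        pgr = (
            pg.mixed_anova(
                _long_frame(pre, post, group),
                dv="y", within="phase", subject="subj", between="grp",
            )
            .set_index("Source")
        )
        # condition and interaction agree for any group sizes
        assert res.table.loc["condition", "F"] == pytest.approx(pgr.loc["grp", "F"])
        assert res.table.loc["interaction", "F"] == pytest.approx(pgr.loc["Interaction", "F"])
        assert res.table.loc["condition", "p"] == pytest.approx(pgr.loc["grp", "p_unc"])
        if n1 == n2:
            # the within main effect coincides when the design is balanced
            # (unbalanced designs: this package uses unweighted type-III
            # cell means, pingouin weights by group size)
            assert res.table.loc["test", "F"] == pytest.approx(pgr.loc["phase", "F"])

    def test_within_f_relates_to_squared_paired_t(self, rng):
        """With balanced groups and equal group difference-score means,
        F(test) = t^2 * (N-2)/(N-1): the ANOVA error loses one df to the
        group term but describes the same variation."""
        n = 12
        pre_a = rng.normal(0, 1, n)
        post_a = pre_a + rng.normal(0.4, 1, n)
        # group B replicates group A's difference scores exactly
        pre_b = rng.normal(2, 1, n)
        post_b = pre_b + (post_a - pre_a)
        pre = np.concatenate([pre_a, pre_b])
        post = np.concatenate([post_a, post_b])
        group = np.repeat(["A", "B"], n)
        res = mixed_anova_2x2(pre, post, group)
        t = paired_t(pre, post, compute_bf=False).t
        N = 2 * n
        assert res.table.loc["test", "F"] == pytest.approx(t**2 * (N - 2) / (N - 1))

    def test_ges_between_zero_and_one(self, rng):
        pre = rng.normal(0, 1, 30)
        post = pre + rng.normal(0.5, 1, 30)
        group = np.array(["A", "B"] * 15)
        ges = mixed_anova_2x2(pre, post, group).table["ges"]
        assert ((ges >= 0) & (ges <= 1)).all()


class TestAnovaBF:
    def test_null_data_favour_null_in_majority(self, rng):
        below_one = 0
        total = 0
        for rep in range(12):
            subj = rng.normal(0, 1, 40)
            pre = subj + rng.normal(0, 1, 40)
            post = subj + rng.normal(0, 1, 40)
            bf = anova_bf_approx(pre, post, np.array(["A", "B"] * 20),
                                 mc_iterations=1500, seed=rep)
            below_one += int((bf["bf10"] < 1).sum())
            total += 3
        assert below_one / total > 0.6

    def test_planted_within_effect_detected(self, rng):
        subj = rng.normal(0, 1, 50)
        pre = subj + rng.normal(0, 1, 50)
        post = subj + rng.normal(1.0, 1, 50)  # standardized shift 1.0
        bf = anova_bf_approx(pre, post, np.array(["A", "B"] * 25),
                             mc_iterations=2000, seed=5)
        assert bf.loc["test", "bf10"] > 10
        assert bf.loc["condition", "bf10"] < 3  # no planted condition effect

    def test_monte_carlo_error_shrinks_with_iterations(self, rng):
        subj = rng.normal(0, 1, 40)
        pre = subj + rng.normal(0, 1, 40)
        post = subj + rng.normal(0.3, 1, 40)
        grp = np.array(["A", "B"] * 20)
        se1 = anova_bf_approx(pre, post, grp, mc_iterations=8000, seed=1)["bf_se"]
        se2 = anova_bf_approx(pre, post, grp, mc_iterations=16000, seed=2)["bf_se"]
        ratio = (se1 / se2).to_numpy()
        assert np.all(ratio > 1.05) and np.all(ratio < 2.0)

    def test_seeded_reproducibility(self, rng):
        pre = rng.normal(0, 1, 20)
        post = pre + rng.normal(0.2, 1, 20)
        grp = np.array(["A", "B"] * 10)
        a = anova_bf_approx(pre, post, grp, mc_iterations=1000, seed=7)
        b = anova_bf_approx(pre, post, grp, mc_iterations=1000, seed=7)
        pd.testing.assert_frame_equal(a, b)

    def test_iteration_floor_enforced(self, rng):
        with pytest.raises(ConfigurationError):
            anova_bf_approx(rng.normal(size=8), rng.normal(size=8),
                            np.array(["A", "B"] * 4), mc_iterations=10)


class TestMeanRatingsTests:
    def test_identical_phases_give_null_results(self):
        groups = {}
        for pid in ("p1", "p2", "p3"):
            ratings = ([6, 5], [1, 2, 3, 2, 1, 4])
            groups[(pid, "A", "pre")] = ratings
            groups[(pid, "A", "post")] = ratings
        with pytest.warns(RuntimeWarning):
            out = mean_ratings_tests(make_table(groups), compute_bf=False)
        assert set(out) == {"Control", "Conspiracy", "Discrediting", "Impersonation"}
        for res in out.values():
            assert (res.t, res.p) == (0.0, 1.0)

    def test_three_participant_hand_means(self):
        # Control means: pre (6.5, 5.0, 4.0), post (5.5, 5.0, 5.0)
        groups = {
            ("p1", "A", "pre"): ([7, 6], [1, 2, 3]),
            ("p1", "A", "post"): ([6, 5], [1, 2, 3]),
            ("p2", "A", "pre"): ([5, 5], [2, 2, 2]),
            ("p2", "A", "post"): ([5, 5], [3, 2, 1]),
            ("p3", "A", "pre"): ([4, 4], [1, 1, 1]),
            ("p3", "A", "post"): ([5, 5], [2, 2, 2]),
        }
        out = mean_ratings_tests(make_table(groups), compute_bf=False)
        pre_means = np.array([6.5, 5.0, 4.0])
        post_means = np.array([5.5, 5.0, 5.0])
        expected = paired_t(pre_means, post_means, compute_bf=False)
        assert out["Control"].t == pytest.approx(expected.t)
        assert out["Control"].p == pytest.approx(expected.p)

    def test_bias_shift_depresses_all_categories(self):
        """A pure conservative criterion shift lowers the mean rating of every
        category, mimicking an apparent intervention effect."""
        config = SimulationConfig(delta_criterion=0.5)
        table = simulate_study(config, seed=17)
        out = mean_ratings_tests(table, compute_bf=False)
        for category, res in out.items():
            assert res.t < 0, category
            assert res.p < 0.01, category
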