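"""Functional mean-equality tests: oracles, calibration, power, invariants."""

import numpy as np
import pytest
from scipy import stats

from stagewalk.errors import DegenerateInputError, NumericalDegeneracyError
from stagewalk.meantests import (
    PValueSummary,
    TestSpec as MeanTestSpec,
    anova_maxF,
    anova_rp,
    l2_mean_test,
    pointwise_f,
    random_projections,
    repeated_test,
    sphere_directions,
)
from stagewalk.preprocess import interpolate_to_seconds
from stagewalk.synthetic import ar1_curves, generate_cohort

from conftest import small_cohort_config


def null_groups(n_groups, n_per_group, length, seed):
    rng = np.random.default_rng(seed)
    return [
        ar1_curves(n_per_group, length, phi=0.5, sd=1.0, rng=rng)
        for _ in range(n_groups)
    ]


class TestRandomProjections:
    def test_directions_have_unit_norm(self):
        dirs = sphere_directions(50, 17, np.random.default_rng(0))
        np.testing.assert_allclose(np.linalg.norm(dirs, axis=1), 1.0, atol=1e-12)

    def test_identical_curves_project_constantly(self):
        curves = np.tile(np.arange(8.0), (5, 1))
        proj, _ = random_projections(curves, k=4, seed=1)
        assert np.allclose(proj, proj[0])

    def test_sphere_marginal_matches_known_law_in_3d(self):
        # the first coordinate of a uniform point on S^2 is uniform on [-1,1]
        dirs = sphere_directions(10_000, 3, np.random.default_rng(2))
        ks = stats.kstest(dirs[:, 0], stats.uniform(loc=-1, scale=2).cdf)
        assert ks.pvalue > 0.01


class TestAnovaRP:
    def test_null_rejection_rate_not_anticonservative(self):
        # Bonferroni combination is conservative under the null
        rejections = 0
        n_sim = 200
        for s in range(n_sim):
            g = null_groups(3, 6, 15, seed=1000 + s)
            res = anova_rp(g, k=10, combine="bonferroni", seed=s)
            rejections += res.p_value <= 0.05
        se = np.sqrt(0.05 * 0.95 / n_sim)
        assert rejections / n_sim <= 0.05 + 2 * se

    def test_fdr_dominates_bonferroni(self):
        for s in range(20):
            g = null_groups(3, 5, 12, seed=s)
            p_b = anova_rp(g, k=8, combine="bonferroni", seed=s).p_value
            p_f = anova_rp(g, k=8, combine="fdr", seed=s).p_value
            assert p_f <= p_b + 1e-12

    def test_power_under_large_mean_offset(self):
        for s in range(50):
            g = null_groups(3, 8, 20, seed=300 + s)
            g[1] = g[1] + 10.0  # offset far above noise on every grid point
            assert anova_rp(g, k=10, seed=s).p_value < 0.001

    def test_small_group_rejected(self):
        g = null_groups(3, 4, 10, seed=0)
        g[0] = g[0][:1]
        with pytest.raises(DegenerateInputError):
            anova_rp(g, k=5, seed=0)

    def test_degenerate_projection_named(self):
        g = [np.ones((4, 6)), np.ones((4, 6)), np.ones((4, 6))]
        with pytest.raises(NumericalDegeneracyError, match="projection 0"):
            anova_rp(g, k=3, seed=0)


class TestMaxF:
    def test_matches_bruteforce_pointwise_loop(self):
        rng = np.random.default_rng(5)
        groups = [rng.normal(size=(3, 5)) for _ in range(3)]
        f_vec = pointwise_f(groups)
        for t in range(5):
            f_t, _ = stats.f_oneway(*[g[:, t] for g in groups])
            assert f_vec[t] == pytest.approx(f_t, abs=1e-10)
        res = anova_maxF(groups, B=19, seed=0)
        assert res.statistic == pytest.approx(float(f_vec.max()), rel=1e-9)

    def test_pointwise_f_invariant_to_common_curve_shift(self):
        rng = np.random.default_rng(6)
        groups = [rng.normal(size=(4, 9)) for _ in range(3)]
        common = rng.normal(size=9)
        shifted = [g + common for g in groups]
        np.testing.assert_allclose(pointwise_f(groups), pointwise_f(shifted), rtol=1e-9)

    def test_null_rejection_rate_calibrated(self):
        # groups large enough for the centered bootstrap to be consistent
        n_sim, rej = 200, 0
        for s in range(n_sim):
            g = null_groups(3, 15, 15, seed=5000 + s)
            rej += anova_maxF(g, B=199, seed=s).p_value <= 0.05
        se = np.sqrt(0.05 * 0.95 / n_sim)
        assert abs(rej / n_sim - 0.05) <= 2 * se

    def test_p_floor_when_observed_exceeds_all_bootstrap(self):
        g1 = np.tile([0.0], (5, 10)) + np.random.default_rng(0).normal(0, 0.01, (5, 10))
        g2 = g1 + 100.0
        g3 = g1 - 100.0
        res = anova_maxF([g1, g2, g3], B=999, seed=1)
        assert res.p_value == pytest.approx(1.0 / 1000.0)

    def test_all_zero_variance_is_an_error(self):
        g = [np.ones((3, 4)), 2 * np.ones((3, 4)), 3 * np.ones((3, 4))]
        with pytest.raises(NumericalDegeneracyError):
            anova_maxF(g, B=9, seed=0)


class TestL2:
    def test_identical_groups_give_zero_statistic_and_p_one(self):
        g = np.random.default_rng(1).normal(size=(6, 12))
        res = l2_mean_test(g, g.copy(), B=99, seed=0)
        assert res.statistic == 0.0
        assert res.p_value == 1.0

    def test_constant_curves_closed_form(self):
        l, c1, c2 = 13, 2.0, 5.0
        g1 = np.full((4, l), c1)
        g2 = np.full((3, l), c2)
        g1[0, 0] += 1e-9  # avoid total degeneracy in the bootstrap
        res = l2_mean_test(g1, g2, B=9, seed=0)
        # trapezoid of a constant (c1-c2)^2 over l unit steps = (c1-c2)^2 (l-1)
        assert res.statistic == pytest.approx((c1 - c2) ** 2 * (l - 1), rel=1e-6)

    def test_null_rejection_rate_calibrated(self):
        n_sim, rej = 200, 0
        for s in range(n_sim):
            g = null_groups(2, 10, 30, seed=7000 + s)
            rej += l2_mean_test(g[0], g[1], B=199, seed=s).p_value <= 0.05
        se = np.sqrt(0.05 * 0.95 / n_sim)
        assert abs(rej / n_sim - 0.05) <= 2 * se

    def test_statistic_zero_iff_means_coincide(self):
        rng = np.random.default_rng(3)
        g1 = rng.normal(size=(5, 8))
        g2 = g1 + rng.normal(size=8)  # different mean curve
        assert l2_mean_test(g1, g2, B=9, seed=0).statistic > 0
        m = g1[0]
        ga = np.vstack([m + 1, m - 1])  # perturbations cancel: same sample mean
        gb = np.vstack([m + 2, m - 2])
        assert l2_mean_test(ga, gb, B=9, seed=0).statistic == pytest.approx(0.0, abs=1e-18)

    def test_mismatched_grids_rejected(self):
        with pytest.raises(ValueError):
            l2_mean_test(np.ones((3, 5)), np.ones((3, 6)), B=9, seed=0)

    def test_bootstrap_pvalues_in_range_and_uniform_under_null(self):
        # group size where the centered bootstrap's O(1/n) bias is negligible
        ps = []
        for s in range(500):
            g = null_groups(2, 60, 20, seed=20_000 + s)
            ps.append(l2_mean_test(g[0], g[1], B=199, seed=s).p_value)
        ps = np.asarray(ps)
        assert np.all((ps >= 1 / 200) & (ps <= 1.0))
        # approx uniform: compare to U(0,1) with discreteness slack
        assert stats.kstest(ps, "uniform").pvalue > 0.01


class TestRepeated:
    def test_singleton_summary(self, small_cohort):
        curves = [
            interpolate_to_seconds(r) for p in small_cohort.patients for r in p.recordings
        ]
        spec = MeanTestSpec("l2", B=49, pair=("early", "middle"))
        summ = repeated_test(curves, "x", spec, n_reps=1, seed=0)
        assert summ.count == 1
        assert summ.sd == 0.0
        assert summ.mean == summ.p_values[0]

    def test_strong_separation_rejects_every_repetition(self):
        cfg = small_cohort_config(
            stage_effect={"x": 8.0, "y": 7.0, "z": 0.2}, seed=17, durations=(40.0, 80.0)
        )
        curves = [
            interpolate_to_seconds(r)
            for p in generate_cohort(cfg).patients
            for r in p.recordings
        ]
        spec = MeanTestSpec("l2", B=99, pair=("early", "late"))
        summ = repeated_test(curves, "x", spec, n_reps=50, seed=1)
        assert summ.prop_leq_05 == 1.0

    def test_summary_fields_consistent(self):
        summ = PValueSummary.from_pvalues([0.01, 0.2, 0.04, 0.9])
        assert summ.count == 4
        assert summ.mean == pytest.approx(np.mean([0.01, 0.2, 0.04, 0.9]))
        assert summ.sd == pytest.approx(np.std([0.01, 0.2, 0.04, 0.9], ddof=1))
        assert summ.prop_leq_05 == pytest.approx(0.5)

    def test_monotone_power_in_effect_size(self):
        """Rejection of early-vs-late L2 grows with the generator's x effect."""
        props = []
        for effect in (0.0, 1.0, 6.0):
            cfg = small_cohort_config(
                stage_effect={"x": effect, "y": 0.5 * effect, "z": 0.1},
                seed=29,
                durations=(40.0, 70.0),
            )
            curves = [
                interpolate_to_seconds(r)
                for p in generate_cohort(cfg).patients
                for r in p.recordings
            ]
            spec = MeanTestSpec("l2", B=99, pair=("early", "late"))
            props.append(
                repeated_test(curves, "x", spec, n_reps=100, seed=2).prop_leq_05
            )
        assert props[0] <= props[1] <= props[2]
        assert props[2] == 1.0
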