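import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from admixscan import scan
from admixscan.scan import (
    RiskModel,
    ancestry_prior,
    build_risk_models,
    case_control_z,
    correct_lod_subgroups,
    credible_interval,
    define_extremes,
    genome_wide_score,
    locus_lod,
    lod_matrix,
    model_average_lod,
)


class TestRiskModels:
    def test_eighteen_prespecified_models(self):
        models = build_risk_models()
        assert len(models) == 18

    def test_family_two_uses_reciprocal_zero_copy_risk(self):
        models = build_risk_models()
        m = [m for m in models if m.r1 == 0.5 and m.r0 == 2.0]
        assert len(m) == 1

    def test_null_model_excluded(self):
        assert all(m.risks.tolist() != [1.0, 1.0, 1.0] for m in build_risk_models())

    def test_family_one_two_copy_risk_is_log_linear(self):
        models = build_risk_models()
        for m in models[:12]:
            assert m.r2 == pytest.approx(m.r1**2 / m.r0)

    def test_nonpositive_risk_rejected(self):
        with pytest.raises(ValueError):
            RiskModel(1.0, 0.0, 1.0)


class TestLocusLod:
    def test_null_model_gives_zero(self):
        rng = np.random.default_rng(0)
        gamma = rng.dirichlet([1, 1, 1], size=20)
        theta = rng.uniform(0.6, 0.9, size=20)
        assert locus_lod(gamma, theta, RiskModel(1, 1, 1)) == pytest.approx(0.0)

    def test_gamma_equal_to_prior_gives_zero(self):
        theta = np.array([0.7, 0.85, 0.9])
        gamma = ancestry_prior(theta)
        for m in build_risk_models():
            assert locus_lod(gamma, theta, m) == pytest.approx(0.0, abs=1e-12)

    def test_hand_computed_single_case(self):
        # theta 0.5, gamma (0,0,1), risks (1,2,4): f = 4 / 2.25
        lod = locus_lod(np.array([[0, 0, 1.0]]), np.array([0.5]), RiskModel(1, 2, 4))
        assert lod == pytest.approx(np.log10(4 / 2.25), abs=1e-6)
        assert lod == pytest.approx(0.2499, abs=5e-4)

    def test_additive_over_cases(self):
        rng = np.random.default_rng(1)
        gamma = rng.dirichlet([2, 3, 1], size=10)
        theta = rng.uniform(0.6, 0.9, size=10)
        m = RiskModel(1, 0.5, 0.25)
        total = locus_lod(gamma, theta, m)
        parts = sum(locus_lod(gamma[i : i + 1], theta[i : i + 1], m) for i in range(10))
        assert total == pytest.approx(parts)

    def test_locus_relabeling_permutes_lod_rows(self):
        rng = np.random.default_rng(2)
        gamma = rng.dirichlet([2, 3, 1], size=(8, 5))
        theta = rng.uniform(0.6, 0.9, size=8)
        models = build_risk_models()[:4]
        lods = lod_matrix(gamma, theta, models)
        perm = np.array([3, 1, 4, 0, 2])
        lods_p = lod_matrix(gamma[:, perm], theta, models)
        np.testing.assert_allclose(lods_p, lods[perm], atol=1e-12)

    def test_invalid_gamma_rejected(self):
        with pytest.raises(ValueError):
            locus_lod(np.array([[0.5, 0.1, 0.1]]), np.array([0.5]), RiskModel(1, 2, 4))


class TestGenomeWideScore:
    def test_all_zero_lods_give_zero(self):
        assert genome_wide_score(np.zeros(50)) == pytest.approx(0.0)

    def test_single_locus_identity(self):
        assert genome_wide_score(np.array([2.31])) == pytest.approx(2.31)

    def test_two_locus_average_on_bayes_factor_scale(self):
        assert genome_wide_score(np.array([1.0, 0.0])) == pytest.approx(np.log10(5.5))

    def test_models_averaged_before_loci(self):
        lods = np.array([[1.0, 0.0], [0.0, 0.0]])
        per_locus = model_average_lod(lods)
        np.testing.assert_allclose(per_locus, [np.log10(5.5), 0.0])
        assert genome_wide_score(lods) == pytest.approx(np.log10((5.5 + 1) / 2))

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            genome_wide_score(np.array([]))

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.floats(min_value=-5, max_value=8))
    def test_single_locus_single_model_is_identity(self, lod):
        assert genome_wide_score(np.array([[lod]])) == pytest.approx(lod, abs=1e-9)


class TestSubgroupCorrection:
    def test_published_arithmetic(self):
        # likelihood ratio 10^5.47 = 295120.9, halved -> LOD 5.17
        assert 10**5.47 == pytest.approx(295120.9, abs=0.5)
        assert round(correct_lod_subgroups(5.47, 2), 2) == 5.17
        assert 10 ** correct_lod_subgroups(5.47, 2) == pytest.approx(147560.5, abs=0.5)

    def test_identity_and_log_arithmetic(self):
        assert correct_lod_subgroups(3.3, 1) == pytest.approx(3.3)
        assert correct_lod_subgroups(3.0, 10) == pytest.approx(2.0)

    def test_invalid_subgroup_count(self):
        with pytest.raises(ValueError):
            correct_lod_subgroups(3.0, 0)


class TestCaseControlZ:
    def test_identical_groups_give_zero(self):
        gamma = np.tile([0.3, 0.5, 0.2], (5, 1))
        theta = np.full(5, 0.8)
        assert case_control_z(gamma, gamma, theta, theta) == pytest.approx(0.0)

    def test_sign_flips_under_group_swap(self):
        rng = np.random.default_rng(3)
        gc = rng.dirichlet([3, 2, 1], size=30)
        gt = rng.dirichlet([1, 2, 3], size=30)
        th = rng.uniform(0.6, 0.9, size=60)
        z1 = case_control_z(gc, gt, th[:30], th[30:])
        z2 = case_control_z(gt, gc, th[30:], th[:30])
        assert z1 == pytest.approx(-z2)
        assert z1 != 0

    def test_small_group_rejected(self):
        g = np.tile([0.3, 0.5, 0.2], (2, 1))
        with pytest.raises(ValueError):
            case_control_z(g[:1], g, np.array([0.8]), np.array([0.8, 0.8]))

    def test_null_distribution_is_standard_normal(self):
        # truth-level simulation: both groups drawn from the ancestry prior
        rng = np.random.default_rng(4)
        n, L = 200, 500
        zs = np.empty(L)
        theta_c = rng.beta(11.6, 2.5, size=n)
        theta_t = rng.beta(11.6, 2.5, size=n)
        for j in range(L):
            ec = rng.binomial(2, 1 - theta_c)
            et = rng.binomial(2, 1 - theta_t)
            gc = np.eye(3)[ec]
            gt = np.eye(3)[et]
            zs[j] = case_control_z(gc, gt, theta_c, theta_t)
        assert abs(zs.mean()) < 0.1
        assert 0.85 <= zs.std(ddof=1) <= 1.15

    def test_genome_wide_significance_threshold(self):
        from admixscan.scan import THRESHOLDS

        assert THRESHOLDS["cc_z"] == 4.06


class TestDefineExtremes:
    def test_small_integer_split(self):
        x = np.arange(20.0)
        cases, controls = define_extremes(x, "high_is_case", 0.15)
        assert len(cases) == 3 and len(controls) == 3
        assert set(cases) == {17, 18, 19} and set(controls) == {0, 1, 2}

    @pytest.mark.parametrize("n,expected", [(1737, (261, 260)), (1001, (151, 150))])
    def test_published_cohort_splits(self, n, expected):
        rng = np.random.default_rng(5)
        cases, controls = define_extremes(rng.normal(size=n), "low_is_case", 0.15)
        assert (len(cases), len(controls)) == expected

    def test_direction_reversal_swaps_groups(self):
        x = np.random.default_rng(6).normal(size=20)
        c1, q1 = define_extremes(x, "high_is_case", 0.15)
        c2, q2 = define_extremes(x, "low_is_case", 0.15)
        np.testing.assert_array_equal(c1, q2)
        np.testing.assert_array_equal(q1, c2)

    @pytest.mark.parametrize("frac", [0.0, 0.5, -0.1])
    def test_invalid_fraction_rejected(self, frac):
        with pytest.raises(ValueError):
            define_extremes(np.arange(10.0), "high_is_case", frac)

    def test_missing_values_rejected(self):
        with pytest.raises(ValueError):
            define_extremes(np.array([1.0, np.nan]), "high_is_case", 0.15)


class TestCredibleInterval:
    def test_uniform_density_central_interval(self):
        pos = np.linspace(0, 100e6, 101)
        lo, hi = credible_interval(pos, np.ones(101), 0.95)
        assert lo == pytest.approx(2.5e6, rel=1e-6)
        assert hi == pytest.approx(97.5e6, rel=1e-6)

    def test_point_mass_degenerates_to_peak_neighbourhood(self):
        pos = np.arange(10) * 1e6
        bf = np.full(10, 1e-12)
        bf[4] = 1.0
        lo, hi = credible_interval(pos, bf, 0.95)
        assert 3e6 < lo < 4e6 and 4e6 < hi < 5e6

    def test_full_coverage_spans_markers(self):
        pos = np.array([5e6, 9e6, 20e6])
        assert credible_interval(pos, np.array([1.0, 2.0, 1.0]), 1.0) == (5e6, 20e6)

    def test_mass_outside_each_tail_matches_coverage(self):
        rng = np.random.default_rng(7)
        pos = np.sort(rng.uniform(0, 50e6, size=40))
        bf = rng.gamma(2.0, size=40)
        lo, hi = credible_interval(pos, bf, 0.9)
        grid = np.linspace(pos[0], pos[-1], 200001)
        dens = np.interp(grid, pos, bf)
        dens /= np.trapezoid(dens, grid)
        mass_below = np.trapezoid(np.where(grid <= lo, dens, 0), grid)
        mass_above = np.trapezoid(np.where(grid >= hi, dens, 0), grid)
        assert mass_below == pytest.approx(0.05, abs=2e-3)
        assert mass_above == pytest.approx(0.05, abs=2e-3)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            credible_interval(np.array([1.0]), np.array([1.0]))
        with pytest.raises(ValueError):
            credible_interval(np.array([1.0, 2.0]), np.array([0.0, 0.0]))
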