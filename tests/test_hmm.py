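import itertools

import numpy as np
import pandas as pd
import pytest

from admixscan import _hmm_core
from admixscan.cohort import SimParams, simulate_cohort
from admixscan.hmm import (
    default_arms,
    estimate_theta_moment,
    forward_backward,
    local_african_dosage,
    mcmc_fit,
    regional_ancestry,
)
from admixscan.panel import AncestralPanel, generate_aim_panel


def _panel(freq_a, freq_e, pos_cm, chrom=None):
    L = len(freq_a)
    chrom = chrom or [1] * L
    return AncestralPanel(
        pd.DataFrame(
            {
                "snp_id": [f"m{i}" for i in range(L)],
                "chrom": chrom,
                "pos_bp": (np.asarray(pos_cm) * 1e6).astype(int) + 1,
                "pos_cM": pos_cm,
                "freq_A": freq_a,
                "freq_E": freq_e,
                "n_A": [200] * L,
                "n_E": [200] * L,
            }
        )
    )


def _path_sum_oracle(geno, panel, theta, lam):
    """Posterior over European counts by exhaustive per-copy path enumeration."""
    L = len(panel)
    d = panel.morgan_gaps()
    starts = panel.chrom_start_mask()
    pi = {1: theta, 0: 1 - theta}  # copy state 1 = African

    def path_prob(path):
        p = pi[path[0]]
        for k in range(1, L):
            if starts[k]:
                p *= pi[path[k]]
            else:
                stay = np.exp(-lam * d[k])
                p *= stay * (path[k] == path[k - 1]) + (1 - stay) * pi[path[k]]
        return p

    post = np.zeros((L, 3))
    total = 0.0
    for c1 in itertools.product([0, 1], repeat=L):
        for c2 in itertools.product([0, 1], repeat=L):
            pr = path_prob(c1) * path_prob(c2)
            for j in range(L):
                f1 = panel.freq_A[j] if c1[j] == 1 else panel.freq_E[j]
                f2 = panel.freq_A[j] if c2[j] == 1 else panel.freq_E[j]
                g = geno[j]
                if g < 0:
                    em = 1.0
                elif g == 0:
                    em = (1 - f1) * (1 - f2)
                elif g == 1:
                    em = f1 * (1 - f2) + (1 - f1) * f2
                else:
                    em = f1 * f2
                pr *= em
            total += pr
            for j in range(L):
                euro = (c1[j] == 0) + (c2[j] == 0)
                post[j, euro] += pr
    return post / total


class TestForwardBackward:
    def test_uninformative_emission_returns_binomial_prior(self):
        panel = _panel([0.4], [0.4], [0.0])
        for theta in (0.3, 0.8):
            gamma = forward_backward(np.array([1]), panel, theta, 6.0)
            q = [theta**2, 2 * theta * (1 - theta), (1 - theta) ** 2]
            np.testing.assert_allclose(gamma[0], q, atol=1e-12)

    def test_distant_markers_decorrelate(self):
        # 50 Morgans between markers: posterior at marker 2 ignores marker 1
        panel = _panel([0.9, 0.9], [0.1, 0.1], [0.0, 5000.0])
        g_ref = forward_backward(np.array([-1, 1]), panel, 0.7, 1.0)
        for g1 in (0, 1, 2):
            gamma = forward_backward(np.array([g1, 1]), panel, 0.7, 1.0)
            np.testing.assert_allclose(gamma[1], g_ref[1], atol=1e-8)

    @pytest.mark.parametrize(
        "case",
        [
            # the 3-marker hand case: theta .5, lambda 1, 0.5 Morgan gaps
            dict(fa=[0.9, 0.8, 0.9], fe=[0.1, 0.2, 0.1], cm=[0.0, 50.0, 100.0],
                 geno=[2, 1, 0], theta=0.5, lam=1.0),
            dict(fa=[0.95, 0.7, 0.6, 0.9], fe=[0.05, 0.25, 0.5, 0.2],
                 cm=[0.0, 10.0, 35.0, 40.0], geno=[0, -1, 2, 1], theta=0.82, lam=6.0),
            dict(fa=[0.9, 0.8, 0.85, 0.7, 0.95], fe=[0.2, 0.1, 0.3, 0.4, 0.05],
                 cm=[0.0, 20.0, 20.5, 60.0, 95.0], geno=[1, 2, 2, 0, 1],
                 theta=0.65, lam=4.0),
        ],
    )
    def test_matches_exhaustive_path_enumeration(self, case):
        panel = _panel(case["fa"], case["fe"], case["cm"])
        geno = np.array(case["geno"])
        gamma = forward_backward(geno, panel, case["theta"], case["lam"])
        oracle = _path_sum_oracle(geno, panel, case["theta"], case["lam"])
        assert np.abs(gamma - oracle).max() < 1e-10

    def test_label_symmetry(self):
        # swapping ancestral populations maps theta -> 1-theta, gamma(a) -> gamma(2-a)
        panel = _panel([0.9, 0.7, 0.8], [0.1, 0.4, 0.2], [0.0, 15.0, 42.0])
        swapped = _panel([0.1, 0.4, 0.2], [0.9, 0.7, 0.8], [0.0, 15.0, 42.0])
        geno = np.array([2, 1, 0])
        g = forward_backward(geno, panel, 0.8, 6.0)
        gs = forward_backward(geno, swapped, 0.2, 6.0)
        np.testing.assert_allclose(g, gs[:, ::-1], atol=1e-12)

    def test_negative_gap_rejected(self):
        panel = _panel([0.9, 0.8], [0.1, 0.2], [0.0, 10.0])
        with pytest.raises(ValueError):
            forward_backward(np.array([1, 1]), panel, 1.2, 6.0)


class TestDosageAndRegional:
    def test_local_dosage_arithmetic(self):
        gamma = np.array([[[1, 0, 0], [0, 0, 1], [0.2, 0.5, 0.3]]])
        assert local_african_dosage(gamma, 0)[0] == pytest.approx(2.0)
        assert local_african_dosage(gamma, 1)[0] == pytest.approx(0.0)
        assert local_african_dosage(gamma, 2)[0] == pytest.approx(0.9)

    def test_regional_uniform_prior(self):
        theta = 0.8
        q = np.array([theta**2, 2 * theta * (1 - theta), (1 - theta) ** 2])
        gamma = np.tile(q, (3, 5, 1))
        np.testing.assert_allclose(regional_ancestry(gamma, np.arange(5)), 0.8)

    def test_regional_hand_case(self):
        # E[EuroCount] = (0.4, 0.8) -> mean African fraction (2 - 0.6) / 2 = 0.7
        gamma = np.array([[[0.6, 0.4, 0.0], [0.3, 0.6, 0.1]]])
        assert regional_ancestry(gamma, [0, 1])[0] == pytest.approx(0.7)

    def test_empty_region_rejected(self):
        with pytest.raises(ValueError):
            regional_ancestry(np.ones((2, 3, 3)) / 3, [])

    def test_whole_genome_region_equals_paa(self, recovery_mcmc):
        _, _, post = recovery_mcmc
        whole = regional_ancestry(post.gamma, np.arange(post.gamma.shape[1]))
        np.testing.assert_allclose(whole, post.paa, atol=1e-9)

    def test_default_arms_partition_markers(self, small_panel):
        arms = default_arms(small_panel)
        allidx = np.sort(np.concatenate(list(arms.values())))
        np.testing.assert_array_equal(allidx, np.arange(len(small_panel)))


class TestMomentEstimator:
    def test_recovers_simulated_theta(self):
        panel = generate_aim_panel(300, 3, 0.75, seed=199)
        params = SimParams(n_individuals=150, seed=200)
        c = simulate_cohort(panel, params)
        est = estimate_theta_moment(c.genotypes, panel)
        err = est - c.theta_true
        assert abs(err.mean()) < 0.02  # unbiased
        assert np.mean(np.abs(err)) < 0.06  # root-L consistent at 300 AIMs

    def test_uninformative_panel_falls_back_to_half(self):
        panel = _panel([0.5, 0.5], [0.5, 0.5], [0.0, 10.0])
        est = estimate_theta_moment(np.array([[1, 2]]), panel)
        assert est[0] == pytest.approx(0.5)


class TestMCMC:
    def test_same_seed_reproduces_output(self, small_panel):
        params = SimParams(n_individuals=25, seed=300)
        c = simulate_cohort(small_panel, params)
        a = mcmc_fit(c.genotypes, small_panel, seed=301)
        b = mcmc_fit(c.genotypes, small_panel, seed=301)
        np.testing.assert_array_equal(a.gamma, b.gamma)
        np.testing.assert_array_equal(a.paa, b.paa)
        np.testing.assert_array_equal(a.params.lambda_trace, b.params.lambda_trace)

    def test_uninformative_panel_keeps_prior_spread(self):
        panel = generate_aim_panel(40, 1, 0.75, seed=302)
        t = panel.table.copy()
        t["freq_E"] = t["freq_A"]  # no ancestry information at any marker
        flat = AncestralPanel(t)
        params = SimParams(n_individuals=30, seed=303)
        c = simulate_cohort(flat, params)
        post = mcmc_fit(c.genotypes, flat, seed=304)
        assert np.all(np.abs(post.paa - 0.5) < 0.25)

    def test_parameter_recovery(self, recovery_mcmc):
        _, _, post = recovery_mcmc
        assert 0.77 <= post.paa.mean() <= 0.83
        assert abs(post.params.lambda_mean - 6.0) <= 1.8  # within 30%

    def test_posterior_calibration(self, recovery_mcmc):
        _, cohort, post = recovery_mcmc
        conf = post.gamma.max(axis=2)
        call = post.gamma.argmax(axis=2)
        sel = (conf >= 0.8) & (conf <= 0.9)
        assert sel.sum() > 500
        hit = (call[sel] == cohort.true_ancestry[sel]).mean()
        assert 0.75 <= hit <= 0.95

    def test_marginal_consistency_paa_vs_gamma(self, recovery_mcmc):
        _, _, post = recovery_mcmc
        afr = 2 - (post.gamma[:, :, 1] + 2 * post.gamma[:, :, 2])
        np.testing.assert_allclose(afr.mean(axis=1) / 2, post.paa, atol=1e-6)

    def test_gamma_rows_are_distributions(self, recovery_mcmc):
        _, _, post = recovery_mcmc
        np.testing.assert_allclose(post.gamma.sum(axis=2), 1.0, atol=1e-9)
        assert post.gamma.min() >= 0


def test_compiled_and_numpy_sweeps_agree(small_panel):
    """The numba kernel and the vectorized fallback consume the same uniforms
    and must produce identical path statistics and matching marginals."""
    params = SimParams(n_individuals=15, seed=400)
    c = simulate_cohort(small_panel, params)
    geno = np.ascontiguousarray(c.genotypes)
    n, L = geno.shape
    rng = np.random.default_rng(401)
    theta = estimate_theta_moment(geno, small_panel)
    d = small_panel.morgan_gaps()
    starts = small_panel.chrom_start_mask()
    stay = np.exp(-6.0 * d)
    stay[starts] = 0.0
    u = rng.random((n, L, 4))
    results = []
    for fn in (_hmm_core._sweep_jit, _hmm_core._sweep_numpy):
        nA = np.zeros(n, np.int64)
        nd = np.zeros(n, np.int64)
        R = np.zeros(L, np.int64)
        vA, tA, vE, tE = (np.zeros(L, np.int64) for _ in range(4))
        ga = np.zeros((n, L, 3))
        fn(geno, stay, starts, theta, small_panel.freq_A.copy(), small_panel.freq_E.copy(),
           u, True, nA, nd, R, vA, tA, vE, tE, ga)
        results.append((nA, nd, R, vA, tA, vE, tE, ga))
    for a, b in list(zip(*results))[:7]:
        np.testing.assert_array_equal(a, b)
    np.testing.assert_allclose(results[0][7], results[1][7], atol=1e-12)
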