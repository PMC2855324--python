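from fractions import Fraction
from math import factorial

import numpy as np
import pandas as pd
import pytest

from admixscan import qc
from admixscan.cohort import SimParams, simulate_cohort
from admixscan.panel import AncestralPanel, generate_aim_panel, generate_ancestral_genotypes


def _panel_from(freq_a, freq_e, pos_bp, chrom=None, n=200):
    L = len(freq_a)
    chrom = chrom or [1] * L
    return AncestralPanel(
        pd.DataFrame(
            {
                "snp_id": [f"s{i}" for i in range(L)],
                "chrom": chrom,
                "pos_bp": pos_bp,
                "pos_cM": np.asarray(pos_bp) * 1e-6,
                "freq_A": freq_a,
                "freq_E": freq_e,
                "n_A": [n] * L,
                "n_E": [n] * L,
            }
        )
    )


class TestCallRateFilters:
    def test_sample_filter_examples(self):
        geno = np.zeros((3, 100), dtype=np.int8)
        geno[1, :7] = -1  # call rate 0.93 < 0.94
        geno[2, :6] = -1  # call rate 0.94, retained under strict <
        assert list(qc.sample_call_rate_filter(geno)) == [1]
        assert list(qc.sample_call_rate_filter(geno, threshold=0.0)) == []

    def test_snp_filter_counts(self):
        geno = np.zeros((100, 3), dtype=np.int8)
        geno[:6, 1] = -1  # snp call rate 0.94 < 0.95
        geno[:5, 2] = -1  # 0.95, retained
        assert list(qc.snp_call_rate_filter(geno)) == [1]


class TestDuplicateCheck:
    def test_identical_rows_flagged_with_lower_call_rate_excluded(self):
        rng = np.random.default_rng(0)
        geno = rng.integers(0, 3, size=(3, 100)).astype(np.int8)
        geno[2] = geno[0]
        geno[2, :5] = -1  # duplicate with lower call rate
        flagged = qc.duplicate_check(geno)
        assert len(flagged) == 1
        assert flagged[0]["i"] == 0 and flagged[0]["j"] == 2
        assert flagged[0]["concordance"] == pytest.approx(1.0)
        assert flagged[0]["exclude"] == 2

    def test_discordant_rows_not_flagged(self):
        geno = np.array([[0] * 50, [2] * 50], dtype=np.int8)
        assert qc.duplicate_check(geno) == []

    def test_partial_concordance_threshold(self):
        a = np.zeros(100, dtype=np.int8)
        b = np.zeros(100, dtype=np.int8)
        b[:20] = 1  # 80/100 agreement > 0.75
        assert len(qc.duplicate_check(np.vstack([a, b]))) == 1
        c = b.copy()
        c[20:25] = 1  # 75/100 agreement, not > 0.75
        assert qc.duplicate_check(np.vstack([a, c])) == []


class TestHetExcess:
    def test_closed_form_all_het_at_half_frequency(self):
        # 1000 SNPs with mixture p=0.5: Z = (1000-500)/sqrt(250) ~ 31.6
        panel = _panel_from([0.5] * 1000, [0.5] * 1000, np.arange(1, 1001) * 10_000)
        geno = np.ones((1, 1000), dtype=np.int8)
        z = qc.het_excess_z(geno, np.array([0.8]), panel)
        assert z[0] == pytest.approx(500 / np.sqrt(250), rel=1e-9)
        assert z[0] > 10

    def test_null_simulation_calibration(self):
        rng = np.random.default_rng(5)
        panel = generate_aim_panel(200, 1, 0.75, seed=6)
        theta = rng.beta(11.6, 2.5, size=500)
        p = theta[:, None] * panel.freq_A + (1 - theta[:, None]) * panel.freq_E
        geno = rng.binomial(2, p).astype(np.int8)
        z = qc.het_excess_z(geno, theta, panel)
        assert np.mean(np.abs(z) < 3) >= 0.99

    def test_no_snps_is_an_error(self):
        panel = _panel_from([], [], [])
        with pytest.raises(ValueError):
            qc.het_excess_z(np.zeros((2, 0), dtype=np.int8), np.array([0.8, 0.8]), panel)

    def test_all_missing_sample_gets_nan(self):
        panel = _panel_from([0.5, 0.5], [0.5, 0.5], [100, 300000])
        geno = np.array([[1, 1], [-1, -1]], dtype=np.int8)
        z = qc.het_excess_z(geno, np.array([0.8, 0.8]), panel)
        assert np.isnan(z[1]) and np.isfinite(z[0])


def _hwe_exact_oracle(n_AA, n_Aa, n_aa):
    """Exact-rational enumeration of the conditional HWE test."""
    n = n_AA + n_Aa + n_aa
    n_a = 2 * n_aa + n_Aa
    rare = min(n_a, 2 * n_AA + n_Aa)
    if rare == 0:
        return 1.0
    probs = {}
    for het in range(rare % 2, rare + 1, 2):
        homr = (rare - het) // 2
        homc = n - het - homr
        # multinomial weight of a genotype configuration given the allele counts
        probs[het] = Fraction(2**het, factorial(homr) * factorial(het) * factorial(homc))
    total = sum(probs.values())
    probs = {h: p / total for h, p in probs.items()}
    obs = probs[n_Aa]
    return float(sum(p for p in probs.values() if p <= obs))


class TestHWEExact:
    @pytest.mark.parametrize(
        "counts",
        [(25, 50, 25), (21, 58, 21), (40, 20, 40), (5, 5, 90), (50, 0, 50), (1, 10, 1)],
    )
    def test_matches_exact_rational_enumeration(self, counts):
        assert qc.hwe_exact_test(*counts) == pytest.approx(_hwe_exact_oracle(*counts), rel=1e-9)

    def test_extreme_disequilibrium_essentially_zero(self):
        assert qc.hwe_exact_test(50, 0, 50) < 1e-20

    def test_monomorphic_returns_one(self):
        assert qc.hwe_exact_test(10, 0, 0) == 1.0

    def test_filter_requires_equilibrium_in_both_panels(self):
        ok, pa, pe = qc.hwe_filter_panels((25, 50, 25), (50, 0, 50))
        assert not ok and pa > 0.01 and pe < 0.01


class TestFreqcheck:
    def test_observed_at_mixture_passes_with_zero_statistic(self):
        p_mix = 0.8 * 0.9 + 0.2 * 0.1
        ok, z, p = qc.freqcheck(0.9, 0.1, 200, 200, int(p_mix * 2000), 2000, 0.8)
        assert ok and abs(z) < 0.05

    def test_gross_mixture_violation_fails(self):
        ok, z, p = qc.freqcheck(0.9, 0.1, 200, 200, 200, 2000, 0.8)
        assert not ok and abs(z) > 20

    def test_null_simulation_pass_rate(self):
        # freq_A == freq_E: mixture frequency exact for every theta
        rng = np.random.default_rng(7)
        passes = 0
        for _ in range(1000):
            cnt = rng.binomial(2000, 0.3)
            ok, _, _ = qc.freqcheck(0.3, 0.3, 200, 200, int(cnt), 2000, 0.77)
            passes += ok
        assert passes >= 995

    def test_empty_observation_rejected(self):
        with pytest.raises(ValueError):
            qc.freqcheck(0.9, 0.1, 200, 200, 0, 0, 0.8)


class TestLdcheck:
    def test_less_informative_proximal_marker_removed(self):
        panel = _panel_from([0.9, 0.6], [0.1, 0.4], [100_000, 200_000])
        kept = qc.ldcheck(panel)
        assert list(panel.snp_id[kept]) == ["s0"]

    def test_distant_markers_all_retained_without_ld_data(self):
        panel = _panel_from([0.9, 0.9, 0.9], [0.1, 0.1, 0.1], [100_000, 400_000, 700_000])
        assert len(qc.ldcheck(panel)) == 3

    def test_chain_of_three_keeps_middle(self):
        # In = (low, high, low) at 0 / 150 kb / 300 kb: both flanks fall
        panel = _panel_from([0.7, 0.95, 0.7], [0.3, 0.05, 0.3], [1, 150_001, 300_001])
        kept = qc.ldcheck(panel)
        assert list(panel.snp_id[kept]) == ["s1"]

    def test_row_order_invariance(self):
        panel = generate_aim_panel(40, 2, 0.75, seed=9, spacing_bp=150_000)
        kept_ids = set(panel.snp_id[qc.ldcheck(panel)])
        shuffled = AncestralPanel(
            panel.table.sample(frac=1.0, random_state=1).reset_index(drop=True)
        )
        kept_shuffled = set(shuffled.snp_id[qc.ldcheck(shuffled)])
        assert kept_ids == kept_shuffled

    def test_true_ld_detected_and_pruned(self):
        # duplicate a marker so its panel genotypes are perfectly correlated;
        # 500 kb apart: beyond the 200 kb distance rule, inside the LD horizon
        panel = _panel_from([0.9, 0.85], [0.1, 0.15], [100_000, 600_000])
        rng = np.random.default_rng(10)
        ga = rng.binomial(2, 0.9, size=(100, 1))
        ge = rng.binomial(2, 0.1, size=(100, 1))
        anc = {"A": np.hstack([ga, ga]).astype(np.int8), "E": np.hstack([ge, ge]).astype(np.int8)}
        kept = qc.ldcheck(panel, ancestral_genotypes=anc)
        assert list(panel.snp_id[kept]) == ["s0"]  # higher informativeness wins


class TestCascade:
    def test_clean_cohort_survives_with_alpha_tail_losses_only(self):
        panel = generate_aim_panel(120, 2, 0.75, seed=50)
        params = SimParams(n_individuals=300, seed=51)
        cohort = simulate_cohort(panel, params)
        ancestral = generate_ancestral_genotypes(panel, seed=52)
        report = qc.run_qc(cohort.genotypes, panel, ancestral_genotypes=ancestral)
        assert len(report.kept_samples) == 300
        # HWE (alpha 0.01 x 2 panels), freqcheck (0.001) and the gated ldcheck
        # together should lose only a few markers out of 120
        assert len(report.kept_snps) >= 112
        stages = list(report.stage_counts)
        assert stages == [
            "input", "snp_call_rate", "sample_call_rate", "duplicates",
            "het_excess", "hwe", "freqcheck", "ldcheck",
        ]
        counts = [c["snps"] for c in report.stage_counts.values()]
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_injected_defects_are_caught_with_one_reason_each(self):
        panel = generate_aim_panel(100, 2, 0.75, seed=53)
        params = SimParams(n_individuals=120, seed=54)
        cohort = simulate_cohort(panel, params)
        geno = cohort.genotypes.copy()
        geno[0, :20] = -1            # sample call rate 0.80
        geno[2] = geno[1]            # duplicate pair
        geno[3] = 1                  # heterozygous everywhere
        report = qc.run_qc(geno, panel, sample_ids=np.array([f"S{i}" for i in range(120)]))
        tab = report.sample_table.set_index("sample_id")
        assert tab.loc["S0", "reason"] == "call_rate"
        assert tab.loc["S2", "reason"] == "duplicate"
        assert tab.loc["S3", "reason"] == "het_excess"
        assert (report.sample_table.reason != "").sum() == 3
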