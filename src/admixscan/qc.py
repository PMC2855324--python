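"""Sample- and SNP-level quality-control filters for admixture scans.

The cascade mirrors standard admixture-scan practice: drop low-call-rate
SNPs and samples, flag duplicate samples and heterozygosity outliers, then
apply three marker filters - Hardy-Weinberg equilibrium in each ancestral
panel, a "freqcheck" that the admixed allele frequency is consistent with
the ancestry-weighted mixture of the ancestral frequencies, and an
"ldcheck" that iteratively prunes markers closer than 200 kb or in
detectable ancestral-panel LD, keeping the more ancestry-informative member.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy.special import gammaln
from scipy.stats import norm
from scipy.stats import t as _tdist

from .panel import AncestralPanel, rosenberg_informativeness

MISSING = -1


# --------------------------------------------------------------------------- #
# call-rate and sample-level filters
# --------------------------------------------------------------------------- #

def sample_call_rate(genotypes: np.ndarray) -> np.ndarray:
    geno = np.atleast_2d(genotypes)
    return (geno >= 0).mean(axis=1)


def snp_call_rate(genotypes: np.ndarray) -> np.ndarray:
    geno = np.atleast_2d(genotypes)
    return (geno >= 0).mean(axis=0)


def sample_call_rate_filter(genotypes: np.ndarray, threshold: float = 0.94) -> np.ndarray:
    """Indices of samples whose fraction of non-missing calls is below threshold."""
    return np.flatnonzero(sample_call_rate(genotypes) < threshold)


def snp_call_rate_filter(genotypes: np.ndarray, threshold: float = 0.95) -> np.ndarray:
    """Indices of SNPs whose genotyping success rate is below threshold."""
    return np.flatnonzero(snp_call_rate(genotypes) < threshold)


def duplicate_check(genotypes: np.ndarray, threshold: float = 0.75) -> list[dict]:
    """Flag sample pairs with genotype concordance above threshold.

    Concordance = identical calls / jointly non-missing calls. For each
    flagged pair the member with the lower call rate is marked for exclusion
    (ties broken by sample order). Returns a list of dicts with keys
    i, j, concordance, exclude.
    """
    geno = np.atleast_2d(genotypes)
    n = geno.shape[0]
    if n < 2:
        return []
    cr = sample_call_rate(geno)
    obs = geno >= 0
    flagged = []
    for i in range(n - 1):
        joint = obs[i] & obs[i + 1 :]
        match = joint & (geno[i] == geno[i + 1 :])
        denom = joint.sum(axis=1)
        with np.errstate(invalid="ignore"):
            conc = np.where(denom > 0, match.sum(axis=1) / np.maximum(denom, 1), 0.0)
        for off in np.flatnonzero(conc > threshold):
            j = i + 1 + off
            worse = j if cr[j] < cr[i] else i if cr[i] < cr[j] else j
            flagged.append(
                {"i": i, "j": int(j), "concordance": float(conc[off]), "exclude": int(worse)}
            )
    return flagged


def het_excess_z(
    genotypes: np.ndarray, theta_hat: np.ndarray, panel: AncestralPanel
) -> np.ndarray:
    """Z-score for excess/deficiency of heterozygous calls per sample.

    Under stationary two-way admixture the two alleles of an individual with
    African proportion theta are i.i.d. Bernoulli with mixture frequency
    p = theta*freq_A + (1-theta)*freq_E, so the per-SNP heterozygosity
    probability is h = 2p(1-p) with Bernoulli variance h(1-h). The Z sums
    over the sample's non-missing SNPs; Z > 10 conventionally indicates a
    parent of non-admixed ancestry. All-missing samples get Z = nan.
    """
    geno = np.atleast_2d(genotypes)
    if geno.shape[1] == 0:
        raise ValueError("no SNPs available for the heterozygosity check")
    th = np.asarray(theta_hat, float)[:, None]
    p = th * panel.freq_A[None, :] + (1 - th) * panel.freq_E[None, :]
    h = 2 * p * (1 - p)
    obs = geno >= 0
    obs_het = (geno == 1) & obs
    exp_het = np.where(obs, h, 0.0).sum(axis=1)
    var_het = np.where(obs, h * (1 - h), 0.0).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (obs_het.sum(axis=1) - exp_het) / np.sqrt(var_het)
    z[obs.sum(axis=1) == 0] = np.nan
    return z


# --------------------------------------------------------------------------- #
# SNP filters
# --------------------------------------------------------------------------- #

def hwe_exact_test(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Exact conditional Hardy-Weinberg test p-value.

    Conditions on the observed allele counts and sums the probabilities of
    all heterozygote counts no more probable than the observed one (the
    standard exact HWE test). Monomorphic markers return 1.
    """
    if min(n_AA, n_Aa, n_aa) < 0:
        raise ValueError("genotype counts must be >= 0")
    n = n_AA + n_Aa + n_aa
    if n == 0:
        raise ValueError("no genotypes")
    n_a = 2 * n_aa + n_Aa  # copies of one allele
    n_A = 2 * n_AA + n_Aa
    rare = min(n_a, n_A)
    if rare == 0:
        return 1.0

    hets = np.arange(rare % 2, rare + 1, 2)  # feasible het counts share the parity of rare
    homr = (rare - hets) // 2
    homc = n - hets - homr
    # log P(het | allele counts) up to a constant
    logp = hets * np.log(2.0) - (gammaln(hets + 1) + gammaln(homr + 1) + gammaln(homc + 1))
    logp -= logp.max()
    p = np.exp(logp)
    p /= p.sum()
    p_obs = p[np.flatnonzero(hets == n_Aa)][0]
    return float(min(1.0, p[p <= p_obs * (1 + 1e-12)].sum()))


def hwe_filter_panels(
    counts_A: tuple[int, int, int], counts_E: tuple[int, int, int], alpha: float = 0.01
) -> tuple[bool, float, float]:
    """Marker passes when exact HWE p > alpha in *both* ancestral panels."""
    p_a = hwe_exact_test(*counts_A)
    p_e = hwe_exact_test(*counts_E)
    return (p_a > alpha and p_e > alpha, p_a, p_e)


def freqcheck(
    freq_A: float,
    freq_E: float,
    n_A: int,
    n_E: int,
    obs_count: int,
    obs_n: int,
    theta_bar: float,
    alpha: float = 0.001,
) -> tuple[bool, float, float]:
    """Mixture-consistency test of the admixed allele frequency.

    Two-sided Z test of the observed admixed allele count against
    p_mix = theta_bar*freq_A + (1-theta_bar)*freq_E, with the variance
    widened by the sampling error of the finite ancestral panels
    (theta^2 fA(1-fA)/n_A + (1-theta)^2 fE(1-fE)/n_E). Returns
    (pass, z, p); fails when p <= alpha.
    """
    if obs_n <= 0:
        raise ValueError("obs_n must be positive")
    if not (0 <= obs_count <= obs_n):
        raise ValueError("need 0 <= obs_count <= obs_n")
    p_mix = theta_bar * freq_A + (1 - theta_bar) * freq_E
    var = (
        p_mix * (1 - p_mix) / obs_n
        + theta_bar**2 * freq_A * (1 - freq_A) / n_A
        + (1 - theta_bar) ** 2 * freq_E * (1 - freq_E) / n_E
    )
    obs_freq = obs_count / obs_n
    if var <= 0:
        z = 0.0 if obs_freq == p_mix else np.inf * np.sign(obs_freq - p_mix)
    else:
        z = (obs_freq - p_mix) / np.sqrt(var)
    p = 2 * norm.sf(abs(z)) if np.isfinite(z) else 0.0
    return (p > alpha, float(z), float(p))


def _detectable_r2(genotypes: np.ndarray, i: int, j: int, alpha: float = 0.001) -> float:
    """Squared genotype correlation in one reference panel, or 0 if not *detectable*.

    Detectability is a two-sided correlation test at ``alpha``: with the small
    reference panels behind an AIM set, raw r-squared has heavy sampling tails
    (r^2 > 0.05 occurs for ~8% of truly independent pairs at 60 diploids), so
    LD is only asserted when the correlation is also significantly nonzero.
    """
    g = genotypes[:, [i, j]].astype(float)
    ok = (g >= 0).all(axis=1)
    g = g[ok]
    n = len(g)
    if n < 4 or g[:, 0].std() == 0 or g[:, 1].std() == 0:
        return 0.0
    r = float(np.corrcoef(g[:, 0], g[:, 1])[0, 1])
    if abs(r) >= 1.0:
        return r * r
    t = abs(r) * np.sqrt((n - 2) / (1 - r * r))
    if 2 * _tdist.sf(t, df=n - 2) >= alpha:
        return 0.0
    return r * r


def ldcheck(
    panel: AncestralPanel,
    ancestral_genotypes: Optional[dict] = None,
    window_bp: int = 200_000,
    r2_max: float = 0.05,
    metric: str = "rosenberg",
    ld_horizon_bp: int = 1_000_000,
) -> np.ndarray:
    """Iteratively prune proximal or LD'd markers, keeping the more informative.

    While any retained pair on one chromosome is within ``window_bp`` or has
    detectable r-squared above ``r2_max`` in either ancestral panel (when
    ancestral genotypes are provided), the least informative marker involved
    in any violation is removed. LD is only evaluated for pairs within
    ``ld_horizon_bp``: in outbred ancestral populations LD decays within
    ~1 Mb, and testing distant pairs would only accumulate sampling false
    positives. Informativeness is Rosenberg's In by default, or the absolute
    frequency difference with ``metric="absdiff"``. Ties are broken by
    (chrom, pos_bp, snp_id), which makes the result invariant to input row
    order. Returns the retained marker indices (panel order).
    """
    L = len(panel)
    if L == 0:
        return np.arange(0)
    if metric == "rosenberg":
        info = rosenberg_informativeness(panel.freq_A, panel.freq_E)
    elif metric == "absdiff":
        info = np.abs(panel.freq_A - panel.freq_E)
    else:
        raise ValueError(f"unknown informativeness metric {metric!r}")

    chrom, pos = panel.chrom, panel.pos_bp
    retained = np.ones(L, dtype=bool)

    def violations() -> set[int]:
        bad: set[int] = set()
        idx = np.flatnonzero(retained)
        for c in np.unique(chrom[idx]):
            on = idx[chrom[idx] == c]
            p = pos[on]
            close = np.diff(p) <= window_bp  # sorted within chromosome
            for k in np.flatnonzero(close):
                bad.add(int(on[k]))
                bad.add(int(on[k + 1]))
            if ancestral_genotypes is not None:
                for a in range(len(on)):
                    for b in range(a + 1, len(on)):
                        if p[b] - p[a] > ld_horizon_bp:
                            break
                        r2 = max(
                            _detectable_r2(g, on[a], on[b])
                            for g in ancestral_genotypes.values()
                        )
                        if r2 > r2_max:
                            bad.add(int(on[a]))
                            bad.add(int(on[b]))
        return bad

    while True:
        bad = violations()
        if not bad:
            break
        order = sorted(bad, key=lambda k: (info[k], chrom[k], pos[k], panel.snp_id[k]))
        retained[order[0]] = False
    return np.flatnonzero(retained)


# --------------------------------------------------------------------------- #
# the cascade
# --------------------------------------------------------------------------- #

@dataclass
class QCReport:
    """Outcome of the QC cascade: per-sample and per-SNP tables plus stage counts."""

    sample_table: pd.DataFrame
    snp_table: pd.DataFrame
    stage_counts: dict = field(default_factory=dict)
    kept_samples: np.ndarray = field(default_factory=lambda: np.arange(0))
    kept_snps: np.ndarray = field(default_factory=lambda: np.arange(0))


def run_qc(
    genotypes: np.ndarray,
    panel: AncestralPanel,
    ancestral_genotypes: Optional[dict] = None,
    sample_ids: Optional[np.ndarray] = None,
    sample_cr_threshold: float = 0.94,
    snp_cr_threshold: float = 0.95,
    dup_threshold: float = 0.75,
    het_z_threshold: float = 10.0,
    hwe_alpha: float = 0.01,
    freqcheck_alpha: float = 0.001,
    ld_window_bp: int = 200_000,
    ld_r2_max: float = 0.05,
) -> QCReport:
    """Run the full QC cascade and report what survived each stage.

    Stage order: SNP call rate -> sample call rate -> duplicates ->
    heterozygosity excess -> ancestral-panel HWE (needs ancestral genotypes;
    skipped otherwise) -> freqcheck -> ldcheck. Every exclusion carries one
    primary reason; the stage_counts dict records the surviving sample and
    SNP counts after each stage.
    """
    from .hmm import estimate_theta_moment

    geno = np.atleast_2d(genotypes)
    n, L = geno.shape
    if sample_ids is None:
        sample_ids = np.array([f"S{i:05d}" for i in range(n)])

    snp_reason = np.array([""] * L, dtype=object)
    sample_reason = np.array([""] * n, dtype=object)
    counts = {"input": {"samples": n, "snps": L}}

    # SNP call rate
    s_cr = snp_call_rate(geno)
    for j in snp_call_rate_filter(geno, snp_cr_threshold):
        snp_reason[j] = "call_rate"
    counts["snp_call_rate"] = {"samples": n, "snps": int((snp_reason == "").sum())}

    # sample call rate (on SNPs surviving the call-rate stage)
    snp_ok = snp_reason == ""
    cr = sample_call_rate(geno[:, snp_ok]) if snp_ok.any() else np.zeros(n)
    for i in np.flatnonzero(cr < sample_cr_threshold):
        sample_reason[i] = "call_rate"
    counts["sample_call_rate"] = {"samples": int((sample_reason == "").sum()), "snps": int(snp_ok.sum())}

    # duplicates
    dup_partner = np.array([""] * n, dtype=object)
    for pair in duplicate_check(geno[:, snp_ok], dup_threshold):
        dup_partner[pair["i"]] = sample_ids[pair["j"]]
        dup_partner[pair["j"]] = sample_ids[pair["i"]]
        if sample_reason[pair["exclude"]] == "":
            sample_reason[pair["exclude"]] = "duplicate"
    counts["duplicates"] = {"samples": int((sample_reason == "").sum()), "snps": int(snp_ok.sum())}

    # heterozygosity excess
    theta_hat = estimate_theta_moment(geno[:, snp_ok], panel.subset(snp_ok))
    het_z = het_excess_z(geno[:, snp_ok], theta_hat, panel.subset(snp_ok))
    for i in np.flatnonzero(np.nan_to_num(het_z) > het_z_threshold):
        if sample_reason[i] == "":
            sample_reason[i] = "het_excess"
    counts["het_excess"] = {"samples": int((sample_reason == "").sum()), "snps": int(snp_ok.sum())}
    sample_ok = sample_reason == ""

    # HWE in both ancestral panels
    hwe_pa = np.full(L, np.nan)
    hwe_pe = np.full(L, np.nan)
    if ancestral_genotypes is not None:
        for j in np.flatnonzero(snp_ok):
            ps = {}
            for pop in ("A", "E"):
                gj = ancestral_genotypes[pop][:, j]
                gj = gj[gj >= 0]
                ps[pop] = hwe_exact_test(
                    int((gj == 2).sum()), int((gj == 1).sum()), int((gj == 0).sum())
                )
            hwe_pa[j], hwe_pe[j] = ps["A"], ps["E"]
            if min(ps["A"], ps["E"]) <= hwe_alpha:
                snp_reason[j] = "hwe"
        snp_ok = snp_reason == ""
    counts["hwe"] = {"samples": int(sample_ok.sum()), "snps": int(snp_ok.sum())}

    # freqcheck against the ancestry-weighted mixture frequency
    theta_bar = float(theta_hat[sample_ok].mean()) if sample_ok.any() else 0.5
    fc_z = np.full(L, np.nan)
    for j in np.flatnonzero(snp_ok):
        gj = geno[sample_ok, j]
        gj = gj[gj >= 0]
        if gj.size == 0:
            snp_reason[j] = "freqcheck_no_data"
            continue
        ok, z, _ = freqcheck(
            panel.freq_A[j], panel.freq_E[j], panel.n_A[j], panel.n_E[j],
            int(gj.sum()), 2 * gj.size, theta_bar, freqcheck_alpha,
        )
        fc_z[j] = z
        if not ok:
            snp_reason[j] = "freqcheck"
    snp_ok = snp_reason == ""
    counts["freqcheck"] = {"samples": int(sample_ok.sum()), "snps": int(snp_ok.sum())}

    # ldcheck on the survivors
    survivors = np.flatnonzero(snp_ok)
    sub_panel = panel.subset(survivors)
    sub_anc = (
        None
        if ancestral_genotypes is None
        else {k: v[:, survivors] for k, v in ancestral_genotypes.items()}
    )
    kept_local = ldcheck(sub_panel, sub_anc, ld_window_bp, ld_r2_max)
    kept = survivors[kept_local]
    dropped_ld = np.setdiff1d(survivors, kept)
    snp_reason[dropped_ld] = "ldcheck"
    counts["ldcheck"] = {"samples": int(sample_ok.sum()), "snps": int(kept.size)}

    sample_table = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "call_rate": sample_call_rate(geno),
            "dup_partner": dup_partner,
            "het_excess_z": het_excess_z(geno, estimate_theta_moment(geno, panel), panel),
            "excluded": sample_reason != "",
            "reason": sample_reason,
        }
    )
    snp_table = pd.DataFrame(
        {
            "snp_id": panel.snp_id,
            "call_rate": s_cr,
            "hwe_p_A": hwe_pa,
            "hwe_p_E": hwe_pe,
            "freqcheck_z": fc_z,
            "excluded": snp_reason != "",
            "reason": snp_reason,
        }
    )
    return QCReport(
        sample_table=sample_table,
        snp_table=snp_table,
        stage_counts=counts,
        kept_samples=np.flatnonzero(sample_ok),
        kept_snps=kept,
    )
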