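"""Local-ancestry inference for a two-way admixed cohort.

The observable data are unphased variant counts at ancestry-informative
markers; the hidden process is the pair of ancestral backgrounds carried by
an individual's two chromosome copies. :func:`forward_backward` gives the
exact per-marker posterior over the European-allele count for fixed
parameters. :func:`mcmc_fit` integrates over the nuisance parameters -
per-individual African proportion theta_i, the shared ancestry-switch
intensity lambda (generations since admixture), and the ancestral allele
frequencies (Beta posteriors seeded from the finite reference panels) - by
Gibbs sampling with a forward-filter backward-sample step for the ancestry
paths, mirroring the design of the classical admixture-scan software.
Defaults are 100 burn-in and 200 follow-on iterations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from . import _hmm_core
from .panel import AncestralPanel


@dataclass
class HMMParams:
    """Posterior summaries of the nuisance parameters after an MCMC run."""

    theta: np.ndarray  # per-individual African proportion, posterior mean
    lambda_mean: float
    lambda_trace: np.ndarray  # follow-on iterations
    freq_A: np.ndarray  # posterior-mean ancestral frequencies
    freq_E: np.ndarray


@dataclass
class AncestryPosterior:
    """Per-individual, per-marker ancestry posterior plus derived summaries.

    gamma[i, j, a] = P(a European-derived alleles at marker j | data), each
    triple summing to 1. paa is the genome-wide African proportion computed
    from gamma (unweighted marker mean of African dosage / 2), so the
    marginal-consistency identity paa == mean local dosage / 2 holds exactly.
    """

    gamma: np.ndarray
    paa: np.ndarray
    sample_id: Optional[np.ndarray] = None
    params: Optional[HMMParams] = field(default=None, repr=False)

    def __post_init__(self) -> None:
        sums = self.gamma.sum(axis=2)
        if not np.allclose(sums, 1.0, atol=1e-9):
            raise ValueError("each gamma triple must sum to 1")


def local_african_dosage(gamma: np.ndarray, locus: int) -> np.ndarray:
    """Expected African-allele count (in [0, 2]) at one marker; the regression exposure."""
    g = np.atleast_3d(gamma)[:, locus, :]
    return 2.0 - (g[:, 1] + 2.0 * g[:, 2])


def regional_ancestry(gamma: np.ndarray, markers_in_region) -> np.ndarray:
    """Mean expected African-allele fraction over a set of markers, per individual."""
    idx = np.asarray(markers_in_region)
    if idx.size == 0:
        raise ValueError("region is empty")
    g = gamma[:, idx, :]
    afr = 2.0 - (g[:, :, 1] + 2.0 * g[:, :, 2])
    return afr.mean(axis=1) / 2.0


def default_arms(panel: AncestralPanel) -> dict[str, np.ndarray]:
    """Chromosome-arm marker index sets; each chromosome split at its bp midpoint."""
    arms: dict[str, np.ndarray] = {}
    for c in np.unique(panel.chrom):
        on = np.flatnonzero(panel.chrom == c)
        pos = panel.pos_bp[on]
        mid = (pos.min() + pos.max()) / 2.0
        p_arm, q_arm = on[pos <= mid], on[pos > mid]
        if p_arm.size:
            arms[f"{c}p"] = p_arm
        if q_arm.size:
            arms[f"{c}q"] = q_arm
    return arms


def estimate_theta_moment(genotypes: np.ndarray, panel: AncestralPanel) -> np.ndarray:
    """Method-of-moments African proportion per individual.

    Least-squares fit of g/2 on the ancestral frequency contrast:
    E[g/2] = theta*freq_A + (1-theta)*freq_E. Robust enough to seed the
    MCMC and to drive the heterozygosity QC filter.
    """
    geno = np.atleast_2d(genotypes).astype(float)
    obs = geno >= 0
    diff = (panel.freq_A - panel.freq_E)[None, :]
    num = np.where(obs, (geno / 2.0 - panel.freq_E[None, :]) * diff, 0.0).sum(axis=1)
    den = np.where(obs, diff * diff, 0.0).sum(axis=1)
    theta = np.where(den > 1e-12, num / np.maximum(den, 1e-12), 0.5)
    return np.clip(theta, 0.01, 0.99)


def _stay_probs(panel: AncestralPanel, lambda_gen: float) -> tuple[np.ndarray, np.ndarray]:
    d = panel.morgan_gaps()
    if np.any(d < 0):
        raise ValueError("negative genetic map gap")
    starts = panel.chrom_start_mask()
    stay = np.exp(-lambda_gen * d)
    stay[starts] = 0.0
    return stay, starts


def forward_backward(
    genotypes: np.ndarray,
    panel: AncestralPanel,
    theta,
    lambda_gen: float,
    freq_A: Optional[np.ndarray] = None,
    freq_E: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Exact posterior marginals of the European-allele count.

    ``genotypes`` may be a single individual (L,) or a matrix (N, L); theta a
    scalar or per-individual vector. Frequencies default to the panel values.
    Returns gamma with matching leading shape.
    """
    geno = np.asarray(genotypes)
    single = geno.ndim == 1
    geno = np.atleast_2d(geno)
    th = np.broadcast_to(np.asarray(theta, float), (geno.shape[0],)).copy()
    if np.any((th <= 0) | (th >= 1)):
        raise ValueError("theta must lie in (0, 1)")
    stay, _ = _stay_probs(panel, lambda_gen)
    fa = panel.freq_A if freq_A is None else np.asarray(freq_A, float)
    fe = panel.freq_E if freq_E is None else np.asarray(freq_E, float)
    gamma = _hmm_core.forward_backward_exact(geno, stay, th, fa, fe)
    return gamma[0] if single else gamma


def _lambda_loglik(lam: float, d: np.ndarray, R: np.ndarray, m2n: int, interior: np.ndarray) -> float:
    """Log-likelihood of lambda given sampled stationary-redraw indicators.

    Each of the 2N copies independently redraws over an interval of d Morgans
    with probability 1 - exp(-lambda*d); R[j] of them did at interval j.
    """
    dj = d[interior]
    Rj = R[interior]
    p = -lam * dj
    with np.errstate(divide="ignore"):
        log1m = np.where(dj > 0, np.log1p(-np.exp(p)), -np.inf)
    ll = np.where(Rj > 0, Rj * log1m, 0.0) + (m2n - Rj) * p
    return float(ll.sum())


def mcmc_fit(
    genotypes: np.ndarray,
    panel: AncestralPanel,
    burn_in: int = 100,
    iters: int = 200,
    seed: int = 0,
    lambda_init: float = 6.0,
    lambda_bounds: tuple[float, float] = (0.05, 500.0),
    proposal_sd: float = 0.15,
) -> AncestryPosterior:
    """Gibbs/Metropolis sampler over ancestry paths and nuisance parameters.

    Per iteration: (a) forward-filter backward-sample the pair-ancestry path
    of every individual given (theta, lambda, frequencies); (b) augment with
    stationary-redraw indicators, making theta_i conjugate (Beta posterior
    over draws into each ancestry) and giving lambda a simple censored-
    exponential likelihood updated by a log-scale Metropolis step; (c) assign
    each observed allele to a chromosome copy and update the ancestral
    frequency Beta posteriors (Jeffreys prior plus panel counts plus
    ancestry-assigned admixed alleles). Reported gamma is the mean over
    follow-on iterations of the exact smoothing marginals given each
    iteration's parameter draw (a Rao-Blackwellized average, lower Monte
    Carlo noise than path indicators); paa is derived from gamma. Fixed
    seed implies identical output.
    """
    geno = np.ascontiguousarray(np.atleast_2d(genotypes), dtype=np.int8)
    n, L = geno.shape
    if L != len(panel):
        raise ValueError("genotype columns must match panel")
    rng = np.random.default_rng(seed)

    d = panel.morgan_gaps()
    starts = panel.chrom_start_mask()
    interior = ~starts

    # Beta posteriors for ancestral frequencies: Jeffreys + panel allele counts
    xA = np.round(panel.freq_A * panel.n_A)
    xE = np.round(panel.freq_E * panel.n_E)
    aA0, bA0 = 0.5 + xA, 0.5 + panel.n_A - xA
    aE0, bE0 = 0.5 + xE, 0.5 + panel.n_E - xE

    theta = estimate_theta_moment(geno, panel)
    pA = aA0 / (aA0 + bA0)
    pE = aE0 / (aE0 + bE0)
    lam = float(lambda_init)

    gamma_acc = np.zeros((n, L, 3))
    theta_sum = np.zeros(n)
    fa_sum = np.zeros(L)
    fe_sum = np.zeros(L)
    lam_trace = []

    nA_draw = np.zeros(n, dtype=np.int64)
    n_draw = np.zeros(n, dtype=np.int64)
    R = np.zeros(L, dtype=np.int64)
    varA = np.zeros(L, dtype=np.int64)
    totA = np.zeros(L, dtype=np.int64)
    varE = np.zeros(L, dtype=np.int64)
    totE = np.zeros(L, dtype=np.int64)

    stay = np.exp(-lam * d)
    stay[starts] = 0.0

    total = burn_in + iters
    for it in range(total):
        u = rng.random((n, L, 4))
        for arr in (nA_draw, n_draw, R, varA, totA, varE, totE):
            arr[:] = 0
        _hmm_core.sweep(
            geno, stay, starts, theta, pA, pE, u, it >= burn_in,
            nA_draw, n_draw, R, varA, totA, varE, totE, gamma_acc,
        )
        # theta | draws ~ Beta (uniform prior)
        theta = rng.beta(1.0 + nA_draw, 1.0 + (n_draw - nA_draw))
        theta = np.clip(theta, 1e-4, 1 - 1e-4)
        # ancestral frequencies | panel counts + assigned admixed alleles
        pA = np.clip(rng.beta(aA0 + varA, bA0 + (totA - varA)), 1e-4, 1 - 1e-4)
        pE = np.clip(rng.beta(aE0 + varE, bE0 + (totE - varE)), 1e-4, 1 - 1e-4)
        # lambda | redraw indicators: Metropolis on log scale, flat prior on log lambda
        prop = lam * np.exp(proposal_sd * rng.standard_normal())
        if lambda_bounds[0] <= prop <= lambda_bounds[1]:
            ll_cur = _lambda_loglik(lam, d, R, 2 * n, interior)
            ll_prop = _lambda_loglik(prop, d, R, 2 * n, interior)
            if np.log(rng.random()) < ll_prop - ll_cur:
                lam = prop
        stay = np.exp(-lam * d)
        stay[starts] = 0.0
        if it >= burn_in:
            theta_sum += theta
            fa_sum += pA
            fe_sum += pE
            lam_trace.append(lam)

    gamma = gamma_acc / float(iters)
    gamma /= gamma.sum(axis=2, keepdims=True)
    afr = 2.0 - (gamma[:, :, 1] + 2.0 * gamma[:, :, 2])
    paa = afr.mean(axis=1) / 2.0
    params = HMMParams(
        theta=theta_sum / iters,
        lambda_mean=float(np.mean(lam_trace)),
        lambda_trace=np.asarray(lam_trace),
        freq_A=fa_sum / iters,
        freq_E=fe_sum / iters,
    )
    return AncestryPosterior(gamma=gamma, paa=paa, params=params)


def posterior_to_long_table(post: AncestryPosterior, panel: AncestralPanel) -> pd.DataFrame:
    """Long-format (sample, snp, p0, p1, p2) table of the ancestry posterior."""
    n, L, _ = post.gamma.shape
    sample = (
        post.sample_id
        if post.sample_id is not None
        else np.array([f"S{i:05d}" for i in range(n)])
    )
    return pd.DataFrame(
        {
            "sample_id": np.repeat(sample, L),
            "snp_id": np.tile(panel.snp_id, n),
            "p0": post.gamma[:, :, 0].ravel(),
            "p1": post.gamma[:, :, 1].ravel(),
            "p2": post.gamma[:, :, 2].ravel(),
        }
    )
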