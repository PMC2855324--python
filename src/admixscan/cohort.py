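"""Synthetic admixed cohorts with known local-ancestry truth.

The generator emulates a recently admixed two-way population (African-American
style). Each individual i has a genome-wide African proportion theta_i drawn
from a Beta distribution; each of the two chromosome copies carries a
two-state ancestry mosaic along the genetic map, switching at intensity
lambda_gen per Morgan towards the stationary law (theta_i, 1 - theta_i).
Alleles are then drawn from the ancestral frequency of the background the
copy sits on. Phenotypes follow the study cohort's printed moments (trait
mean 199.6, SD 16.5 um; hypertension prevalence 57.9%; African proportion
0.824 +- 0.098), with an optional planted local-ancestry effect confined to
the hypertensive stratum.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .panel import AncestralPanel

MISSING = -1  # genotype code for a missing call

#: Cohort summary moments used for covariate simulation, by hypertension
#: stratum (1 = hypertensive, 0 = not): (mean, SD) or category proportions.
COVARIATE_MOMENTS = {
    1: {
        "age": (59.0, 5.5),
        "female": 0.663,
        "map6yr": (98.5, 10.2),
        "glucose": (118.9, 47.1),
        "hdl": (54.9, 18.3),
        "ldl": (129.5, 36.7),
        "trig": (119.0, 69.8),
        "bmi": (31.4, 6.4),
        "smoking": {"current": 0.189, "former": 0.327, "never": 0.484},
        "alcohol": {"current": 0.290, "former": 0.310, "never": 0.400},
    },
    0: {
        "age": (57.5, 5.1),
        "female": 0.598,
        "map6yr": (87.1, 7.4),
        "glucose": (108.4, 37.6),
        "hdl": (57.1, 18.5),
        "ldl": (127.6, 36.9),
        "trig": (103.4, 59.8),
        "bmi": (29.0, 6.0),
        "smoking": {"current": 0.221, "former": 0.326, "never": 0.453},
        "alcohol": {"current": 0.359, "former": 0.280, "never": 0.361},
    },
}

TRAIT_MEAN = 199.6  # um, venular-caliber-like trait
TRAIT_SD = 16.5
CRAE_MEAN = 164.8  # um, arteriolar-caliber-like companion trait
CRAE_SD = 15.7

# standardized covariate effects on the traits (per SD of covariate, in trait SD)
_COV_EFFECTS_CRVE = {"map6yr": 0.15, "glucose": 0.10, "age": -0.10}
_COV_EFFECTS_CRAE = {"map6yr": -0.20, "glucose": 0.05, "age": -0.10}


def mean_arterial_pressure(sbp: float, dbp: float) -> float:
    """Mean arterial pressure (mmHg): two thirds diastolic plus one third systolic."""
    sbp = float(sbp)
    dbp = float(dbp)
    if dbp < 0:
        raise ValueError("pressures must be non-negative")
    if sbp < dbp:
        raise ValueError(f"systolic ({sbp}) below diastolic ({dbp})")
    return (2.0 * dbp + sbp) / 3.0


@dataclass
class SimParams:
    """Parameters of the cohort generator.

    lambda_gen is the ancestry-switch intensity per Morgan per chromosome
    copy, interpretable as generations since admixture; 6 is the conventional
    value for African Americans. theta_mean/theta_sd parameterize the Beta
    distribution of individual African proportion. effect_size is the planted
    trait shift in SD units per African allele at risk_locus, applied in the
    hypertensive stratum only; global_effect_size (trait SD per SD of theta)
    plants a purely genome-wide-ancestry-driven signal instead, used to test
    confounding control.
    """

    n_individuals: int
    lambda_gen: float = 6.0
    theta_mean: float = 0.824
    theta_sd: float = 0.098
    effect_size: float = 0.0
    risk_locus: Optional[str] = None
    strat_prevalence: float = 0.579
    global_effect_size: float = 0.0
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_individuals < 0:
            raise ValueError("n_individuals must be >= 0")
        if not np.isfinite(self.lambda_gen) or self.lambda_gen <= 0:
            raise ValueError("lambda_gen must be a positive finite number")
        if not (0 < self.theta_mean < 1):
            raise ValueError("theta_mean must be in (0, 1)")
        if self.theta_sd < 0:
            raise ValueError("theta_sd must be >= 0")
        if self.theta_sd > 0:
            a, b = self.beta_params()
            if a <= 0 or b <= 0:
                raise ValueError("(theta_mean, theta_sd) not fittable by a Beta distribution")
        if not (0 <= self.strat_prevalence <= 1):
            raise ValueError("strat_prevalence must be in [0, 1]")
        if not (0 <= self.missing_rate < 1):
            raise ValueError("missing_rate must be in [0, 1)")

    def beta_params(self) -> tuple[float, float]:
        """Beta(a, b) moments fit for the African-proportion distribution."""
        m, s = self.theta_mean, self.theta_sd
        if s == 0:
            return (np.inf, np.inf)
        nu = m * (1 - m) / (s * s) - 1.0
        return (m * nu, (1 - m) * nu)


@dataclass
class AdmixedCohort:
    """Genotypes, local-ancestry truth and phenotypes for a simulated cohort.

    genotypes: individuals x SNPs variant-allele counts, MISSING (-1) for no-calls.
    true_ancestry: European-allele count {0,1,2} per individual x SNP.
    copy_ancestry: per-copy background (1 = African) individuals x SNPs x 2.
    theta_true: simulated genome-wide African proportion per individual.
    phenotypes: one row per individual (filled by :func:`simulate_phenotypes`).
    """

    panel: AncestralPanel
    genotypes: np.ndarray
    true_ancestry: np.ndarray
    copy_ancestry: np.ndarray = field(repr=False)
    theta_true: np.ndarray
    sample_id: np.ndarray
    phenotypes: Optional[pd.DataFrame] = None

    def __post_init__(self) -> None:
        if self.genotypes.shape != self.true_ancestry.shape:
            raise ValueError("genotype and ancestry matrices must share dimensions")
        if self.genotypes.shape[1] != len(self.panel):
            raise ValueError("genotype columns must match panel SNPs")

    @property
    def n_individuals(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_snps(self) -> int:
        return self.genotypes.shape[1]

    def subset_samples(self, keep) -> "AdmixedCohort":
        keep = np.asarray(keep)
        return AdmixedCohort(
            panel=self.panel,
            genotypes=self.genotypes[keep],
            true_ancestry=self.true_ancestry[keep],
            copy_ancestry=self.copy_ancestry[keep],
            theta_true=self.theta_true[keep],
            sample_id=self.sample_id[keep],
            phenotypes=None
            if self.phenotypes is None
            else self.phenotypes.iloc[np.asarray(keep)].reset_index(drop=True),
        )

    def subset_snps(self, keep) -> "AdmixedCohort":
        keep = np.asarray(keep)
        return AdmixedCohort(
            panel=self.panel.subset(keep),
            genotypes=self.genotypes[:, keep],
            true_ancestry=self.true_ancestry[:, keep],
            copy_ancestry=self.copy_ancestry[:, keep],
            theta_true=self.theta_true,
            sample_id=self.sample_id,
            phenotypes=self.phenotypes,
        )


def _simulate_copy_ancestry(
    panel: AncestralPanel, theta: np.ndarray, lambda_gen: float, rng: np.random.Generator
) -> np.ndarray:
    """Two-state ancestry mosaics (1 = African) for 2 copies per individual.

    The chain starts at its stationary law at each chromosome start; over a gap
    of d Morgans a copy keeps its state with probability exp(-lambda*d) and is
    otherwise redrawn from (theta, 1-theta). Returns (N, L, 2) int8.
    """
    n = len(theta)
    L = len(panel)
    d = panel.morgan_gaps()
    starts = panel.chrom_start_mask()
    stay = np.exp(-lambda_gen * d)
    stay[starts] = 0.0  # forces a stationary redraw at chromosome starts

    th = theta[:, None]  # (N, 1) broadcasting over the 2 copies
    anc = np.empty((n, L, 2), dtype=np.int8)
    state = np.zeros((n, 2), dtype=np.int8)
    for j in range(L):
        if j > 0:
            redraw = rng.random((n, 2)) >= stay[j]
            new = (rng.random((n, 2)) < th).astype(np.int8)
            state = np.where(redraw, new, state)
        else:
            state = (rng.random((n, 2)) < th).astype(np.int8)
        anc[:, j, :] = state
    return anc


def simulate_cohort(panel: AncestralPanel, params: SimParams) -> AdmixedCohort:
    """Simulate admixed genotypes with known per-locus ancestry truth.

    Deterministic given ``params`` (including its seed). Raises on an empty
    panel or non-monotone genetic map (the panel class enforces the latter).
    """
    if len(panel) == 0:
        raise ValueError("panel is empty")
    rng = np.random.default_rng(params.seed)
    n = params.n_individuals

    if params.theta_sd == 0:
        theta = np.full(n, params.theta_mean)
    else:
        a, b = params.beta_params()
        theta = rng.beta(a, b, size=n)
    theta = np.clip(theta, 1e-6, 1 - 1e-6)

    copy_anc = _simulate_copy_ancestry(panel, theta, params.lambda_gen, rng)

    # allele on each copy: Bernoulli(freq_A) on African background, else Bernoulli(freq_E)
    fa = panel.freq_A[None, :, None]
    fe = panel.freq_E[None, :, None]
    p = np.where(copy_anc == 1, fa, fe)
    alleles = (rng.random(copy_anc.shape) < p).astype(np.int8)
    geno = alleles.sum(axis=2).astype(np.int8)

    if params.missing_rate > 0:
        miss = rng.random(geno.shape) < params.missing_rate
        geno[miss] = MISSING

    euro = (2 - copy_anc.sum(axis=2)).astype(np.int8)
    sample_id = np.array([f"S{i:05d}" for i in range(n)])
    return AdmixedCohort(
        panel=panel,
        genotypes=geno,
        true_ancestry=euro,
        copy_ancestry=copy_anc,
        theta_true=theta,
        sample_id=sample_id,
    )


def _draw_covariates(strata: np.ndarray, rng: np.random.Generator) -> pd.DataFrame:
    """Independent covariates matched to the per-stratum cohort moments."""
    n = len(strata)
    cols: dict[str, np.ndarray] = {}
    num_keys = ["age", "map6yr", "glucose", "hdl", "ldl", "trig", "bmi"]
    for key in num_keys:
        x = np.empty(n)
        for s in (0, 1):
            m, sd = COVARIATE_MOMENTS[s][key]
            mask = strata == s
            x[mask] = rng.normal(m, sd, size=mask.sum())
        cols[key] = x
    sex = np.empty(n, dtype=int)
    for s in (0, 1):
        mask = strata == s
        sex[mask] = rng.random(mask.sum()) < COVARIATE_MOMENTS[s]["female"]
    cols["sex"] = sex
    cols["site"] = np.where(rng.random(n) < 0.8, "jackson", "forsyth")
    for cat in ("smoking", "alcohol"):
        out = np.empty(n, dtype=object)
        for s in (0, 1):
            props = COVARIATE_MOMENTS[s][cat]
            mask = strata == s
            out[mask] = rng.choice(
                list(props.keys()), size=mask.sum(), p=np.array(list(props.values()))
            )
        cols[cat] = out
    return pd.DataFrame(cols)


def simulate_phenotypes(cohort: AdmixedCohort, params: SimParams) -> AdmixedCohort:
    """Fill the cohort's phenotype table, planting the configured ancestry effects.

    The venular-caliber-like trait is built on the printed cohort moments:

        crve = 199.6 + 16.5 * (covariate z-effects
                               + effect_size * (afrDosage - 2*theta_mean) * 1[hyp]
                               + global_effect_size * (theta - theta_mean)/theta_sd
                               + residual noise)

    The planted local term is centred on the expected African dosage so the
    stratum means stay at their printed, essentially equal values; only the
    within-stratum association with local ancestry is planted. Residual noise
    is scaled so the total trait SD is close to 16.5. Raises if risk_locus is
    set but absent from the panel.
    """
    rng = np.random.default_rng(params.seed + 1_000_003)
    n = cohort.n_individuals
    strata = (rng.random(n) < params.strat_prevalence).astype(int)
    cov = _draw_covariates(strata, rng)

    def z(col):
        # standardize against the overall printed moments so effects are in SD units
        m1, s1 = COVARIATE_MOMENTS[1][col]
        m0, s0 = COVARIATE_MOMENTS[0][col]
        p = params.strat_prevalence
        m = p * m1 + (1 - p) * m0
        s = np.sqrt(p * s1**2 + (1 - p) * s0**2 + p * (1 - p) * (m1 - m0) ** 2)
        return (cov[col].to_numpy() - m) / s

    def build(mean, sd, effects, planted):
        lin = np.zeros(n)
        for col, b in effects.items():
            lin += b * z(col)
        explained = sum(b * b for b in effects.values())
        noise = rng.normal(0.0, np.sqrt(max(1.0 - explained, 0.05)), size=n)
        return mean + sd * (lin + planted + noise)

    planted = np.zeros(n)
    if params.effect_size != 0.0:
        if params.risk_locus is None:
            raise ValueError("effect_size set but risk_locus is None")
        j = cohort.panel.index_of(params.risk_locus)  # KeyError if absent
        afr_dosage = 2.0 - cohort.true_ancestry[:, j]
        planted += params.effect_size * (afr_dosage - 2.0 * params.theta_mean) * strata
    if params.global_effect_size != 0.0:
        sd = params.theta_sd if params.theta_sd > 0 else 1.0
        planted += params.global_effect_size * (cohort.theta_true - params.theta_mean) / sd

    crve = build(TRAIT_MEAN, TRAIT_SD, _COV_EFFECTS_CRVE, planted)
    crae = build(CRAE_MEAN, CRAE_SD, _COV_EFFECTS_CRAE, np.zeros(n))

    pheno = pd.DataFrame({"sample_id": cohort.sample_id, "crve_like": crve, "crae_like": crae})
    pheno = pd.concat([pheno, cov], axis=1)
    pheno["hypertension"] = strata
    cohort.phenotypes = pheno
    return cohort
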