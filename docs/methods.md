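# Methods

## The generative model

The cohort generator and the inference engine share one model of recent
two-way admixture. Individual *i* draws a genome-wide African proportion
θᵢ from a Beta distribution fitted by moments to (mean 0.824, SD 0.098),
the printed distribution of the emulated cohort. Each of the two chromosome
copies carries a two-state ancestry mosaic along the genetic map: at each
chromosome start the state is drawn from the stationary law (θᵢ, 1−θᵢ), and
over a gap of *d* Morgans the state is kept with probability e^(−λd) and
otherwise redrawn from the stationary law. λ (per Morgan, per copy) is the
exchange-rate parameterization of "generations since admixture"; the
default is 6, the conventional African-American value, and it is a free,
configurable parameter because the emulated study never reports its own
estimate. Stationary initialization makes the single-locus prior on the
European-allele count exactly Binomial(2, 1−θᵢ), which is the null the scan
statistics assume.

Genotypes are variant-allele counts: each copy draws its allele
Bernoulli(f_A) on African background and Bernoulli(f_E) on European
background, independently across markers given the ancestry mosaic. This
matches an AIM panel *after* LD pruning — within-ancestry haplotype LD is
deliberately out of scope, so the generator cannot exercise LD-aware
emission models (none are implemented) and the ldcheck filter's r² branch
is tested with purpose-built correlated reference genotypes instead.

### Ancestral panels

`generate_aim_panel` spaces markers evenly with ±30% jitter (default 2 Mb)
and uses the 1 cM/Mb desk-scale map. Per-SNP frequency differences are
drawn Uniform(diff_spec/2, diff_spec) with random sign; the default
diff_spec = 0.75 yields a mean |f_A − f_E| ≈ 0.56, matching curated
African/European panels. Panel sample sizes default to 120 chromosomes per
population (a HapMap-scale reference); these counts drive the Beta
posteriors that propagate finite-panel frequency uncertainty through the
MCMC and the freqcheck variance widening.

### Phenotypes

The venular-caliber-like trait is built on the printed cohort moments
(mean 199.6, SD 16.5 µm), with per-stratum covariate distributions matched
to the printed stratified table and modest standardized covariate effects
(MAP +0.15, glucose +0.10, age −0.10 SD per SD; residual noise scaled so
the total SD stays near 16.5). Covariates are otherwise independent — they
exist to exercise the adjustment step, not to model real correlation
structure. The planted local effect is

  β · (afrDosage − 2·θ_mean) · 1[hypertensive],  β = effect_size · 16.5,

i.e. *centred* on the expected African dosage. An uncentred term would
shift the hypertensive group mean by ~0.6 trait SD, contradicting the
essentially equal stratum means of the emulated cohort and leaking the
effect into the full-sample extreme split; centring only moves the stratum
intercept, which every downstream analysis absorbs. A separate
`global_effect_size` (trait SD per SD of θ) plants a purely
genome-wide-ancestry-driven signal for the confounding-control experiments.

## Local-ancestry inference

`forward_backward` runs the exact sum-product recursion on the joint state
of the two copies (4 states; emission couples the copies through the
unphased genotype, missing calls emit likelihood 1) and returns the
count-collapsed posterior γᵢⱼ over {0,1,2} European alleles. It is tested
to 1e-10 against brute-force enumeration of all per-copy ancestry paths on
up to 5 markers.

`mcmc_fit` integrates over the nuisance parameters. Per iteration:

1. forward-filter backward-sample a joint ancestry path per individual;
2. augment each interval with a *stationary-redraw* indicator (probability
   (1−e^(−λd))·π(s′) relative to staying), which makes θᵢ conjugate — a
   Beta(1+draws-to-African, 1+draws-to-European) update over the redraw and
   chromosome-start events — and gives λ a censored-exponential likelihood
   over the redraw indicators, updated by a log-scale Metropolis step
   (proposal SD 0.15, flat prior on log λ in [0.05, 500]);
3. assign each observed allele to a copy (heterozygotes probabilistically)
   and update the ancestral-frequency Beta posteriors
   Beta(0.5 + panel count + assigned admixed alleles, …) — a Jeffreys prior
   plus the finite panel, so panel uncertainty propagates.

Defaults are 100 burn-in + 200 follow-on iterations; a 10× longer run is
available for stability checks. Reported γ is the follow-on mean of the
*exact smoothing marginals* given each iteration's parameter draw (a
Rao-Blackwellized average — same estimand as averaging sampled-path
indicators, with about half the LOD-scale Monte Carlo noise). The global
ancestry PAAᵢ is defined as the unweighted marker mean of the posterior
African dosage / 2, so the identity PAA = mean dosage/2 holds exactly.
At study scale (1,737 × 1,359 markers) the λ posterior is extremely tight
and the Metropolis chain moves rarely; this is posterior concentration, not
failure to converge — the recovery test at 200 × 300 markers shows proper
mixing and ±30% accuracy.

The per-iteration sweep is a numba kernel (a vectorized numpy fallback with
bit-identical path statistics is kept and tested against it, and is used
automatically when numba is unavailable).

### Which θ feeds the scan

The case-only LOD contrasts γ against the prior Binomial(2, 1−θᵢ). θᵢ here
is the MCMC posterior mean of the *model* stationary proportion, not the
realized genome average PAAᵢ: PAA is computed from the same γ whose locus
deviations the scan tests, so using it as the prior self-centres the
deviations and dilutes contrast (measured: 14/20 vs 18/20 correct peak
chromosomes in the stratified-recovery experiment). PAA remains the
global-ancestry covariate in the regressions, where the realized average is
exactly what confounding adjustment calls for.

## Scan statistics

18 pre-specified European-ancestry risk models in three families over folds
ρ ∈ {0.4, 0.5, 0.67, 1.5, 2.0, 2.5}: (1, ρ, ·), (1/ρ, ρ, ·) and (ρ, 1, 1);
the unspecified two-copy risk in families 1–2 is filled log-linearly
(r₂ = r₁²/r₀), with explicit triples accepted for risk-model refinement.
Per-locus evidence is the model-averaged Bayes factor (log₁₀ reported);
the genome-wide score averages Bayes factors over loci before the log.
The subgroup correction divides the likelihood ratio by the number of
subgroup hypotheses on the Bayes-factor scale. The case-control Z uses the
empirical group variances of the per-individual ancestry deviation; its
null standard-normality is checked by simulation rather than assumed.
Extreme-tail splits take ceil(frac·N) cases and floor(frac·N) controls
(reproducing the 261/260 and 151/150 splits at N = 1737 and 1001; no single
rounding rule reproduces the printed 110/109 at N = 736, which is noted and
not matched).

The credible interval treats normalized per-marker Bayes factors as a
piecewise-linear density over physical position under a flat positional
prior and excludes (1−coverage)/2 mass from each side by exact piecewise
(quadratic) inversion of the cumulative; a marker-mass (non-interpolated)
variant is not exposed because the trapezoidal density is strictly more
informative at AIM spacing.

## QC cascade

Stage order: SNP call rate (≥0.95) → sample call rate (≥0.94) → duplicates
(genotype concordance > 0.75 over jointly non-missing calls; the
lower-call-rate member is dropped, ties by sample order) → heterozygosity
excess (Z > 10 against the ancestry-mixture expectation 2p(1−p),
p = θf_A + (1−θ)f_E, with θ from a least-squares moment estimator) → exact
conditional Hardy–Weinberg test in *both* ancestral panels (drop at
p ≤ 0.01 in either) → freqcheck → ldcheck.

freqcheck tests the admixed allele count against the mixture frequency
p_mix = θ̄f_A + (1−θ̄)f_E with the variance widened by the panel sampling
terms θ̄²f_A(1−f_A)/n_A + (1−θ̄)²f_E(1−f_E)/n_E; α = 0.001 (the emulated
study states no threshold; this keeps null loss ≈ 0.1%).

ldcheck iteratively removes the less informative member (Rosenberg's Iₙ;
|f_A−f_E| available) of any retained pair that is within 200 kb or in
detectable ancestral-panel LD. "Detectable" is operationalized as r² > 0.05
*and* correlation significantly nonzero at α = 0.001, evaluated only for
pairs within a 1 Mb horizon: with 60-diploid panels, raw r² > 0.05 alone
would flag ~8% of truly independent pairs, and scanning all same-chromosome
pairs accumulates false flags with no biological counterpart. Ties in
informativeness are broken by (chrom, pos, snp_id), making the retained set
invariant to input row order. On a clean synthetic cohort the cascade loses
no samples and only the HWE/freqcheck α-tail of markers (measured: 6 of
1,365 at study scale).

## Association analysis

The trait is residualized by OLS on age, sex, site, 6-year mean arterial
pressure and fasting glucose (categoricals one-hot; rank-deficient designs
are rejected naming the collinear columns), then rank-transformed through
Φ⁻¹((rank−0.5)/n) with average ranks for ties. Correlations are Spearman
(ρ notation of the emulated report; Pearson by flag), with the two-sided
t approximation on n−2 df; both reproduce the printed p-values at these
sample sizes. The nested regressions (local; +global; +global+regional
ancestry) use OLS with Wald intervals; regional ancestry is the unweighted
marker mean over the chromosome arm, arms defaulting to a midpoint split
when no centromere table is supplied. Stratum heterogeneity is the normal
Z on the coefficient difference from the fully adjusted models. The
"1,000 independent chromosomal chunks → ×2,000 for two subgroups"
multiple-testing factor is a configuration constant, not re-derived.

## What the tests do and do not show

The synthetic cohort matches the study's printed structure (marker count
and informativeness, sample size, ancestry distribution, stratum
prevalence, trait moments, planted effect size) but not real-data
pathologies: genotyping batch effects, within-ancestry LD, covariate
correlation structure, population substructure beyond the Beta law, or
ancestry-informativeness bias in panel frequencies. Passing the acceptance
suite therefore certifies the *statistical machinery* — exactness of the
HMM, calibration of the null, power and localization at the planted effect
size, confounding control of the nested models — not robustness to those
real-data features.

Measured under the committed study conditions (20 seeds, fixed a priori):
the stratified scan's max-LOD locus lands on the true chromosome and the
95% credible interval covers the true locus in 18/20 runs each; the
fully-adjusted regression averages β = 0.371 against the planted 0.37; the
heterogeneity test rejects in 16/20 runs; the genome-wide score exceeds 2
in 0/20 null scans and the pooled null case-control Z has mean −0.002,
SD 0.993. Single-seed locus LODs at study scale fluctuate widely (the
worked example's 2.06 against a published 5.47-style value is within that
spread — peak LODs reported by a scan that searched the genome are
upward-selected realizations).

## Numerical and implementation choices

- Forward recursions renormalize per marker; degenerate all-zero rows fall
  back to uniform (cannot occur with frequencies clipped to [1e-4, 1−1e-4],
  which also keeps Beta draws away from absorbing states).
- The λ likelihood term log(1−e^(−λd)) is only evaluated on intervals with
  observed redraws; zero-length gaps are handled by the stay-probability
  short-circuit.
- The exact HWE test enumerates heterozygote counts in log-space with a
  ≤-observed-probability sum (1e-12 slack for float ties); the unit-test
  oracle recomputes it in exact rational arithmetic.
- All randomness flows from `numpy.random.default_rng` seeds; the numba
  kernel consumes pre-generated uniforms, so compiled and fallback paths
  are deterministic and identical in their integer statistics.
- Problem sizes in the acceptance suite (3 chromosomes × 100 AIMs,
  N = 1737 or 400, 20 seeds; 180-marker panels for the regression
  experiments) are the spec-scale study conditions for desk-scale
  validation; the analysis scripts run the full 22 × 1,365 configuration.

## Known limitations

Two ancestral populations only; no phased output and no per-individual λ;
emission treats markers independently given ancestry (post-pruning
assumption); the Metropolis proposal for λ is tuned for cohort sizes in the
hundreds and mixes slowly (though harmlessly) at thousands of individuals;
the pipeline's loaded-data path (ped/map or dosage TSV) trusts the panel's
allele orientation — mismatched allele codes are errors, never flipped.
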