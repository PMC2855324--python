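"""Admixture-scan statistics: case-only LOD, case-control Z, localization.

The case-only statistic asks whether the local-ancestry posterior of the
cases deviates from each case's own genome-wide ancestry prior in the
direction predicted by a relative-risk model for the European-allele count
at the locus. Evidence is averaged over a pre-specified bank of 18 risk
models; the log10 of the locus Bayes factor is the locus-specific LOD
(genome-wide significant above 5) and the log10 of the genome-averaged
Bayes factor is the genome-wide score (significant above 2). The
case-control statistic compares locus-specific ancestry deviations between
phenotype-extreme groups and is approximately standard normal under the
null, with |Z| > 4.06 (two-sided P < 5e-5) the genome-wide criterion.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

#: default significance thresholds reported alongside scan output
THRESHOLDS = {"genome_score": 2.0, "locus_lod": 5.0, "cc_z": 4.06}

RISK_FOLDS = (0.4, 0.5, 0.67, 1.5, 2.0, 2.5)


@dataclass(frozen=True)
class RiskModel:
    """Relative risks of case status for 0, 1, 2 European-derived alleles."""

    r0: float
    r1: float
    r2: float
    label: str = ""

    def __post_init__(self) -> None:
        if min(self.r0, self.r1, self.r2) <= 0:
            raise ValueError("risks must be positive")

    @property
    def risks(self) -> np.ndarray:
        return np.array([self.r0, self.r1, self.r2])


def build_risk_models() -> list[RiskModel]:
    """The 18 pre-specified European-ancestry risk models.

    Three families of six over the fold set {0.4, 0.5, 0.67, 1.5, 2.0, 2.5}:
    (1) one European copy carries risk rho, zero copies risk 1;
    (2) one copy risk rho, zero copies the reciprocal 1/rho;
    (3) zero copies risk rho, one or two copies risk 1.
    The two-copy risk in families 1-2, not pinned down by the family
    definition, is filled in log-linearly: r2 = r1^2 / r0.
    """
    models = []
    for rho in RISK_FOLDS:
        r0, r1 = 1.0, rho
        models.append(RiskModel(r0, r1, r1 * r1 / r0, f"one-copy {rho}"))
    for rho in RISK_FOLDS:
        r0, r1 = 1.0 / rho, rho
        models.append(RiskModel(r0, r1, r1 * r1 / r0, f"one-copy {rho}, zero-copy inverse"))
    for rho in RISK_FOLDS:
        models.append(RiskModel(rho, 1.0, 1.0, f"zero-copy {rho}"))
    return models


def ancestry_prior(theta: np.ndarray) -> np.ndarray:
    """Binomial(2, 1-theta) prior over the European-allele count, (N, 3)."""
    th = np.asarray(theta, float)
    return np.stack([th * th, 2 * th * (1 - th), (1 - th) * (1 - th)], axis=-1)


def locus_lod(gamma_cases: np.ndarray, theta_cases: np.ndarray, model: RiskModel) -> float:
    """Case-only LOD at one locus under one risk model.

    Per case, the Bayes factor is the risk-model-weighted posterior mass over
    European-allele counts divided by the same weighting of the individual's
    genome-wide ancestry prior; the LOD is the log10 product over cases.
    """
    g = np.atleast_2d(gamma_cases)
    if not np.allclose(g.sum(axis=1), 1.0, atol=1e-6):
        raise ValueError("gamma rows must sum to 1")
    r = model.risks
    num = g @ r
    den = ancestry_prior(theta_cases) @ r
    return float(np.log10(num / den).sum())


def lod_matrix(
    gamma_cases: np.ndarray, theta_cases: np.ndarray, models: Sequence[RiskModel]
) -> np.ndarray:
    """LOD for every locus x model; gamma_cases is (n_cases, L, 3)."""
    g = gamma_cases
    q = ancestry_prior(theta_cases)
    out = np.empty((g.shape[1], len(models)))
    for m, model in enumerate(models):
        r = model.risks
        num = np.tensordot(g, r, axes=([2], [0]))  # (n, L)
        den = (q @ r)[:, None]
        out[:, m] = np.log10(num / den).sum(axis=0)
    return out


def model_average_lod(lods: np.ndarray) -> np.ndarray:
    """Per-locus LOD averaged over risk models on the Bayes-factor scale."""
    lods = np.atleast_2d(lods)
    ref = lods.max(axis=1, keepdims=True)
    return (ref[:, 0] + np.log10(np.mean(10.0 ** (lods - ref), axis=1)))


def genome_wide_score(lods: np.ndarray) -> float:
    """log10 of the mean Bayes factor over all loci (and risk models).

    Accepts a per-locus vector of LODs or a locus x model matrix; models are
    averaged first, then loci.
    """
    lods = np.asarray(lods, float)
    if lods.ndim == 2:
        lods = model_average_lod(lods)
    if lods.size == 0:
        raise ValueError("need at least one locus")
    ref = lods.max()
    return float(ref + np.log10(np.mean(10.0 ** (lods - ref))))


def correct_lod_subgroups(lod: float, k: int) -> float:
    """Divide the likelihood ratio by k (subgroup hypotheses) on the LOD scale."""
    if k < 1:
        raise ValueError("k must be >= 1")
    return lod - math.log10(k)


def case_control_z(
    gamma_cases: np.ndarray,
    gamma_controls: np.ndarray,
    theta_cases: np.ndarray,
    theta_controls: np.ndarray,
) -> float:
    """Standardized case-control difference in locus ancestry deviation.

    delta_i = E[EuropeanCount]/2 - (1 - theta_i) measures how much more
    European the locus is than the individual's genome-wide expectation;
    Z = (mean delta_cases - mean delta_controls) / pooled SE. Negative Z
    means cases carry *more African* ancestry at the locus than controls.
    """
    gc = np.atleast_2d(gamma_cases)
    gt = np.atleast_2d(gamma_controls)
    if len(gc) < 2 or len(gt) < 2:
        raise ValueError("each group needs at least 2 members")

    def deltas(g, th):
        euro = g[:, 1] + 2.0 * g[:, 2]
        return euro / 2.0 - (1.0 - np.asarray(th, float))

    dc = deltas(gc, theta_cases)
    dt = deltas(gt, theta_controls)
    se = math.sqrt(dc.var(ddof=1) / len(dc) + dt.var(ddof=1) / len(dt))
    if se == 0:
        return 0.0
    return float((dc.mean() - dt.mean()) / se)


def define_extremes(
    adjusted_trait: np.ndarray, direction: str, frac: float = 0.15
) -> tuple[np.ndarray, np.ndarray]:
    """Extreme-tail case/control split of an adjusted trait.

    cases = ceil(frac*N) most extreme values in the case direction,
    controls = floor(frac*N) most extreme in the other; ties broken by
    stable sample order. ``direction`` is "high_is_case" or "low_is_case".
    """
    if not (0 < frac < 0.5):
        raise ValueError("frac must be in (0, 0.5)")
    if direction not in ("high_is_case", "low_is_case"):
        raise ValueError(f"unknown direction {direction!r}")
    x = np.asarray(adjusted_trait, float)
    if np.any(~np.isfinite(x)):
        raise ValueError("adjusted trait contains missing values")
    n = len(x)
    n_cases = math.ceil(frac * n)
    n_controls = math.floor(frac * n)
    order = np.argsort(x, kind="stable")
    if direction == "high_is_case":
        cases = order[::-1][:n_cases]
        controls = order[:n_controls]
    else:
        cases = order[:n_cases]
        controls = order[::-1][:n_controls]
    return np.sort(cases), np.sort(controls)


def credible_interval(
    pos_bp: np.ndarray, bayes_factors: np.ndarray, coverage: float = 0.95
) -> tuple[float, float]:
    """Central credible interval for a trait-locus position on one chromosome.

    Normalized per-marker Bayes factors define a piecewise-linear posterior
    density over physical position (flat positional prior); the interval
    excludes (1-coverage)/2 posterior mass from each side. Exact piecewise
    inversion (the cumulative is piecewise quadratic).
    """
    pos = np.asarray(pos_bp, float)
    bf = np.asarray(bayes_factors, float)
    if len(pos) < 2:
        raise ValueError("need at least 2 markers")
    if np.any(bf < 0) or not np.any(bf > 0):
        raise ValueError("Bayes factors must be non-negative with positive total mass")
    if not (0 < coverage <= 1):
        raise ValueError("coverage must be in (0, 1]")
    order = np.argsort(pos, kind="stable")
    pos, bf = pos[order], bf[order]
    if coverage == 1.0:
        return (float(pos[0]), float(pos[-1]))

    seg_mass = 0.5 * (bf[1:] + bf[:-1]) * np.diff(pos)
    total = seg_mass.sum()
    if total <= 0:
        raise ValueError("zero posterior mass over the marker span")
    cum = np.r_[0.0, np.cumsum(seg_mass)] / total
    dens = bf / total

    def invert(target: float) -> float:
        k = int(np.searchsorted(cum, target, side="right") - 1)
        k = min(max(k, 0), len(seg_mass) - 1)
        rem = target - cum[k]
        x0, x1 = pos[k], pos[k + 1]
        y0, y1 = dens[k], dens[k + 1]
        slope = (y1 - y0) / (x1 - x0)
        # solve y0*t + slope*t^2/2 = rem for t in [0, x1-x0]
        if abs(slope) < 1e-30:
            t = rem / y0 if y0 > 0 else 0.0
        else:
            disc = y0 * y0 + 2 * slope * rem
            t = (-y0 + math.sqrt(max(disc, 0.0))) / slope
        return float(x0 + min(max(t, 0.0), x1 - x0))

    tail = (1.0 - coverage) / 2.0
    return (invert(tail), invert(1.0 - tail))


@dataclass
class ScanResult:
    """Full output of one admixture scan."""

    lod: np.ndarray  # locus x model LOD matrix
    lod_avg: np.ndarray  # model-averaged per-locus LOD
    cc_z: np.ndarray  # per-locus case-control Z
    score: float  # genome-wide score
    peak_idx: int
    models: list[RiskModel] = field(repr=False)
    case_idx: np.ndarray = field(repr=False, default=None)
    control_idx: np.ndarray = field(repr=False, default=None)
    credible: Optional[tuple[int, float, float]] = None  # (chrom, start_bp, end_bp)

    @property
    def peak_lod(self) -> float:
        return float(self.lod_avg[self.peak_idx])


def run_scan(
    gamma: np.ndarray,
    theta: np.ndarray,
    case_idx: np.ndarray,
    control_idx: np.ndarray,
    panel=None,
    models: Optional[Sequence[RiskModel]] = None,
    coverage: float = 0.95,
) -> ScanResult:
    """Case-only LOD scan plus case-control Z at every locus.

    ``gamma`` is the (N, L, 3) ancestry posterior for the full sample;
    case/control index arrays select the extreme groups. When a panel is
    given, the peak chromosome's credible interval is computed from the
    model-averaged Bayes factors of its markers.
    """
    models = list(models) if models is not None else build_risk_models()
    theta = np.asarray(theta, float)
    lods = lod_matrix(gamma[case_idx], theta[case_idx], models)
    lod_avg = model_average_lod(lods)
    score = genome_wide_score(lods)
    L = gamma.shape[1]
    cc = np.array(
        [
            case_control_z(
                gamma[case_idx, j, :], gamma[control_idx, j, :],
                theta[case_idx], theta[control_idx],
            )
            for j in range(L)
        ]
    )
    peak = int(np.argmax(lod_avg))
    credible = None
    if panel is not None:
        chrom = int(panel.chrom[peak])
        on = np.flatnonzero(panel.chrom == chrom)
        if on.size >= 2:
            bf = 10.0 ** (lod_avg[on] - lod_avg[on].max())
            lo, hi = credible_interval(panel.pos_bp[on], bf, coverage)
            credible = (chrom, lo, hi)
    return ScanResult(
        lod=lods,
        lod_avg=lod_avg,
        cc_z=cc,
        score=score,
        peak_idx=peak,
        models=models,
        case_idx=np.asarray(case_idx),
        control_idx=np.asarray(control_idx),
        credible=credible,
    )
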