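"""Quantitative-trait association of local ancestry, and the surrounding
adjustment, transformation and multiple-testing machinery.

Workflow: residualize the trait on clinical covariates, normal-quantile
transform the residuals, then regress the transformed trait on the expected
African-allele dosage at a locus, optionally with genome-wide (global) and
chromosome-arm (regional) ancestry as covariates. The nested specifications
separate a truly local signal from one induced by overall ancestry. A
normal Z test compares the local-ancestry coefficients between strata.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats


@dataclass
class RegressionFit:
    """OLS fit of a transformed trait on African-allele dosage."""

    beta: float  # trait Z-units per African allele copy
    se: float
    ci95: tuple[float, float]
    p: float
    covariates: tuple[str, ...] = ()
    n: int = 0


def _design_matrix(covariates: pd.DataFrame) -> pd.DataFrame:
    """One-hot encode categoricals, add an intercept, keep numerics as-is."""
    parts = [pd.Series(1.0, index=covariates.index, name="const")]
    for col in covariates.columns:
        s = covariates[col]
        if s.dtype == object or isinstance(s.dtype, pd.CategoricalDtype):
            dummies = pd.get_dummies(s, prefix=col, drop_first=True, dtype=float)
            parts.append(dummies)
        else:
            parts.append(s.astype(float))
    return pd.concat(parts, axis=1)


def _check_full_rank(X: pd.DataFrame) -> None:
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        # name the offending columns: those whose removal restores the rank deficit
        bad = []
        arr = X.to_numpy()
        for k, name in enumerate(X.columns):
            rest = np.delete(arr, k, axis=1)
            if np.linalg.matrix_rank(rest) == rank:
                bad.append(name)
        raise ValueError(f"design matrix is rank-deficient; collinear columns: {bad}")


def adjust_phenotype(trait: np.ndarray, covariates: pd.DataFrame) -> np.ndarray:
    """OLS residuals of the trait on the covariate design (complete cases only)."""
    y = np.asarray(trait, float)
    X = _design_matrix(covariates)
    if np.any(~np.isfinite(y)) or np.any(~np.isfinite(X.to_numpy())):
        raise ValueError("adjustment requires complete cases")
    _check_full_rank(X)
    fit = sm.OLS(y, X).fit()
    return np.asarray(fit.resid)


def normal_quantile_transform(x: np.ndarray) -> np.ndarray:
    """Rank-based inverse normal transform: rank k of n maps to Phi^-1((k-0.5)/n).

    Ties receive average ranks, preserving order; the output is distribution-
    free with mean ~0 and SD ~1 for large n.
    """
    x = np.asarray(x, float)
    if len(x) < 2:
        raise ValueError("need at least 2 observations")
    if np.all(x == x[0]):
        raise ValueError("all values identical; transform undefined")
    ranks = stats.rankdata(x, method="average")
    return stats.norm.ppf((ranks - 0.5) / len(x))


def spearman_p_from_rho(rho: float, n: int) -> float:
    """Two-sided p-value for a rank correlation via the t approximation on n-2 df."""
    if n < 3:
        raise ValueError("need n >= 3")
    if abs(rho) >= 1:
        return 0.0
    t = rho * np.sqrt((n - 2) / (1 - rho * rho))
    return float(2 * stats.t.sf(abs(t), df=n - 2))


def correlation_with_p(x: np.ndarray, y: np.ndarray, method: str = "spearman") -> tuple[float, float]:
    """Correlation coefficient and two-sided p (t approximation, n-2 df)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) < 3 or len(x) != len(y):
        raise ValueError("need two equal-length vectors, n >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero-variance input")
    if method == "spearman":
        rho = float(stats.spearmanr(x, y).statistic)
    elif method == "pearson":
        rho = float(np.corrcoef(x, y)[0, 1])
    else:
        raise ValueError(f"unknown method {method!r}")
    return rho, spearman_p_from_rho(rho, len(x))


def local_ancestry_regression(
    trait_transformed: np.ndarray,
    local_dosage: np.ndarray,
    global_paa: Optional[np.ndarray] = None,
    regional: Optional[np.ndarray] = None,
) -> RegressionFit:
    """OLS of the transformed trait on African-allele dosage at a locus.

    ``global_paa`` and ``regional`` add the genome-wide and chromosome-arm
    ancestry covariates of the nested model specifications. Reports the
    dosage coefficient with Wald SE, 95% CI and p-value.
    """
    y = np.asarray(trait_transformed, float)
    x = np.asarray(local_dosage, float)
    if np.std(x) == 0:
        raise ValueError("local dosage is constant")
    cols = {"local_dosage": x}
    if global_paa is not None:
        cols["global_paa"] = np.asarray(global_paa, float)
    if regional is not None:
        cols["regional"] = np.asarray(regional, float)
    X = pd.DataFrame(cols)
    X.insert(0, "const", 1.0)
    _check_full_rank(X)
    fit = sm.OLS(y, X).fit()
    beta = float(fit.params["local_dosage"])
    se = float(fit.bse["local_dosage"])
    ci = fit.conf_int().loc["local_dosage"]
    return RegressionFit(
        beta=beta,
        se=se,
        ci95=(float(ci[0]), float(ci[1])),
        p=float(fit.pvalues["local_dosage"]),
        covariates=tuple(c for c in cols if c != "local_dosage"),
        n=len(y),
    )


def heterogeneity_z(beta1: float, se1: float, beta2: float, se2: float) -> tuple[float, float]:
    """Z test for a difference between two independent regression coefficients."""
    if se1 <= 0 or se2 <= 0:
        raise ValueError("standard errors must be positive")
    z = (beta1 - beta2) / np.sqrt(se1 * se1 + se2 * se2)
    return float(z), z_to_p(z)


def z_to_p(z: float) -> float:
    """Two-sided standard-normal tail probability."""
    return float(2 * stats.norm.sf(abs(z)))


def p_to_z(p: float) -> float:
    """Inverse of :func:`z_to_p` (magnitude only)."""
    return float(stats.norm.isf(p / 2))


def bonferroni(p: float, k: int) -> float:
    """Multiply by the number of hypotheses, clamped at 1."""
    if k < 1:
        raise ValueError("k must be >= 1")
    return float(min(1.0, p * k))


def se_from_ci(lower: float, upper: float) -> float:
    """Reconstruct a Wald SE from a printed 95% CI: (upper - lower) / (2 * 1.96)."""
    return (upper - lower) / (2 * 1.959963984540054)


def effect_in_trait_units(beta_z: float, trait_sd: float) -> float:
    """Convert a Z-scale coefficient back to raw trait units."""
    return beta_z * trait_sd
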