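"""Per-variant logistic association and the three result filters.

Effects are per-unit ALT dosage log odds ratios from a Newton-Raphson
maximum-likelihood logistic fit with Wald standard errors; the
technical-comparison mode runs identical machinery with the genotyping
platform as the outcome.  Result filters (evaluated in the fixed order
MAF, R2, R2-difference, all three always computed for reporting):

* MAF > 0.01 (strictly),
* overall imputation R2 > 0.8 (strictly),
* |R2_array - R2_WGS| < 0.1 (a difference of 0.1 or more fails).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import ARRAY, ConfigError, DosageMatrix

__all__ = [
    "logistic_assoc",
    "score_test_assoc",
    "compute_maf",
    "assoc_scan",
    "apply_result_filters",
    "genomic_lambda",
    "platform_association_mode",
]

GENOME_WIDE_SIG = 5e-8

PASS = "PASS"
FAIL_MAF = "FAIL_MAF"
FAIL_R2 = "FAIL_R2"
FAIL_R2DIFF = "FAIL_R2DIFF"
NOCONV = "NOCONV"

ASSOC_COLUMNS = [
    "CHROM", "POS", "REF", "ALT", "BETA", "SE", "P",
    "MAF", "R2", "R2_ARR", "R2_WGS", "FILTER", "N", "FLAG",
]


def _newton_logistic(
    x: np.ndarray, y: np.ndarray, max_iter: int = 40, tol: float = 1e-10
) -> tuple[np.ndarray, np.ndarray, bool]:
    """Newton-Raphson logistic MLE; returns (beta, cov, converged)."""
    n, p = x.shape
    beta = np.zeros(p)
    converged = False
    for _ in range(max_iter):
        eta = np.clip(x @ beta, -35, 35)
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = mu * (1.0 - mu)
        grad = x.T @ (y - mu)
        hess = (x * w[:, None]).T @ x
        try:
            step = np.linalg.solve(hess, grad)
        except np.linalg.LinAlgError:
            return beta, np.full((p, p), np.nan), False
        # step-halving keeps early iterations stable under separation
        if np.abs(step).max() > 10:
            step *= 10 / np.abs(step).max()
        beta = beta + step
        if np.abs(grad).max() < tol or np.abs(step).max() < 1e-12:
            converged = True
            break
    if np.abs(beta).max() > 15:  # (quasi-)separation
        converged = False
    eta = np.clip(x @ beta, -35, 35)
    mu = 1.0 / (1.0 + np.exp(-eta))
    w = mu * (1.0 - mu)
    hess = (x * w[:, None]).T @ x
    try:
        cov = np.linalg.inv(hess)
    except np.linalg.LinAlgError:
        cov = np.full((p, p), np.nan)
        converged = False
    return beta, cov, converged


def _design(dosage: np.ndarray, covariates: np.ndarray | None) -> np.ndarray:
    n = len(dosage)
    cols = [np.ones(n), np.asarray(dosage, dtype=float)]
    if covariates is not None:
        cov = np.atleast_2d(np.asarray(covariates, dtype=float))
        if cov.shape[0] != n:
            cov = cov.T
        cols.extend(cov.T)
    x = np.column_stack(cols)
    rank = np.linalg.matrix_rank(x[:, 2:]) if x.shape[1] > 2 else 0
    if covariates is not None and rank < x.shape[1] - 2:
        raise ConfigError("rank-deficient covariate matrix")
    return x


def logistic_assoc(
    dosage: np.ndarray,
    phenotype: np.ndarray,
    covariates: np.ndarray | None = None,
) -> tuple[float, float, float, str]:
    """Wald test of the dosage term; returns (beta, se, p, flag).

    Requires >= 10 cases and >= 10 controls.  Constant dosage, or
    non-convergence/separation, is flagged with p set to 1.
    """
    y = np.asarray(phenotype, dtype=float)
    if (y == 1).sum() < 10 or (y == 0).sum() < 10:
        raise ConfigError("need at least 10 cases and 10 controls")
    d = np.asarray(dosage, dtype=float)
    if d.std() == 0.0:
        return 0.0, np.nan, 1.0, NOCONV
    x = _design(d, covariates)
    beta, cov, converged = _newton_logistic(x, y)
    if not converged or not np.isfinite(cov[1, 1]) or cov[1, 1] <= 0:
        return float(beta[1]), np.nan, 1.0, NOCONV
    se = float(np.sqrt(cov[1, 1]))
    if se > 100:  # flat likelihood, effectively no information
        return float(beta[1]), np.nan, 1.0, NOCONV
    z = beta[1] / se
    p = float(2.0 * stats.norm.sf(abs(z)))
    return float(beta[1]), se, max(p, 5e-324), ""


def score_test_assoc(
    dosage: np.ndarray,
    phenotype: np.ndarray,
    covariates: np.ndarray | None = None,
) -> tuple[float, float]:
    """Rao score test of the dosage term under the covariate-only null.

    Returns (chi2, p).  Available as an alternative to the Wald test.
    """
    y = np.asarray(phenotype, dtype=float)
    d = np.asarray(dosage, dtype=float)
    x = _design(d, covariates)
    z = np.delete(x, 1, axis=1)  # null design: intercept + covariates
    beta0, _, conv = _newton_logistic(z, y)
    if not conv:
        return np.nan, 1.0
    mu = 1.0 / (1.0 + np.exp(-np.clip(z @ beta0, -35, 35)))
    w = mu * (1.0 - mu)
    u = float(d @ (y - mu))
    dwz = (z * w[:, None]).T @ d
    v = float(d @ (w * d) - dwz @ np.linalg.solve((z * w[:, None]).T @ z, dwz))
    if v <= 0:
        return np.nan, 1.0
    chi2 = u * u / v
    return chi2, float(stats.chi2.sf(chi2, 1))


def compute_maf(dosage: np.ndarray) -> float:
    """Minor allele frequency from mean dosage."""
    d = np.asarray(dosage, dtype=float)
    if d.size == 0:
        raise ConfigError("empty dosage vector")
    p = d.mean() / 2.0
    return float(min(p, 1.0 - p))


def assoc_scan(
    dm: DosageMatrix,
    phenotype: np.ndarray,
    covariates: np.ndarray | None = None,
) -> pd.DataFrame:
    """Logistic association of every variant's dosage with the phenotype."""
    rows = []
    table = dm.variants.df
    n = dm.n_samples
    for j in range(dm.n_variants):
        d = dm.dosages[:, j]
        maf = compute_maf(d)
        if d.std() == 0.0:
            beta, se, p, flag = 0.0, np.nan, 1.0, NOCONV
        else:
            beta, se, p, flag = logistic_assoc(d, phenotype, covariates)
        rows.append(
            {
                "CHROM": table["chrom"].iat[j],
                "POS": int(table["pos"].iat[j]),
                "REF": table["ref"].iat[j],
                "ALT": table["alt"].iat[j],
                "BETA": beta,
                "SE": se,
                "P": p,
                "MAF": maf,
                "R2": dm.r2_all[j],
                "R2_ARR": dm.r2_array[j],
                "R2_WGS": dm.r2_wgs[j],
                "FILTER": "",
                "N": n,
                "FLAG": flag,
            }
        )
    return pd.DataFrame(rows, columns=ASSOC_COLUMNS)


def apply_result_filters(
    records: pd.DataFrame,
    maf_min: float = 0.01,
    r2_min: float = 0.8,
    r2diff_max: float = 0.1,
) -> tuple[pd.DataFrame, dict]:
    """Assign filter verdicts and return (records, counts per verdict).

    The verdict is the first failing rule in the fixed order
    MAF -> R2 -> R2DIFF; all rules are evaluated for every record.
    A difference in per-platform R2 of ``r2diff_max`` or more fails.
    """
    rec = records.copy()
    verdicts = []
    for _, row in rec.iterrows():
        fail_maf = not (row["MAF"] > maf_min)
        fail_r2 = not (row["R2"] > r2_min)
        diff = abs(row["R2_ARR"] - row["R2_WGS"])
        fail_diff = (not np.isfinite(diff)) or diff >= r2diff_max
        if fail_maf:
            verdicts.append(FAIL_MAF)
        elif fail_r2:
            verdicts.append(FAIL_R2)
        elif fail_diff:
            verdicts.append(FAIL_R2DIFF)
        else:
            verdicts.append(PASS)
    rec["FILTER"] = verdicts
    counts = rec["FILTER"].value_counts().to_dict()
    return rec, counts


def genomic_lambda(p_values: np.ndarray) -> float:
    """Genomic inflation factor: median chi2(1) quantile over 0.4549."""
    p = np.asarray(p_values, dtype=float)
    p = p[np.isfinite(p)]
    if p.size < 100:
        raise ConfigError("genomic lambda needs >= 100 p-values")
    chi = stats.chi2.isf(np.clip(p, 1e-300, 1.0), df=1)
    return float(np.median(chi) / 0.4549364231195724)


def platform_association_mode(
    dm: DosageMatrix, covariates: np.ndarray | None = None
) -> pd.DataFrame:
    """Association scan with platform (array=1) as the outcome."""
    is_arr = (dm.platform == ARRAY).astype(float)
    if is_arr.sum() == 0 or is_arr.sum() == len(is_arr):
        raise ConfigError("platform association needs both platforms present")
    return assoc_scan(dm, is_arr, covariates)
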