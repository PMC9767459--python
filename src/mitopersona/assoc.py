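"""Covariate-adjusted standardized associations of mtDNAcn with traits.

Each association is an ordinary least-squares regression of z-scored
mtDNAcn on a z-scored continuous trait (binary predictors such as sex or
a CES-D cutoff stay on their native 0/1 coding, so their coefficients are
per-category effects) plus the adjustment set: age, sex, sequence
coverage, platelet count, WBC count, and percent neutrophils,
lymphocytes, basophils, and eosinophils. Effects are therefore in SD of
mtDNAcn per SD of trait and directly comparable across cohorts.
Missingness is handled by listwise deletion; p-values come from the t
distribution with residual degrees of freedom.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from mitopersona.traits import DEFAULT_COVARIATES

logger = logging.getLogger(__name__)


@dataclass
class AssociationResult:
    """Standardized effect of one trait on mtDNAcn in one cohort."""

    cohort: str
    trait: str
    beta: float
    se: float
    p: float
    n: int


def standardize(values) -> np.ndarray:
    """Z-score a vector: mean 0, SD 1 (n-1 denominator).

    Missing values are ignored when computing the moments and propagate
    to the output. A constant vector has no z-score and raises.
    """
    x = np.asarray(values, dtype=float)
    finite = x[np.isfinite(x)]
    if len(np.unique(finite)) < 2:
        raise ValueError("cannot standardize a constant vector (zero variance)")
    sd = finite.std(ddof=1)
    return (x - finite.mean()) / sd


def _is_binary(x: np.ndarray) -> bool:
    vals = np.unique(x[np.isfinite(x)])
    return len(vals) <= 2 and set(vals).issubset({0.0, 1.0})


def _check_rank(X: pd.DataFrame) -> None:
    a = X.to_numpy()
    rank = np.linalg.matrix_rank(a)
    if rank < a.shape[1]:
        # name columns whose removal restores full rank
        guilty = [
            c
            for i, c in enumerate(X.columns)
            if np.linalg.matrix_rank(np.delete(a, i, axis=1)) == rank
        ]
        raise ValueError(f"design matrix is rank deficient; collinear columns: {guilty}")


def adjusted_association(
    data: pd.DataFrame,
    trait: str,
    covariates: list[str] | None = None,
    outcome: str = "mtdnacn",
    cohort: str = "",
) -> AssociationResult:
    """Standardized effect of ``trait`` on ``outcome`` given covariates.

    ``covariates`` defaults to the full adjustment set; pass an empty
    list for an unadjusted fit. The outcome and a continuous trait are
    z-scored; a 0/1 trait is left as-is so the effect is per category.
    """
    covariates = DEFAULT_COVARIATES if covariates is None else list(covariates)
    cols = [outcome, trait, *covariates]
    missing = [c for c in cols if c not in data.columns]
    if missing:
        raise KeyError(f"columns absent from data: {missing}")
    sub = data[cols].apply(pd.to_numeric).dropna()
    n = len(sub)

    y = standardize(sub[outcome])
    x = sub[trait].to_numpy(dtype=float)
    if not _is_binary(x):
        x = standardize(x)
    X = pd.DataFrame({trait: x}, index=sub.index)
    for c in covariates:
        X[c] = sub[c].to_numpy(dtype=float)
    X = sm.add_constant(X)
    _check_rank(X)
    fit = sm.OLS(y, X).fit()
    return AssociationResult(
        cohort=cohort,
        trait=trait,
        beta=float(fit.params[trait]),
        se=float(fit.bse[trait]),
        p=float(fit.pvalues[trait]),
        n=n,
    )


def dichotomize_cesd(scores, cutoff: int = 16):
    """Binary depressive-symptom indicator: 1 if CES-D score >= cutoff.

    The conventional clinical cutoffs are 16 (general populations) and 20
    (older adults); other values are allowed but logged as non-standard.
    Missing scores propagate.
    """
    if cutoff not in (16, 20):
        logger.warning("non-standard CES-D cutoff %s (conventional: 16 or 20)", cutoff)
    x = np.asarray(scores, dtype=float)
    finite = x[np.isfinite(x)]
    if finite.size and (finite.min() < 0 or finite.max() > 60):
        raise ValueError("CES-D scores must lie in [0, 60]")
    out = (x >= cutoff).astype(float)
    out[~np.isfinite(x)] = np.nan
    return out


def percent_difference(beta: float, mean_mtdnacn: float, sd_mtdnacn: float) -> float:
    """Convert a standardized effect to a percent change in mtDNAcn.

    A beta of SD-per-unit-of-predictor times the SD/mean ratio of mtDNAcn
    gives the fractional change per unit; multiply the result by 10 for a
    per-decade age effect.
    """
    if mean_mtdnacn <= 0:
        raise ValueError("mean_mtdnacn must be > 0")
    return 100.0 * beta * sd_mtdnacn / mean_mtdnacn
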