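"""Random-effects meta-analysis across cohorts and FDR control.

Per-cohort standardized effects are pooled with the DerSimonian-Laird
estimator: fixed weights w = 1/se^2 give Cochran's Q, the between-study
variance tau^2 = max(0, (Q - (k-1)) / (sum w - sum w^2 / sum w)), and
random weights w* = 1/(se^2 + tau^2) give the pooled effect, its SE, a
Wald 95% CI, and a two-sided normal p. Inconsistency is summarized as
I^2 = max(0, (Q - df)/Q) * 100. When Q <= k-1 the between-study variance
truncates to zero and random-effects pooling coincides with fixed-effect
pooling.

``se_from_beta_p`` recovers a standard error from a printed effect and
two-sided p-value (assuming a normal test), which lets published
per-cohort results be pooled without access to the underlying data.
The false-discovery-rate family for trait associations is the 35
personality traits; Benjamini-Hochberg adjustment is delegated to
statsmodels.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests


@dataclass
class MetaResult:
    """Pooled effect of one trait across cohorts."""

    trait: str
    pooled_beta: float
    pooled_se: float
    ci95: tuple[float, float]
    p: float
    tau2: float
    Q: float
    p_Q: float
    I2: float
    k: int
    p_fdr: float | None = None


def se_from_beta_p(beta: float, p: float) -> float:
    """Standard error implied by an effect and its two-sided p-value.

    Inverts the normal Wald test: se = |beta| / z(p/2 upper tail).
    """
    if not 0.0 < p < 1.0:
        raise ValueError("p must lie strictly between 0 and 1")
    if beta == 0:
        raise ValueError("beta must be nonzero to recover a standard error")
    return abs(beta) / stats.norm.isf(p / 2.0)


def pool_random_effects(
    results: Sequence[tuple[float, float]],
    trait: str = "",
) -> MetaResult:
    """DerSimonian-Laird pooling of (beta, se) pairs from k >= 2 studies."""
    betas = np.array([b for b, _ in results], dtype=float)
    ses = np.array([s for _, s in results], dtype=float)
    k = len(betas)
    if k < 2:
        raise ValueError("need at least two studies to pool")
    if np.any(ses < 0):
        raise ValueError("standard errors must be non-negative")
    if np.any(ses == 0):
        if np.ptp(betas) == 0:
            # degenerate but well-defined: identical effects known exactly
            return MetaResult(
                trait=trait,
                pooled_beta=float(betas[0]),
                pooled_se=0.0,
                ci95=(float(betas[0]), float(betas[0])),
                p=0.0,
                tau2=0.0,
                Q=0.0,
                p_Q=1.0,
                I2=0.0,
                k=k,
            )
        raise ValueError("zero standard error with discordant effects")

    w = 1.0 / ses**2
    beta_fixed = float(np.sum(w * betas) / np.sum(w))
    Q = float(np.sum(w * (betas - beta_fixed) ** 2))
    df = k - 1
    tau2 = max(0.0, (Q - df) / (np.sum(w) - np.sum(w**2) / np.sum(w)))
    w_star = 1.0 / (ses**2 + tau2)
    pooled = float(np.sum(w_star * betas) / np.sum(w_star))
    pooled_se = float(1.0 / np.sqrt(np.sum(w_star)))
    z = pooled / pooled_se
    p = float(2.0 * stats.norm.sf(abs(z)))
    half = 1.959963984540054 * pooled_se
    I2 = max(0.0, (Q - df) / Q) * 100.0 if Q > 0 else 0.0
    return MetaResult(
        trait=trait,
        pooled_beta=pooled,
        pooled_se=pooled_se,
        ci95=(pooled - half, pooled + half),
        p=p,
        tau2=float(tau2),
        Q=Q,
        p_Q=float(stats.chi2.sf(Q, df)),
        I2=float(I2),
        k=k,
    )


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def pool_table(
    assoc_tables: Iterable[pd.DataFrame],
    fdr_family: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Pool per-cohort association tables trait by trait.

    Each input table needs columns ``trait``, ``beta``, ``se``. BH-FDR
    adjustment is applied only over ``fdr_family`` traits (e.g. the 35
    personality traits); other rows keep an unadjusted ``p_fdr`` of NaN.
    """
    stacked = pd.concat(list(assoc_tables), ignore_index=True)
    rows = []
    for trait, grp in stacked.groupby("trait", sort=False):
        res = pool_random_effects(list(zip(grp["beta"], grp["se"])), trait=trait)
        rows.append(
            dict(
                trait=trait,
                pooled_beta=res.pooled_beta,
                pooled_se=res.pooled_se,
                ci_low=res.ci95[0],
                ci_high=res.ci95[1],
                p=res.p,
                tau2=res.tau2,
                Q=res.Q,
                p_Q=res.p_Q,
                I2=res.I2,
                k=res.k,
            )
        )
    out = pd.DataFrame(rows)
    out["p_fdr"] = np.nan
    if fdr_family is not None:
        mask = out["trait"].isin(fdr_family)
        if mask.any():
            out.loc[mask, "p_fdr"] = bh_fdr(out.loc[mask, "p"].to_numpy())
    return out
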