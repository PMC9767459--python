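"""Product-of-coefficients mediation with bootstrap inference.

Whether mtDNAcn carries part of the PMI-mortality association is tested
with the classical three-model decomposition, all fit by least squares
with the same covariates (age and sex by default):

    outcome  ~ exposure + covariates              -> total effect c
    mediator ~ exposure + covariates              -> path a
    outcome  ~ exposure + mediator + covariates   -> direct c' and path b

The indirect effect is a*b, and because all three fits are linear with a
shared covariate set the decomposition c = c' + a*b holds exactly. The
binary death indicator is treated as a linear-probability outcome: that
is the model under which the additive decomposition is an identity
(it fails for logistic links), and it keeps every path in probability
units. Exposure and mediator stay on their native scales (PMI points,
mtDNAcn copies).

Inference on a*b resamples participants with replacement, refits the
mediator and outcome models per resample, and reports the percentile 95%
CI, a bootstrap sign-test p-value with the add-one correction
(r+1)/(B+1), and a normal-approximation z-test on the bootstrap SE.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


@dataclass
class MediationResult:
    """Decomposition of an exposure effect into direct and mediated parts."""

    exposure: str
    mediator: str
    outcome: str
    total_c: float
    direct_c_prime: float
    path_a: float
    path_b: float
    indirect_ab: float
    n: int
    boot_ci95: tuple[float, float] | None = None
    boot_p: float | None = None
    boot_se: float | None = None
    boot_p_normal: float | None = None
    boot_path_se: dict[str, float] | None = None
    n_boot: int | None = None
    seed: int | None = None


def _lstsq_coef(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    return np.linalg.lstsq(X, y, rcond=None)[0]


def _design(data: pd.DataFrame, cols: list[str]) -> np.ndarray:
    X = np.column_stack([np.ones(len(data))] + [data[c].to_numpy(dtype=float) for c in cols])
    return X


def fit_mediation(
    data: pd.DataFrame,
    exposure: str = "pmi",
    mediator: str = "mtdnacn",
    outcome: str = "dead",
    covariates: tuple[str, ...] = ("age", "sex"),
) -> MediationResult:
    """Point estimates of the total, direct, and indirect effects."""
    cols = [exposure, mediator, outcome, *covariates]
    sub = data[cols].dropna()
    n = len(sub)
    x = sub[exposure].to_numpy(dtype=float)
    m = sub[mediator].to_numpy(dtype=float)
    y = sub[outcome].to_numpy(dtype=float)
    if np.ptp(x) == 0:
        raise ValueError(f"exposure {exposure!r} has zero variance")
    if np.ptp(m) == 0:
        raise ValueError(f"mediator {mediator!r} has zero variance")
    if not set(np.unique(y)).issubset({0.0, 1.0}):
        raise ValueError(f"outcome {outcome!r} must be binary 0/1")

    Xc = _design(sub, [exposure, *covariates])
    Xm = _design(sub, [exposure, mediator, *covariates])
    total_c = float(_lstsq_coef(Xc, y)[1])
    path_a = float(_lstsq_coef(Xc, m)[1])
    coef_out = _lstsq_coef(Xm, y)
    direct, path_b = float(coef_out[1]), float(coef_out[2])
    return MediationResult(
        exposure=exposure,
        mediator=mediator,
        outcome=outcome,
        total_c=total_c,
        direct_c_prime=direct,
        path_a=path_a,
        path_b=path_b,
        indirect_ab=path_a * path_b,
        n=n,
    )


def bootstrap_indirect(
    data: pd.DataFrame,
    exposure: str = "pmi",
    mediator: str = "mtdnacn",
    outcome: str = "dead",
    covariates: tuple[str, ...] = ("age", "sex"),
    n_boot: int = 5000,
    seed: int = 0,
) -> MediationResult:
    """Mediation point estimates plus bootstrap inference on a*b.

    Participants are the resampling unit. A degenerate resample (zero
    variance in exposure or mediator) is redrawn and counted in the log.
    Deterministic given ``seed``.
    """
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100")
    result = fit_mediation(data, exposure, mediator, outcome, covariates)
    sub = data[[exposure, mediator, outcome, *covariates]].dropna()
    n = len(sub)
    x = sub[exposure].to_numpy(dtype=float)
    m = sub[mediator].to_numpy(dtype=float)
    y = sub[outcome].to_numpy(dtype=float)
    Z = np.column_stack([sub[c].to_numpy(dtype=float) for c in covariates]) if covariates else np.empty((n, 0))
    ones = np.ones(n)

    rng = np.random.default_rng(seed)
    draws = np.empty((n_boot, 4))  # a, b, c', ab per resample
    redraws = 0
    for b in range(n_boot):
        while True:
            idx = rng.integers(0, n, n)
            if np.ptp(x[idx]) > 0 and np.ptp(m[idx]) > 0:
                break
            redraws += 1
        Xa = np.column_stack([ones, x[idx], Z[idx]])
        a_hat = _lstsq_coef(Xa, m[idx])[1]
        Xb = np.column_stack([ones, x[idx], m[idx], Z[idx]])
        coef = _lstsq_coef(Xb, y[idx])
        c_prime_hat, b_hat = coef[1], coef[2]
        draws[b] = (a_hat, b_hat, c_prime_hat, a_hat * b_hat)
    if redraws:
        logger.info("bootstrap_indirect: %d degenerate resamples redrawn", redraws)
    ab = draws[:, 3]

    lo, hi = np.percentile(ab, [2.5, 97.5])
    n_le = int(np.sum(ab <= 0))
    n_ge = int(np.sum(ab >= 0))
    boot_p = min(1.0, 2.0 * min(n_le + 1, n_ge + 1) / (n_boot + 1))
    boot_se = float(ab.std(ddof=1))
    from scipy import stats

    z = result.indirect_ab / boot_se if boot_se > 0 else np.inf
    path_sds = draws.std(axis=0, ddof=1)
    result.boot_path_se = {
        "a": float(path_sds[0]),
        "b": float(path_sds[1]),
        "c_prime": float(path_sds[2]),
        "ab": float(path_sds[3]),
        # total effect per resample is c' + a*b by the linear identity
        "c": float((draws[:, 2] + draws[:, 3]).std(ddof=1)),
    }
    result.boot_ci95 = (float(lo), float(hi))
    result.boot_p = float(boot_p)
    result.boot_se = boot_se
    result.boot_p_normal = float(2.0 * stats.norm.sf(abs(z)))
    result.n_boot = n_boot
    result.seed = seed
    return result
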