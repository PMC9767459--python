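"""Cox proportional hazards and Kaplan-Meier survival analysis.

``fit_cox`` maximizes the Cox partial likelihood with Breslow handling of
tied event times by Newton-Raphson with step-halving; standard errors
come from the inverse observed information. Breslow ties are the simplest
consistent choice and coincide with every other convention when event
times are distinct, as they essentially are for real-valued follow-up.
Follow-up time is time since study entry, with age entering as a
covariate.

``kaplan_meier`` wraps the lifelines product-limit estimator and returns
one step function per group (time, number at risk, events, survival).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from scipy import stats

logger = logging.getLogger(__name__)


class ConvergenceError(RuntimeError):
    """Raised when the partial-likelihood maximization does not converge."""


@dataclass
class CoxFit:
    """Fitted Cox model: log-hazard ratios with Wald inference."""

    coefficients: dict[str, float]
    se: dict[str, float]
    p: dict[str, float]
    loglik: float
    n_events: int
    n: int
    n_iter: int

    def hazard_ratios(self) -> dict[str, float]:
        return {k: float(np.exp(v)) for k, v in self.coefficients.items()}


def _partial_loglik_parts(beta, X, time, event):
    """Breslow log partial likelihood, score, and observed information.

    Rows must be sorted by descending time so that the risk set at each
    event time is a prefix cumulative sum.
    """
    n, p = X.shape
    eta = X @ beta
    eta = eta - eta.max()  # guard exp overflow; cancels in ratios
    r = np.exp(eta)
    # prefix sums over the risk set {j: time_j >= t}
    S0 = np.cumsum(r)
    S1 = np.cumsum(r[:, None] * X, axis=0)
    S2 = np.cumsum(r[:, None, None] * (X[:, :, None] * X[:, None, :]), axis=0)

    loglik = 0.0
    score = np.zeros(p)
    info = np.zeros((p, p))
    i = 0
    while i < n:
        j = i
        while j + 1 < n and time[j + 1] == time[i]:
            j += 1
        deaths = np.flatnonzero(event[i : j + 1]) + i
        d = len(deaths)
        if d:
            s0, s1, s2 = S0[j], S1[j], S2[j]
            xbar = s1 / s0
            loglik += float(eta[deaths].sum() - d * np.log(s0))
            score += X[deaths].sum(axis=0) - d * xbar
            info += d * (s2 / s0 - np.outer(xbar, xbar))
        i = j + 1
    return loglik, score, info


def fit_cox(
    data: pd.DataFrame,
    covariates: list[str],
    duration_col: str = "time",
    event_col: str = "dead",
    max_iter: int = 50,
    score_tol: float = 1e-8,
    loglik_rtol: float = 1e-10,
) -> CoxFit:
    """Fit a Cox proportional-hazards model.

    Newton-Raphson from beta = 0, halving any step that lowers the
    partial likelihood; converged when the largest absolute score falls
    below ``score_tol`` or the relative log-likelihood change below
    ``loglik_rtol``. Monotone likelihoods (perfect separation) surface as
    a ConvergenceError naming the runaway covariate.
    """
    sub = data[[duration_col, event_col, *covariates]].dropna()
    time = sub[duration_col].to_numpy(dtype=float)
    event = sub[event_col].to_numpy(dtype=int)
    X = sub[covariates].to_numpy(dtype=float)
    n, p = X.shape
    if event.sum() < 1:
        raise ValueError("no events: cannot fit a Cox model")
    for j, c in enumerate(covariates):
        if np.ptp(X[event == 1, j]) == 0 and np.ptp(X[:, j]) == 0:
            raise ValueError(f"covariate {c!r} is constant")

    order = np.argsort(-time, kind="stable")
    time, event, X = time[order], event[order], X[order]
    center = X.mean(axis=0)
    Xc = X - center  # improves conditioning; coefficients are unchanged

    beta = np.zeros(p)
    loglik, score, info = _partial_loglik_parts(beta, Xc, time, event)
    for it in range(1, max_iter + 1):
        try:
            step = np.linalg.solve(info, score)
        except np.linalg.LinAlgError as err:
            raise ConvergenceError(f"singular information matrix: {err}") from err
        new_beta = beta + step
        new_ll, new_score, new_info = _partial_loglik_parts(new_beta, Xc, time, event)
        halvings = 0
        while new_ll < loglik and halvings < 30:
            step /= 2.0
            new_beta = beta + step
            new_ll, new_score, new_info = _partial_loglik_parts(new_beta, Xc, time, event)
            halvings += 1
        rel_change = abs(new_ll - loglik) / max(1.0, abs(loglik))
        beta, loglik, score, info = new_beta, new_ll, new_score, new_info
        if np.max(np.abs(score)) < score_tol or rel_change < loglik_rtol:
            break
    else:
        worst = covariates[int(np.argmax(np.abs(beta)))]
        raise ConvergenceError(
            f"no convergence in {max_iter} iterations; covariate {worst!r} may "
            "separate events perfectly (monotone likelihood)"
        )
    if np.max(np.abs(beta)) > 15:
        worst = covariates[int(np.argmax(np.abs(beta)))]
        raise ConvergenceError(
            f"diverging coefficient for {worst!r}: monotone likelihood "
            "(perfect separation)"
        )

    cov_beta = np.linalg.inv(info)
    se = np.sqrt(np.diag(cov_beta))
    z = beta / se
    pvals = 2.0 * stats.norm.sf(np.abs(z))
    return CoxFit(
        coefficients=dict(zip(covariates, map(float, beta))),
        se=dict(zip(covariates, map(float, se))),
        p=dict(zip(covariates, map(float, pvals))),
        loglik=float(loglik),
        n_events=int(event.sum()),
        n=n,
        n_iter=it,
    )


def kaplan_meier(
    data: pd.DataFrame,
    group_col: str | None = None,
    duration_col: str = "time",
    event_col: str = "dead",
) -> dict[str, pd.DataFrame]:
    """Product-limit survival curves, optionally per group.

    Returns one DataFrame per group with columns ``time``, ``at_risk``,
    ``events``, ``censored``, ``survival``; survival starts at 1 and is
    non-increasing, and purely censored times do not drop the curve.
    Empty groups are omitted with a warning.
    """
    if group_col is None:
        groups = {"all": data}
    else:
        groups = {str(k): g for k, g in data.groupby(group_col, observed=False)}
    out: dict[str, pd.DataFrame] = {}
    for label, g in groups.items():
        g = g[[duration_col, event_col]].dropna()
        if g.empty:
            warnings.warn(f"group {label!r} has no usable records; omitted", stacklevel=2)
            continue
        kmf = KaplanMeierFitter()
        kmf.fit(g[duration_col], event_observed=g[event_col])
        tab = kmf.event_table.loc[kmf.event_table["removed"] > 0]
        surv = kmf.survival_function_["KM_estimate"]
        out[label] = pd.DataFrame(
            {
                "time": tab.index.to_numpy(dtype=float),
                "at_risk": tab["at_risk"].to_numpy(dtype=int),
                "events": tab["observed"].to_numpy(dtype=int),
                "censored": tab["censored"].to_numpy(dtype=int),
                "survival": surv.loc[tab.index].to_numpy(dtype=float),
            }
        ).reset_index(drop=True)
    return out
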