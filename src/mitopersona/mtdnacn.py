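"""mtDNA copy number from sequencing coverage, and the covariate screen.

A diploid cell carries two copies of the nuclear genome, so mean
sequencing depth over the autosomes measures "per two genome copies"
coverage. Depth is proportional to template copy number, hence

    copies per cell = 2 * (mean mtDNA depth) / (mean autosomal depth).

The estimator starts from per-sample coverage summaries; extracting mean
depths from alignments is upstream-tool territory. Whole-blood estimates
are known to be inflated by platelets (mtDNA without nuclear DNA), which
is handled downstream by covariate adjustment, not by correcting the
estimate itself.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from mitopersona.traits import SCREEN_COVARIATES

logger = logging.getLogger(__name__)


def copy_number(mt_coverage, autosomal_coverage):
    """Vectorized ratio estimator: 2 * mt depth / autosomal depth."""
    return 2.0 * np.asarray(mt_coverage, dtype=float) / np.asarray(
        autosomal_coverage, dtype=float
    )


def estimate_mtdnacn(coverage: pd.DataFrame) -> pd.DataFrame:
    """Estimate copies per cell for each sample in a coverage summary.

    Parameters
    ----------
    coverage
        Table with columns ``sample_id``, ``mt_coverage``,
        ``autosomal_coverage``.

    Returns
    -------
    Table with ``sample_id`` and ``copies_per_cell``. Samples with
    non-positive autosomal coverage cannot be normalized; they are dropped
    and each exclusion is logged.
    """
    required = {"sample_id", "mt_coverage", "autosomal_coverage"}
    missing = required - set(coverage.columns)
    if missing:
        raise ValueError(f"coverage table lacks columns: {sorted(missing)}")
    bad = ~(coverage["autosomal_coverage"] > 0)
    for sid in coverage.loc[bad, "sample_id"]:
        logger.warning("excluding sample %s: non-positive autosomal coverage", sid)
    ok = coverage.loc[~bad]
    return pd.DataFrame(
        {
            "sample_id": ok["sample_id"].to_numpy(),
            "copies_per_cell": copy_number(
                ok["mt_coverage"].to_numpy(), ok["autosomal_coverage"].to_numpy()
            ),
        }
    )


def covariate_screen(
    data: pd.DataFrame,
    covariates: list[str] | None = None,
    outcome: str = "mtdnacn",
) -> pd.DataFrame:
    """Simple linear regression of mtDNAcn on each candidate covariate.

    One unadjusted least-squares fit per covariate (age, sex, sequence
    coverage, platelet count, WBC count, and the five leukocyte
    percentages by default), reporting slope, SE, two-sided t-test
    p-value, and the pairwise-complete n, sorted by p. This is the
    screening step that decides which variables enter the adjusted trait
    models. A constant covariate has no defined slope and is reported as
    not estimable (NaN).
    """
    covariates = SCREEN_COVARIATES if covariates is None else list(covariates)
    rows = []
    y_all = data[outcome].to_numpy(dtype=float)
    for cov in covariates:
        x_all = data[cov].to_numpy(dtype=float)
        keep = np.isfinite(x_all) & np.isfinite(y_all)
        x, y = x_all[keep], y_all[keep]
        n = len(x)
        if n < 3:
            raise ValueError(f"covariate {cov!r}: need >= 3 complete pairs, got {n}")
        if np.ptp(x) == 0:
            rows.append(dict(covariate=cov, slope=np.nan, se=np.nan, p=np.nan, n=n))
            logger.warning("covariate %s is constant; slope not estimable", cov)
            continue
        fit = stats.linregress(x, y)
        rows.append(dict(covariate=cov, slope=fit.slope, se=fit.stderr, p=fit.pvalue, n=n))
    return (
        pd.DataFrame(rows)
        .sort_values("p", na_position="last")
        .reset_index(drop=True)
    )
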