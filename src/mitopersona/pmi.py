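"""Personality-mortality index (PMI) and the vulnerability/self-discipline
cross-classification.

The PMI counts, for each participant, how many of four mortality-linked
facets sit on the favorable side of the cohort median: vulnerability
*below* its median scores one point, while activity, self-discipline, and
competence each score one point when *above* their medians. The index runs
0 (least favorable profile) to 4 (most favorable). Ties at a median score
zero: the scoring rule is strictly directional, and with continuous
T-scores exact ties are rare.

Medians are computed within the analyzed cohort, so the index is invariant
to any cohort-wide strictly monotone transform of a facet.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

GROUP_LABELS = ["LVHD", "LVLD", "HVHD", "HVLD"]


def _asarray(x) -> np.ndarray:
    return np.asarray(x, dtype=float)


def compute_pmi(
    vulnerability,
    activity,
    self_discipline,
    competence,
) -> pd.DataFrame:
    """Score the four-facet personality-mortality index.

    Parameters
    ----------
    vulnerability, activity, self_discipline, competence
        T-score vectors of equal length for the analyzed cohort.

    Returns
    -------
    DataFrame with one 0/1 column per facet (``score_<facet>``) and an
    integer ``pmi`` column in {0,...,4}. Participants missing any facet are
    left unscored (NaN throughout) and counted in the log.
    """
    facets = {
        "vulnerability": _asarray(vulnerability),
        "activity": _asarray(activity),
        "self_discipline": _asarray(self_discipline),
        "competence": _asarray(competence),
    }
    n = len(facets["vulnerability"])
    for name, v in facets.items():
        if len(v) != n:
            raise ValueError(f"facet {name!r} has length {len(v)}, expected {n}")

    complete = np.ones(n, dtype=bool)
    for v in facets.values():
        complete &= np.isfinite(v)
    n_missing = int((~complete).sum())
    if n_missing:
        logger.info("compute_pmi: %d participant(s) unscored (missing facets)", n_missing)

    out = pd.DataFrame(index=pd.RangeIndex(n))
    for name, v in facets.items():
        med = np.median(v[complete]) if complete.any() else np.nan
        if name == "vulnerability":
            score = (v < med).astype(float)
        else:
            score = (v > med).astype(float)
        score[~complete] = np.nan
        out[f"score_{name}"] = score
    out["pmi"] = out[[f"score_{f}" for f in facets]].sum(axis=1, skipna=False)
    return out


def cross_classify(vulnerability, self_discipline) -> pd.Series:
    """Assign the 2x2 vulnerability/self-discipline personality types.

    Low vulnerability means strictly below the cohort median; high
    self-discipline means strictly above. Labels combine the two letters,
    e.g. ``LVHD`` = low vulnerability / high self-discipline (the reference
    group with the perceived lowest mortality risk) and ``HVLD`` its
    opposite. Participants missing either facet get a missing label.
    """
    v = _asarray(vulnerability)
    d = _asarray(self_discipline)
    if len(v) != len(d):
        raise ValueError("facet vectors must have equal length")
    complete = np.isfinite(v) & np.isfinite(d)
    med_v = np.median(v[complete]) if complete.any() else np.nan
    med_d = np.median(d[complete]) if complete.any() else np.nan
    low_v = v < med_v
    high_d = d > med_d
    labels = np.where(low_v, "LV", "HV").astype(object) + np.where(high_d, "HD", "LD")
    labels[~complete] = None
    return pd.Series(
        pd.Categorical(labels, categories=GROUP_LABELS), name="vuln_discipline_group"
    )
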