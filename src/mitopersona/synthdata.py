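"""Synthetic two-cohort generator.

Emulates the data structure of the aging-cohort analyses downstream:
NEO-PI-R T-score traits with a configurable block correlation structure,
CES-D depressive-symptom counts, a five-class leukocyte differential,
platelet and WBC counts, an mtDNAcn per cell with planted trait / age /
sex effects, whole-genome coverage summaries at a configurable depth, and
a PMI -> mtDNAcn -> mortality mediation mechanism with configurable path
coefficients. Real individual-level cohort data of this kind are access
restricted, so all downstream stages are exercised on these simulations.

Mechanics
---------
* Traits are multivariate normal on the T-score scale. The default
  correlation matrix has r=0.5 within a domain block (domain plus its six
  facets) and r=0.2 between blocks.
* mtDNAcn (copies/cell) is built on the standardized scale::

      mtdnacn = mean + sd * (sum_t beta_t z_t + beta_age (age - mean_age)
                             + beta_sex 1[male] + eps)            eps ~ N(0,1)
                + path_a * (PMI - 2)

  so the marginal SD equals ``mtdnacn_sd`` when all effects are zero, and
  ``path_a`` plants a mediation path in copies per PMI point. PMI is the
  true four-facet index of the drawn traits.
* Death follows a linear-probability mechanism,
  ``p = baseline + c' (PMI - 2) + b (mtdnacn - mean)`` clipped to [0, 1],
  and survival time is exponential with the per-person rate solved so that
  P(death within follow-up) equals that probability; the binary death
  indicator and the survival times are therefore mutually consistent.
* Coverage: autosomal depth is Gamma-distributed around the configured
  mean; mitochondrial depth is (mtdnacn / 2) x autosomal depth times a
  mean-one lognormal factor with the configured coefficient of variation.
  Copy numbers and autosomal depths are stored at single precision (far
  beyond physical accuracy), which makes the zero-noise coverage round
  trip through the ratio estimator exact at the bit level.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from mitopersona import pmi as pmi_mod
from mitopersona.traits import DOMAINS, TRAITS, domain_of

logger = logging.getLogger(__name__)


class ConfigurationError(ValueError):
    """Raised for an invalid simulation configuration."""


def default_trait_corr(
    traits: list[str] | None = None,
    within_domain: float = 0.5,
    between_domain: float = 0.2,
) -> pd.DataFrame:
    """Block correlation matrix over traits.

    A domain and its six facets form one block with correlation
    ``within_domain``; pairs from different blocks get ``between_domain``.
    The published facet intercorrelations are not available, so this
    reproduces the qualitative block structure the inventory assumes.
    """
    traits = list(TRAITS if traits is None else traits)
    k = len(traits)
    corr = np.full((k, k), between_domain, dtype=float)
    for i, a in enumerate(traits):
        for j, b in enumerate(traits):
            if domain_of(a) == domain_of(b):
                corr[i, j] = within_domain
    np.fill_diagonal(corr, 1.0)
    return pd.DataFrame(corr, index=traits, columns=traits)


#: Typical leukocyte differential means (percent); sums to 100.
LEUKOCYTE_MEANS = {
    "pct_neutrophils": 60.0,
    "pct_lymphocytes": 30.0,
    "pct_monocytes": 7.0,
    "pct_eosinophils": 2.5,
    "pct_basophils": 0.5,
}


@dataclass
class SimConfig:
    """Parameters of one synthetic cohort.

    Demographic defaults follow the older US aging cohort (n=722, age
    74.88 +/- 10.86 years, 48.1% female, ~35.8x autosomal depth); traits
    default to normative T-scores (mean 50, SD 10). ``mtdnacn_mean`` /
    ``mtdnacn_sd`` default to 150 +/- 41.7 copies per cell: the SD/mean
    ratio of 0.278 is the one implied by a 0.014 SD-per-year age effect
    equating to a 3.89% decline per decade.
    """

    n_participants: int = 722
    seed: int = 0
    label: str = "cohort"
    mean_age: float = 74.88
    sd_age: float = 10.86
    prop_female: float = 0.481
    mean_autosomal_coverage: float = 35.8
    autosomal_coverage_cv: float = 0.05
    coverage_cv: float = 0.05  # multiplicative CV of the mt-depth noise
    trait_means: dict[str, float] = field(default_factory=dict)
    trait_sds: dict[str, float] = field(default_factory=dict)
    trait_corr: pd.DataFrame | None = None
    beta_trait_mtdnacn: dict[str, float] = field(default_factory=dict)
    beta_age: float = 0.0  # SD of mtDNAcn per year
    beta_sex_male: float = 0.0  # SD offset for males
    mtdnacn_mean: float = 150.0
    mtdnacn_sd: float = 41.7
    path_a: float = 0.0  # mtDNAcn copies per PMI point
    path_b: float = 0.0  # death-probability change per mtDNAcn copy
    direct_c_prime: float = 0.0  # death-probability change per PMI point
    baseline_mortality: float = 0.3  # death probability at PMI 2, mean mtDNAcn
    followup_years: float = 15.0
    cesd_mean: float = 5.47
    cesd_sd: float = 5.66
    wbc_mean: float = 6.0  # 10^3 cells/uL
    wbc_sd: float = 1.7
    platelet_mean: float = 250.0  # 10^3/uL
    platelet_sd: float = 60.0
    leukocyte_concentration: float = 120.0  # Dirichlet precision
    measurement_error_sd: float = 0.0  # T-score units added to observed traits
    visit_averaging_factor: float = 1.0  # e.g. 1/sqrt(4) for 4 averaged visits

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.n_participants < 1:
            raise ConfigurationError("n_participants must be >= 1")
        if not 0.0 <= self.prop_female <= 1.0:
            raise ConfigurationError("prop_female must lie in [0, 1]")
        for name in ("sd_age", "mtdnacn_sd", "cesd_sd", "wbc_sd", "platelet_sd"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be > 0")
        for t in list(self.trait_means) + list(self.trait_sds) + list(self.beta_trait_mtdnacn):
            if t not in TRAITS:
                raise ConfigurationError(f"unknown trait in config: {t!r}")
        for t, sd in self.trait_sds.items():
            if sd <= 0:
                raise ConfigurationError(f"trait SD for {t!r} must be > 0")
        corr = self.resolved_trait_corr()
        a = corr.to_numpy()
        if list(corr.index) != TRAITS or list(corr.columns) != TRAITS:
            raise ConfigurationError("trait_corr must be indexed by the full trait set")
        if not np.allclose(a, a.T, atol=1e-10):
            raise ConfigurationError("trait_corr must be symmetric")
        if not np.allclose(np.diag(a), 1.0, atol=1e-10):
            raise ConfigurationError("trait_corr must have a unit diagonal")
        if np.linalg.eigvalsh(a).min() < -1e-8:
            raise ConfigurationError("trait_corr must be positive semi-definite")

    def resolved_trait_corr(self) -> pd.DataFrame:
        if self.trait_corr is None:
            return default_trait_corr()
        return self.trait_corr.loc[
            [t for t in TRAITS if t in self.trait_corr.index],
            [t for t in TRAITS if t in self.trait_corr.columns],
        ]

    def trait_mean(self, t: str) -> float:
        return self.trait_means.get(t, 50.0)

    def trait_sd(self, t: str) -> float:
        return self.trait_sds.get(t, 10.0)

    def with_(self, **kwargs) -> "SimConfig":
        return replace(self, **kwargs)


@dataclass
class Cohort:
    """One simulated cohort: a participant table plus a label.

    ``data`` carries one row per participant with demographics, the 35
    trait T-scores, CES-D, blood-cell covariates, the true mtDNAcn, the
    death indicator (``dead``), and the follow-up time (``time``, years).
    """

    data: pd.DataFrame
    label: str = "cohort"

    def __post_init__(self) -> None:
        missing = [t for t in TRAITS if t not in self.data.columns]
        if missing:
            raise ValueError(f"cohort lacks trait columns: {missing[:3]}...")
        if "time" in self.data.columns and not (self.data["time"] > 0).all():
            raise ValueError("survival time must be > 0 for every record")

    def __len__(self) -> int:
        return len(self.data)


def _float32_round(x: np.ndarray) -> np.ndarray:
    """Quantize to single precision (returned as float64).

    Restricting mantissas to 24 bits keeps products of two such values
    exact in double precision, which is what makes the zero-noise coverage
    round trip bit-exact.
    """
    return np.float64(np.float32(x))


def generate_cohort(config: SimConfig) -> Cohort:
    """Draw one synthetic cohort; deterministic given ``config.seed``."""
    config.validate()
    rng = np.random.default_rng([config.seed, 0])
    n = config.n_participants

    age = rng.normal(config.mean_age, config.sd_age, n)
    sex = (rng.random(n) >= config.prop_female).astype(int)  # 0=female, 1=male

    corr = config.resolved_trait_corr().to_numpy()
    sds = np.array([config.trait_sd(t) for t in TRAITS])
    means = np.array([config.trait_mean(t) for t in TRAITS])
    cov = corr * np.outer(sds, sds)
    latent = rng.multivariate_normal(means, cov, size=n, method="eigh")
    observed = latent.copy()
    if config.measurement_error_sd > 0:
        observed = latent + rng.normal(
            0.0,
            config.measurement_error_sd * config.visit_averaging_factor,
            size=latent.shape,
        )
    traits = pd.DataFrame(observed, columns=TRAITS)

    # CES-D: skewed non-negative count matched to the configured moments.
    shape = (config.cesd_mean / config.cesd_sd) ** 2
    scale = config.cesd_sd**2 / config.cesd_mean
    cesd = np.clip(np.round(rng.gamma(shape, scale, n)), 0, 60)

    wbc = np.clip(rng.normal(config.wbc_mean, config.wbc_sd, n), 0.5, None)
    platelets = np.clip(rng.normal(config.platelet_mean, config.platelet_sd, n), 10.0, None)
    alpha = (
        np.array(list(LEUKOCYTE_MEANS.values())) / 100.0 * config.leukocyte_concentration
    )
    leuko = rng.dirichlet(alpha, size=n) * 100.0

    # mtDNAcn on the standardized scale; planted effects use latent traits.
    z = (latent - means) / sds
    lin = np.zeros(n)
    for t, beta in config.beta_trait_mtdnacn.items():
        lin += beta * z[:, TRAITS.index(t)]
    lin += config.beta_age * (age - config.mean_age)
    lin += config.beta_sex_male * (sex == 1)
    lin += rng.normal(0.0, 1.0, n)
    mtdnacn = config.mtdnacn_mean + config.mtdnacn_sd * lin

    pmi_true = pmi_mod.compute_pmi(
        traits["vulnerability"],
        traits["activity"],
        traits["self_discipline"],
        traits["competence"],
    )["pmi"].to_numpy()
    mtdnacn = mtdnacn + config.path_a * (pmi_true - 2.0)
    # floor at one copy per cell: blood always carries some mtDNA, and the
    # coverage model needs a strictly positive copy number
    mtdnacn = _float32_round(np.clip(mtdnacn, 1.0, None))

    # Linear-probability mortality mechanism, then a consistent
    # exponential event time: P(T <= followup) equals the clipped p.
    p_raw = (
        config.baseline_mortality
        + config.direct_c_prime * (pmi_true - 2.0)
        + config.path_b * (mtdnacn - config.mtdnacn_mean)
    )
    p = np.clip(p_raw, 0.0, 1.0)
    n_clipped = int(((p_raw < 0) | (p_raw > 1)).sum())
    if n_clipped > 0.5 * n:
        warnings.warn(
            f"{n_clipped}/{n} death probabilities clipped to [0, 1]; "
            "the linear-probability mechanism is a poor fit to this config",
            stacklevel=2,
        )
    if n_clipped:
        logger.info("generate_cohort[%s]: clipped %d death probabilities", config.label, n_clipped)

    with np.errstate(divide="ignore"):
        rate = -np.log1p(-np.clip(p, 0.0, 1.0 - 1e-12)) / config.followup_years
    u = rng.random(n)
    with np.errstate(divide="ignore"):
        t_latent = np.where(rate > 0, -np.log1p(-u) / np.where(rate > 0, rate, 1.0), np.inf)
    dead = (t_latent <= config.followup_years).astype(int)
    time = np.minimum(t_latent, config.followup_years)
    time = np.maximum(time, 1e-6)

    data = pd.DataFrame(
        {
            "sample_id": [f"{config.label}_{i:05d}" for i in range(n)],
            "age": age,
            "sex": sex,
            "cesd": cesd,
            "wbc_count": wbc,
            "platelet_count": platelets,
        }
    )
    for j, col in enumerate(LEUKOCYTE_MEANS):
        data[col] = leuko[:, j]
    data = pd.concat([data, traits], axis=1)
    data["mtdnacn"] = mtdnacn
    data["pmi_true"] = pmi_true
    data["dead"] = dead
    data["time"] = time
    return Cohort(data=data, label=config.label)


def generate_coverage(cohort: Cohort, config: SimConfig) -> pd.DataFrame:
    """Per-sample mean mitochondrial and autosomal sequencing depths.

    Mitochondrial depth is (mtDNAcn / 2) x autosomal depth perturbed by a
    mean-one lognormal factor with CV ``config.coverage_cv``; with CV zero
    the ratio estimator returns the planted copy numbers bit-exactly.
    """
    if not (cohort.data["mtdnacn"] > 0).all():
        raise ValueError("every record needs a true mtDNAcn > 0")
    rng = np.random.default_rng([config.seed, 1])
    n = len(cohort)

    cv_a = config.autosomal_coverage_cv
    if cv_a == 0:
        auto = np.full(n, config.mean_autosomal_coverage)
    else:
        auto = rng.gamma(1.0 / cv_a**2, config.mean_autosomal_coverage * cv_a**2, n)
    auto = _float32_round(auto)

    cn = cohort.data["mtdnacn"].to_numpy()
    mt = 0.5 * cn * auto
    if config.coverage_cv > 0:
        sigma2 = np.log1p(config.coverage_cv**2)
        mt = mt * rng.lognormal(-sigma2 / 2.0, np.sqrt(sigma2), n)
    return pd.DataFrame(
        {
            "sample_id": cohort.data["sample_id"].to_numpy(),
            "mt_coverage": mt,
            "autosomal_coverage": auto,
        }
    )


def simulate_study(config: SimConfig) -> tuple[Cohort, pd.DataFrame]:
    """Generate a cohort and run its coverage through the estimator.

    Returns the cohort (with ``mtdnacn`` replaced by the coverage-ratio
    estimate, ``mtdnacn_true`` keeping the planted value, and
    ``autosomal_coverage`` merged in) plus the raw coverage table. This is
    the analysis-ready table every downstream stage consumes.
    """
    from mitopersona.mtdnacn import estimate_mtdnacn

    cohort = generate_cohort(config)
    coverage = generate_coverage(cohort, config)
    est = estimate_mtdnacn(coverage)
    merged = cohort.data.rename(columns={"mtdnacn": "mtdnacn_true"}).merge(
        est.rename(columns={"copies_per_cell": "mtdnacn"}), on="sample_id"
    )
    merged = merged.merge(coverage[["sample_id", "autosomal_coverage"]], on="sample_id")
    return Cohort(data=merged, label=cohort.label), coverage


def exponential_survival(
    log_hazards: np.ndarray,
    baseline_rate: float,
    followup_years: float,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Event times under a proportional-hazards exponential model.

    Helper for planted log-hazard-ratio simulations: the hazard of person
    i is ``baseline_rate * exp(log_hazards[i])``; times beyond the
    follow-up horizon are administratively censored.
    """
    rate = baseline_rate * np.exp(np.asarray(log_hazards, dtype=float))
    t = rng.exponential(1.0 / rate)
    dead = (t <= followup_years).astype(int)
    return pd.DataFrame({"time": np.minimum(t, followup_years), "dead": dead})


def blsa_like_config(**overrides) -> SimConfig:
    """Older, deeply sequenced cohort (n=722, ~35.8x)."""
    base = dict(
        n_participants=722,
        label="BLSA",
        mean_age=74.88,
        sd_age=10.86,
        prop_female=0.481,
        mean_autosomal_coverage=35.8,
        cesd_mean=5.47,
        cesd_sd=5.66,
        beta_age=-0.014,
        beta_sex_male=-0.2,
        visit_averaging_factor=0.5,  # traits averaged over ~4 visits
    )
    base.update(overrides)
    return SimConfig(**base)


def sardinia_like_config(**overrides) -> SimConfig:
    """Younger, low-pass cohort (n=587, ~3.8x)."""
    base = dict(
        n_participants=587,
        label="SardiNIA",
        mean_age=57.28,
        sd_age=13.24,
        prop_female=0.622,
        mean_autosomal_coverage=3.8,
        cesd_mean=11.66,
        cesd_sd=7.79,
        beta_age=-0.0065,
        beta_sex_male=-0.2,
    )
    base.update(overrides)
    return SimConfig(**base)


def mediation_scenario(
    n: int = 20_000,
    seed: int = 0,
    path_a: float = 5.0,
    path_b: float = -0.02,
    direct_c_prime: float = -0.05,
    **overrides,
) -> SimConfig:
    """Config with a planted PMI -> mtDNAcn -> death mediation structure.

    The mediator's residual SD is kept small (4 copies) so that a path-b
    of -0.02 probability per copy keeps death probabilities inside [0, 1]
    (<1% boundary clipping) and the linear-probability mechanism the
    mediation model assumes actually holds.
    """
    base = dict(
        n_participants=n,
        seed=seed,
        label="mediation",
        path_a=path_a,
        path_b=path_b,
        direct_c_prime=direct_c_prime,
        mtdnacn_sd=4.0,
        baseline_mortality=0.5,
        coverage_cv=0.0,
        autosomal_coverage_cv=0.05,
    )
    base.update(overrides)
    return SimConfig(**base)
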