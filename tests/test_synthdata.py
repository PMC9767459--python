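"""Generator behavior: determinism, planted moments and effects, and the
coverage round trip."""

import numpy as np
import pandas as pd
import pytest

from mitopersona import assoc, mtdnacn, synthdata
from mitopersona.synthdata import ConfigurationError, SimConfig
from mitopersona.traits import TRAITS


class TestConfigValidation:
    def test_rejects_non_psd_correlation(self):
        corr = synthdata.default_trait_corr()
        corr.iloc[0, 1] = corr.iloc[1, 0] = 0.99
        corr.iloc[0, 2] = corr.iloc[2, 0] = 0.99
        corr.iloc[1, 2] = corr.iloc[2, 1] = -0.99
        with pytest.raises(ConfigurationError, match="positive semi-definite"):
            SimConfig(trait_corr=corr)

    def test_rejects_asymmetric_correlation(self):
        corr = synthdata.default_trait_corr()
        corr.iloc[0, 1] = 0.9
        with pytest.raises(ConfigurationError, match="symmetric"):
            SimConfig(trait_corr=corr)

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(prop_female=1.2),
            dict(n_participants=0),
            dict(sd_age=-1.0),
            dict(trait_sds={"neuroticism": 0.0}),
            dict(beta_trait_mtdnacn={"not_a_trait": 0.1}),
        ],
    )
    def test_rejects_invalid_scalars(self, kwargs):
        with pytest.raises(ConfigurationError):
            SimConfig(**kwargs)


class TestDeterminism:
    def test_same_seed_byte_identical(self):
        cfg = synthdata.blsa_like_config(n_participants=60, seed=5)
        a = synthdata.generate_cohort(cfg)
        b = synthdata.generate_cohort(cfg)
        assert a.data.to_csv(sep="\t") == b.data.to_csv(sep="\t")
        cov_a = synthdata.generate_coverage(a, cfg)
        cov_b = synthdata.generate_coverage(b, cfg)
        assert cov_a.to_csv(sep="\t") == cov_b.to_csv(sep="\t")

    def test_different_seeds_differ(self):
        a = synthdata.generate_cohort(synthdata.blsa_like_config(n_participants=60, seed=5))
        b = synthdata.generate_cohort(synthdata.blsa_like_config(n_participants=60, seed=6))
        assert not np.array_equal(a.data["mtdnacn"], b.data["mtdnacn"])


class TestCohortStructure:
    def test_demographic_moments_match_config(self):
        cfg = synthdata.blsa_like_config(n_participants=5000, seed=1)
        data = synthdata.generate_cohort(cfg).data
        n = len(data)
        assert abs(data["age"].mean() - 74.88) < 2 * 10.86 / np.sqrt(n)
        assert abs((data["sex"] == 0).mean() - 0.481) < 2 * 0.5 / np.sqrt(n)
        assert abs(data["neuroticism"].mean() - 50.0) < 2 * 10 / np.sqrt(n)
        assert abs(data["neuroticism"].std() - 10.0) < 0.5

    def test_leukocyte_percentages_sum_to_100(self):
        data = synthdata.generate_cohort(SimConfig(n_participants=200, seed=2)).data
        total = sum(
            data[c]
            for c in [
                "pct_neutrophils",
                "pct_lymphocytes",
                "pct_monocytes",
                "pct_eosinophils",
                "pct_basophils",
            ]
        )
        assert np.allclose(total, 100.0)

    def test_cesd_moments_and_range(self):
        data = synthdata.generate_cohort(
            synthdata.blsa_like_config(n_participants=20000, seed=3)
        ).data
        assert data["cesd"].between(0, 60).all()
        assert abs(data["cesd"].mean() - 5.47) < 0.2
        assert abs(data["cesd"].std() - 5.66) < 0.3

    def test_survival_times_positive_and_censoring_consistent(self):
        cfg = SimConfig(n_participants=500, seed=4, baseline_mortality=0.4)
        data = synthdata.generate_cohort(cfg).data
        assert (data["time"] > 0).all()
        censored = data["dead"] == 0
        assert np.allclose(data.loc[censored, "time"], cfg.followup_years)
        assert (data.loc[~censored, "time"] <= cfg.followup_years).all()


class TestNullConfiguration:
    def test_no_effects_no_trait_correlation_with_mtdnacn(self):
        cfg = SimConfig(n_participants=10_000, seed=11)
        data = synthdata.generate_cohort(cfg).data
        for trait in TRAITS:
            r = np.corrcoef(data[trait], data["mtdnacn"])[0, 1]
            assert abs(r) < 0.03, trait

    def test_null_mtdnacn_moments(self):
        cfg = SimConfig(n_participants=20_000, seed=12)
        data = synthdata.generate_cohort(cfg).data
        assert abs(data["mtdnacn"].mean() - 150.0) < 1.0
        assert abs(data["mtdnacn"].std() - 41.7) < 1.0


class TestCoverage:
    def test_zero_noise_proportionality_exact_value(self):
        cohort = synthdata.Cohort(
            pd.DataFrame({**{t: [50.0] for t in TRAITS}, "sample_id": ["s1"], "mtdnacn": [150.0]}),
            label="toy",
        )
        cfg = SimConfig(n_participants=1, coverage_cv=0.0, autosomal_coverage_cv=0.0)
        cov = synthdata.generate_coverage(cohort, cfg)
        assert cov["autosomal_coverage"].iloc[0] == pytest.approx(35.8, abs=1e-5)
        assert cov["mt_coverage"].iloc[0] == 0.5 * 150.0 * cov["autosomal_coverage"].iloc[0]

    def test_zero_noise_round_trip_is_bit_exact(self):
        cfg = synthdata.blsa_like_config(n_participants=2000, seed=13, coverage_cv=0.0)
        cohort = synthdata.generate_cohort(cfg)
        est = mtdnacn.estimate_mtdnacn(synthdata.generate_coverage(cohort, cfg))
        assert np.array_equal(
            est["copies_per_cell"].to_numpy(), cohort.data["mtdnacn"].to_numpy()
        )

    def test_multiplicative_noise_preserves_mean(self):
        cfg = synthdata.blsa_like_config(n_participants=10_000, seed=14, coverage_cv=0.05)
        cohort = synthdata.generate_cohort(cfg)
        est = mtdnacn.estimate_mtdnacn(synthdata.generate_coverage(cohort, cfg))
        planted_mean = cohort.data["mtdnacn"].mean()
        assert abs(est["copies_per_cell"].mean() / planted_mean - 1) < 0.005

    def test_rejects_nonpositive_copy_numbers(self):
        cohort = synthdata.Cohort(
            pd.DataFrame({**{t: [50.0] for t in TRAITS}, "sample_id": ["s1"], "mtdnacn": [0.0]}),
            label="toy",
        )
        with pytest.raises(ValueError, match="mtDNAcn > 0"):
            synthdata.generate_coverage(cohort, SimConfig(n_participants=1))


class TestPlantedEffects:
    def test_clipping_warning_when_mechanism_breaks(self):
        cfg = SimConfig(
            n_participants=300, seed=15, path_b=0.05, baseline_mortality=0.5
        )
        with pytest.warns(UserWarning, match="clipped"):
            synthdata.generate_cohort(cfg)

    def test_planted_beta_recovered_within_ci_across_replicates(self):
        """The assoc stage's 95% CI should cover a planted standardized
        effect in at least ~90% of replicate simulations."""
        planted = -0.11
        hits = 0
        n_rep = 50
        for i in range(n_rep):
            cfg = synthdata.blsa_like_config(
                n_participants=2000,
                seed=100 + i,
                beta_trait_mtdnacn={"neuroticism": planted},
                coverage_cv=0.0,
            )
            data = synthdata.generate_cohort(cfg).data
            res = assoc.adjusted_association(
                data, "neuroticism", covariates=["age", "sex"]
            )
            if res.beta - 1.96 * res.se <= planted <= res.beta + 1.96 * res.se:
                hits += 1
        assert hits >= 0.9 * n_rep
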