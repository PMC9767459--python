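"""Shared locations and cohort configurations for the analysis scripts.

The two cohorts mirror the published study design: an older, deeply
sequenced US cohort (n=722, ~35.8x) and a younger, low-pass island cohort
(n=587, ~3.8x). The planted truth is a -0.11 SD/SD effect of the
Neuroticism domain on mtDNAcn (the published pooled magnitude); because
facets correlate 0.5 with their domain, each Neuroticism facet inherits
roughly half that association marginally, mirroring the published pattern
of facet effects weaker than the domain effect.
"""

from pathlib import Path

from mitopersona import synthdata

RESULTS = Path(__file__).resolve().parent.parent / "results"

#: Published pooled Neuroticism-domain effect used as the planted truth.
PLANTED_TRAIT_EFFECTS = {"neuroticism": -0.11}


def cohort_configs(seed: int = 0) -> list[synthdata.SimConfig]:
    shared = dict(
        beta_trait_mtdnacn=PLANTED_TRAIT_EFFECTS,
        direct_c_prime=-0.04,
        baseline_mortality=0.35,
    )
    return [
        synthdata.blsa_like_config(seed=101 + seed, **shared),
        synthdata.sardinia_like_config(
            seed=202 + seed, **dict(shared, baseline_mortality=0.15)
        ),
    ]
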