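"""NEO-PI-R trait vocabulary shared across the pipeline.

The big-five inventory scores five domains and six facets per domain, all
reported as normative T-scores (mean 50, SD 10). Column names are
snake_case versions of the standard facet names.
"""

DOMAINS: dict[str, list[str]] = {
    "neuroticism": [
        "anxiety",
        "angry_hostility",
        "depression",
        "self_consciousness",
        "impulsiveness",
        "vulnerability",
    ],
    "extraversion": [
        "warmth",
        "gregariousness",
        "assertiveness",
        "activity",
        "excitement_seeking",
        "positive_emotions",
    ],
    "openness": [
        "fantasy",
        "aesthetics",
        "feelings",
        "actions",
        "ideas",
        "values",
    ],
    "agreeableness": [
        "trust",
        "straightforwardness",
        "altruism",
        "compliance",
        "modesty",
        "tender_mindedness",
    ],
    "conscientiousness": [
        "competence",
        "order",
        "dutifulness",
        "achievement_striving",
        "self_discipline",
        "deliberation",
    ],
}

#: All 35 traits (5 domains + 30 facets); the FDR family for meta-analysis.
TRAITS: list[str] = [t for d, facets in DOMAINS.items() for t in [d, *facets]]

#: The four facets entering the personality-mortality index, with the
#: direction that earns a point (low vulnerability is protective; high
#: activity, self-discipline, and competence are protective).
PMI_FACETS: dict[str, str] = {
    "vulnerability": "low",
    "activity": "high",
    "self_discipline": "high",
    "competence": "high",
}

#: Covariates adjusted for in every mtDNAcn association model. Percent
#: monocytes is deliberately absent (only marginally related to mtDNAcn);
#: leaving one leukocyte class out also keeps the percentage columns,
#: which sum to 100, from being collinear.
DEFAULT_COVARIATES: list[str] = [
    "age",
    "sex",
    "autosomal_coverage",
    "platelet_count",
    "wbc_count",
    "pct_neutrophils",
    "pct_lymphocytes",
    "pct_basophils",
    "pct_eosinophils",
]

#: Covariates screened one at a time before the multivariable models.
SCREEN_COVARIATES: list[str] = [
    "age",
    "sex",
    "autosomal_coverage",
    "platelet_count",
    "wbc_count",
    "pct_neutrophils",
    "pct_lymphocytes",
    "pct_monocytes",
    "pct_eosinophils",
    "pct_basophils",
]


def domain_of(trait: str) -> str:
    """Return the domain a trait belongs to (a domain belongs to itself)."""
    for domain, facets in DOMAINS.items():
        if trait == domain or trait in facets:
            return domain
    raise KeyError(f"unknown trait: {trait!r}")
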