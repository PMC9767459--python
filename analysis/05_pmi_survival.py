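"""Personality-mortality index, Cox regression, and Kaplan-Meier curves.

Relates the 0-4 PMI to survival in each cohort: a Cox proportional-
hazards fit of mortality on PMI adjusting for age and sex (cox_<label>.tsv)
and per-index Kaplan-Meier step functions (km_<label>.tsv), plus the
cross-classified vulnerability/self-discipline group sizes.
"""

import pandas as pd
from _common import RESULTS, cohort_configs

from mitopersona import io, survival


def main() -> None:
    for cfg in cohort_configs():
        label = cfg.label
        table = io.read_tsv(RESULTS / f"analysis_{label}.tsv")

        fit = survival.fit_cox(table, covariates=["pmi", "age", "sex"])
        cox_tbl = pd.DataFrame(
            {
                "covariate": list(fit.coefficients),
                "coef": list(fit.coefficients.values()),
                "hr": list(fit.hazard_ratios().values()),
                "se": list(fit.se.values()),
                "p": list(fit.p.values()),
            }
        )
        io.write_tsv(cox_tbl, RESULTS / f"cox_{label}.tsv")

        km = survival.kaplan_meier(table, group_col="pmi")
        km_tbl = pd.concat([g.assign(group=k) for k, g in km.items()], ignore_index=True)
        io.write_tsv(km_tbl, RESULTS / f"km_{label}.tsv")

        print(f"\n{label}: {fit.n_events} deaths among {fit.n}")
        print(cox_tbl.to_string(index=False, float_format=lambda v: f"{v:.4g}"))
        print("2x2 vulnerability/self-discipline groups:",
              table["vuln_discipline_group"].value_counts().to_dict())


if __name__ == "__main__":
    main()
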