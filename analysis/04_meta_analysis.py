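"""Pool the per-cohort associations and control the FDR over 35 traits.

DerSimonian-Laird random-effects pooling of the two cohorts' standardized
effects, Benjamini-Hochberg adjustment over the 35-trait family at the
0.01 threshold, and a forest-plot-ready table of per-cohort and pooled
intervals (meta.tsv, forest.tsv).
"""

import pandas as pd
from _common import RESULTS, cohort_configs

from mitopersona import io
from mitopersona.meta import pool_table
from mitopersona.traits import TRAITS

FDR_THRESHOLD = 0.01


def main() -> None:
    tables = [
        io.read_tsv(RESULTS / f"assoc_{cfg.label}.tsv") for cfg in cohort_configs()
    ]
    pooled = pool_table(tables, fdr_family=TRAITS)
    pooled["significant_fdr"] = pooled["p_fdr"] <= FDR_THRESHOLD
    io.write_tsv(pooled, RESULTS / "meta.tsv")

    forest = pd.concat(tables, ignore_index=True)
    forest["ci_low"] = forest["beta"] - 1.959963984540054 * forest["se"]
    forest["ci_high"] = forest["beta"] + 1.959963984540054 * forest["se"]
    io.write_tsv(forest, RESULTS / "forest.tsv")

    hits = pooled[pooled["significant_fdr"] == True]  # noqa: E712
    print(f"{int(pooled['p_fdr'].notna().sum())} traits in the FDR family; "
          f"{len(hits)} significant at FDR {FDR_THRESHOLD}")
    cols = ["trait", "pooled_beta", "pooled_se", "p", "p_fdr", "I2", "p_Q"]
    print(hits[cols].to_string(index=False, float_format=lambda v: f"{v:.4g}"))


if __name__ == "__main__":
    main()
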