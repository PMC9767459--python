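"""Adjusted standardized associations of each trait with mtDNAcn.

For each cohort, regresses z-scored mtDNAcn on each z-scored trait (all
35 personality traits, CES-D continuous, the two CES-D clinical cutoffs,
and the personality-mortality index) with the full adjustment set, and
writes assoc_<label>.tsv.
"""

import dataclasses

import pandas as pd
from _common import RESULTS, cohort_configs

from mitopersona import assoc, io
from mitopersona.traits import TRAITS


def main() -> None:
    for cfg in cohort_configs():
        label = cfg.label
        table = io.read_tsv(RESULTS / f"analysis_{label}.tsv")
        rows = [
            dataclasses.asdict(
                assoc.adjusted_association(table, trait, cohort=label)
            )
            for trait in [*TRAITS, "cesd", "cesd_ge16", "cesd_ge20", "pmi"]
        ]
        out = pd.DataFrame(rows)
        io.write_tsv(out, RESULTS / f"assoc_{label}.tsv")
        top = out.reindex(out["p"].sort_values().index).head(5)
        print(f"\n{label}: strongest associations")
        print(top.to_string(index=False, float_format=lambda v: f"{v:.4g}"))


if __name__ == "__main__":
    main()
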