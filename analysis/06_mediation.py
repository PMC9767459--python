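"""Does mtDNAcn mediate the PMI-mortality association?

Runs the three-model mediation decomposition with 5000 bootstrap
resamples on a cohort carrying a planted mediation structure at the
published path magnitudes (a ~ 4.9 copies per PMI point, b = -0.02
probability per copy, direct effect -0.05), and writes mediation.tsv.
"""

import dataclasses

import pandas as pd
from _common import RESULTS

from mitopersona import io, synthdata
from mitopersona.cli import _prepare_analysis_table
from mitopersona.mediation import bootstrap_indirect


def main() -> None:
    cfg = synthdata.mediation_scenario(n=20_000, seed=303, path_a=4.89)
    study, _ = synthdata.simulate_study(cfg)
    table = _prepare_analysis_table(study)
    res = bootstrap_indirect(table, n_boot=5000, seed=404)

    row = dataclasses.asdict(res)
    ci = row.pop("boot_ci95")
    row.pop("boot_path_se")
    row["boot_ci_low"], row["boot_ci_high"] = ci
    io.write_tsv(pd.DataFrame([row]), RESULTS / "mediation.tsv")

    print(f"total effect c       = {res.total_c:+.3f} per PMI point")
    print(f"direct effect c'     = {res.direct_c_prime:+.3f}")
    print(f"path a (PMI->mtDNAcn)= {res.path_a:+.2f} copies/point")
    print(f"path b (mtDNAcn->death) = {res.path_b:+.4f} per copy")
    print(f"indirect a*b         = {res.indirect_ab:+.3f} "
          f"[{res.boot_ci95[0]:+.3f}, {res.boot_ci95[1]:+.3f}] "
          f"(bootstrap p = {res.boot_p:.4g}, {res.n_boot} resamples)")


if __name__ == "__main__":
    main()
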