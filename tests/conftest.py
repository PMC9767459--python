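import numpy as np
import pandas as pd
import pytest

from mitopersona import synthdata
from mitopersona.cli import _prepare_analysis_table


def analysis_table(config: synthdata.SimConfig) -> pd.DataFrame:
    """Full analysis-ready table: coverage-estimated mtDNAcn, CES-D
    cutoffs, PMI columns, and the vulnerability/self-discipline class."""
    study, _ = synthdata.simulate_study(config)
    return _prepare_analysis_table(study)


@pytest.fixture(scope="session")
def older_cohort_table() -> pd.DataFrame:
    """A moderately sized cohort shaped like the older, deeply sequenced
    study, with realistic age/sex effects on mtDNAcn."""
    cfg = synthdata.blsa_like_config(n_participants=1500, seed=42)
    return analysis_table(cfg)


@pytest.fixture(scope="session")
def mediation_table() -> pd.DataFrame:
    """Cohort with a planted PMI -> mtDNAcn -> death mediation structure
    (a=5 copies/point, b=-0.02 probability/copy, c'=-0.05)."""
    cfg = synthdata.mediation_scenario(n=6000, seed=17)
    return analysis_table(cfg)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
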