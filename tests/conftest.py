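import pandas as pd
import pytest

from her2low.synthetic_data import SimulationConfig, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A study-structured cohort small enough for fast unit tests."""
    return generate_cohort(SimulationConfig(n_samples=300, seed=11))


@pytest.fixture(scope="session")
def clean_cohort():
    """Cohort with no missingness, for recovery tests needing full eligibility."""
    return generate_cohort(
        SimulationConfig(
            n_samples=400,
            seed=5,
            purity_missing_rate=0.0,
            segment_missing_rate=0.0,
            ihc_nos_rate=0.0,
            er_missing_rate=0.0,
        )
    )


@pytest.fixture()
def toy_annotations():
    return pd.DataFrame(
        {
            "gene": ["TP53", "PIK3CA", "CCND1", "NEWGENE", "MIXED"],
            "role": ["TSG", "oncogene", "oncogene", "other", "TSG"],
            "panel_versions": ["v1,v2,v3", "v1,v2,v3", "v1,v2,v3", "v3", "v2,v3"],
        }
    )
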