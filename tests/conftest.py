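import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import ponvkit as pk
from ponvkit.genotype_qc import GenotypeMatrix, VariantDef

settings.register_profile(
    "ci", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_cohort():
    """One medium default-profile cohort shared across read-only tests."""
    return pk.generate_default_cohort(601, seed=20260920)


@pytest.fixture(scope="session")
def big_cohort():
    """Large cohort for calibration checks (generated once)."""
    return pk.generate_default_cohort(100_000, seed=11)


@pytest.fixture()
def tiny_gm():
    """Three samples, two variants, one missing call."""
    variants = [
        VariantDef("rs1", "1", "A", "G"),
        VariantDef("rs2", "2", "C", "T"),
    ]
    calls = pd.DataFrame(
        {
            "rs1": ["A/A", "A/G", np.nan],
            "rs2": ["C/T", "C/C", "T/T"],
        },
        index=pd.Index(["s1", "s2", "s3"], name="sample_id"),
        dtype=object,
    )
    return GenotypeMatrix(calls, variants)
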