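import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import septimark as sm

settings.register_profile(
    "septimark",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("septimark")


@pytest.fixture
def small_cohort():
    """A compact deterministic cohort touching every table."""
    cfg = sm.CohortConfig(
        n_control=6, n_ns=8, n_s=6, days=(0, 1, 3), n_genes=30, n_mirna=40,
        n_protein=50, noise_sigma=0.4, missing_rate_base=0.05,
        planted_susceptibility=(("GENE0001", 0.8, 0.1),),
        planted_mirna=(("syn-miR-0001", 2.0, "SvsNS"),),
        planted_trend=(("PROT0001", 7, 0, 1.2),),
        planted_marker=(("PROT0002", 2.0),),
        seed=123,
    )
    return sm.generate_cohort(cfg)


@pytest.fixture
def toy_matrix():
    """Complete 12-feature x 6-sample imputed matrix with two 3-sample groups."""
    rng = np.random.default_rng(7)
    values = pd.DataFrame(
        rng.normal(15.0, 1.0, size=(12, 6)),
        index=[f"f{i}" for i in range(12)],
        columns=[f"a{i}" for i in range(3)] + [f"b{i}" for i in range(3)],
    )
    return sm.AbundanceMatrix(values, state="imputed")
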