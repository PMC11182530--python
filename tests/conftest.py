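import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from microscape import SyntheticCohortSpec, TaxonProfileTable, simulate_cohort

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def small_cohort():
    """Tiny three-class cohort: 4 participants/class x 6 visits, 12 genera."""
    spec = SyntheticCohortSpec(
        participants_per_class={"CD": 4, "UC": 4, "nonIBD": 4},
        visits_per_participant=6,
        n_short_participants=3,
        n_genera=12,
        n_assemblages=3,
        depth=500,
        seed=11,
    )
    return simulate_cohort(spec)


@pytest.fixture(scope="session")
def study_cohort():
    """Cohort sized like the study: 65/38/27 participants, 10 visits, 20 short."""
    spec = SyntheticCohortSpec(seed=7)
    return simulate_cohort(spec)


@pytest.fixture()
def toy_table():
    df = pd.DataFrame(
        [[3, 1], [0, 4], [2, 2]],
        index=pd.Index(["s1", "s2", "s3"], name="sample_id"),
        columns=["Bacteroides", "Prevotella"],
    )
    return TaxonProfileTable(df, is_counts=True)


@pytest.fixture()
def disjoint_phi():
    """Planted 2-assemblage composition with disjoint genus supports."""
    phi = np.zeros((2, 4))
    phi[0, :2] = [0.6, 0.4]  # genera A, B
    phi[1, 2:] = [0.7, 0.3]  # genera C, D
    return phi
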