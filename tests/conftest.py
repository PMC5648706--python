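import numpy as np
import pandas as pd
import pytest

from pji_profiler import CohortSpec, CohortTable, NetworkConfig, generate_cohort
from pji_profiler.expression import NON_PJI, PJI

TRIO = ("DEFA1", "IL1B", "LTF")

#: Scaled-down training protocol used for the heavier experiments in this
#: suite: full-batch gradient descent converges well before the library
#: default of 10k epochs on these small calibrated cohorts.
FAST = NetworkConfig(max_epochs=2000)


@pytest.fixture(scope="session")
def xxpress_trio_cohort() -> CohortTable:
    """23/25 synthetic cohort drawn from the Xxpress DEFA1/IL1B/LTF calibrations."""
    return generate_cohort(CohortSpec.from_named("table1_xxpress", genes=TRIO, seed=11))


@pytest.fixture(scope="session")
def rotorgene_trio_cohort() -> CohortTable:
    """38/38 synthetic cohort drawn from the RotorGene trio calibrations."""
    return generate_cohort(CohortSpec.from_named("table1_rotorgene", genes=TRIO, seed=12))


@pytest.fixture(scope="session")
def separable_cohort() -> CohortTable:
    """Cohort with one perfectly separating gene and one noise gene."""
    rng = np.random.default_rng(5)
    n = 40
    defa1 = np.concatenate([rng.uniform(10, 20, n // 2), rng.uniform(0.01, 0.1, n // 2)])
    tlr4 = rng.uniform(1, 5, n)
    labels = [PJI] * (n // 2) + [NON_PJI] * (n // 2)
    idx = [f"P{i:03d}" for i in range(n)]
    values = pd.DataFrame({"DEFA1": defa1, "TLR4": tlr4}, index=idx)
    return CohortTable(values, pd.Series(labels, index=idx))


@pytest.fixture(scope="session")
def noise_cohort() -> CohortTable:
    """Labels carry no signal: expression independent of class."""
    rng = np.random.default_rng(6)
    n = 60
    values = pd.DataFrame(
        {
            "DEFA1": rng.lognormal(0, 1, n),
            "IL1B": rng.lognormal(0, 1, n),
        },
        index=[f"P{i:03d}" for i in range(n)],
    )
    labels = pd.Series([PJI, NON_PJI] * (n // 2), index=values.index)
    return CohortTable(values, labels)
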