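import numpy as np
import pytest

from connaudit import (
    ConnectivitySet,
    EdgeIndex,
    SyntheticSpec,
    generate_cohort,
)


@pytest.fixture(scope="session")
def confound_cohort():
    """Reference confound-scenario cohort: score depends on group only."""
    return generate_cohort(SyntheticSpec(n=600, scenario="confound", seed=0))


@pytest.fixture(scope="session")
def direct_cohort():
    """Direct-scenario cohort: score genuinely depends on the direct edges."""
    return generate_cohort(SyntheticSpec(n=600, scenario="direct", seed=0))


@pytest.fixture(scope="session")
def null_cohort():
    """Null-scenario cohort: no edge effect, equal score means."""
    return generate_cohort(SyntheticSpec(n=300, scenario="null", seed=0))


@pytest.fixture()
def small_connectivity():
    """Deterministic 8-subject, p=5 connectivity set."""
    rng = np.random.default_rng(42)
    values = np.clip(rng.normal(0.2, 0.3, size=(8, 10)), -0.99, 0.99)
    return ConnectivitySet("rest", values, EdgeIndex(5))
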