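import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from protonsel.dose import DoseModelGrid
from protonsel.synthetic import (
    CohortSpec,
    default_phantom_spec,
    generate_cohort,
    generate_phantom,
)
from protonsel.tool import DecisionTool

settings.register_profile(
    "default",
    settings(
        deadline=None,
        derandomize=True,
        suppress_health_check=[HealthCheck.too_slow],
    ),
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def phantom():
    """Deterministic ellipsoidal head-and-neck phantom."""
    return generate_phantom(default_phantom_spec())


@pytest.fixture(scope="session")
def cohort_spec():
    return CohortSpec(n_patients=151, seed=11)


@pytest.fixture(scope="session")
def noisy_cohort(cohort_spec):
    return generate_cohort(cohort_spec)


@pytest.fixture(scope="session")
def noiseless_cohort(cohort_spec):
    return generate_cohort(cohort_spec.noiseless())


@pytest.fixture(scope="session")
def grid_results(noisy_cohort):
    return DoseModelGrid(noisy_cohort.features, noisy_cohort.dmeans).fit()


@pytest.fixture(scope="session")
def fitted_tool(grid_results, cohort_spec):
    return DecisionTool(
        grid_results.selected(),
        dict(cohort_spec.ntcp_models),
        cohort_spec.thresholds,
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
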