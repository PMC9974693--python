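import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def reference_aroma_table():
    """Aroma values for the published min/max mash concentrations."""
    from aromacal import compounds as C

    return C.compute_aroma_values(
        C.reference_concentration_ranges(), C.reference_compounds()
    )


@pytest.fixture(scope="session")
def solution_scores():
    """Attribute scores of the four model solutions under the published
    assignment."""
    from aromacal import compounds as C, grouping as G

    table = C.compute_aroma_values(
        C.model_solution_concentrations(), C.reference_compounds()
    )
    return G.attribute_scores(table, G.default_assignments())


@pytest.fixture(scope="session")
def small_dataset():
    """A 60-sample synthetic dataset at the default study conditions."""
    from aromacal.synthetic_data import GeneratorConfig, simulate_dataset

    return simulate_dataset(GeneratorConfig(n_samples=60, seed=7))
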