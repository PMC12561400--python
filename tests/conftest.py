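import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from bmage.metabolomics import MetaboliteMatrix
from bmage.synthdata import CohortDesign, generate_cohort

settings.register_profile(
    "ci",
    max_examples=50,
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_design() -> CohortDesign:
    """Compact cohort reused across module tests (2 organs, 20 features)."""
    return CohortDesign(
        organs=("plasma", "wat"),
        n_features_per_organ=20,
        n_per_group=8,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_study(small_design):
    return generate_cohort(small_design)


def matrix_from_array(arr, groups, organ="plasma", prefix="f"):
    """Build a MetaboliteMatrix from a plain samples x features array."""
    arr = np.asarray(arr, dtype=float)
    samples = [f"s{i:02d}" for i in range(arr.shape[0])]
    features = [f"{prefix}{j:03d}" for j in range(arr.shape[1])]
    return MetaboliteMatrix(
        intensities=pd.DataFrame(arr, index=samples, columns=features),
        groups=pd.Series(list(groups), index=samples),
        organ=organ,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
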