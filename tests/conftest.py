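import numpy as np
import pytest

import icpbin as icp


@pytest.fixture(scope="session")
def strong_spec():
    return icp.load_preset("strong")


@pytest.fixture(scope="session")
def identifiable_spec():
    """Two parents shifted directly (their own mechanisms, never the
    outcome's), plus one shifted noise predictor: every invariant subset must
    contain both parents, so the intersection identifies S* exactly."""
    adjacency = np.zeros((4, 4))
    adjacency[0, 3] = 1.5
    adjacency[1, 3] = -1.2
    return icp.SCMSpec(
        names=["X1", "X2", "X3"],
        adjacency=adjacency,
        interventions={
            1: [("X1", "shift", 1.0), ("X2", "shift", -1.0), ("X3", "shift", 1.0)]
        },
    )


@pytest.fixture(scope="session")
def null_calibration_spec():
    """Parents untouched and the single intervened predictor independent of
    the outcome: the invariance test on S* is exactly calibrated here."""
    adjacency = np.zeros((4, 4))
    adjacency[0, 3] = 1.0
    adjacency[1, 3] = -0.8
    return icp.SCMSpec(
        names=["X1", "X2", "X3"],
        adjacency=adjacency,
        interventions={1: [("X3", "shift", 1.0)]},
    )


@pytest.fixture(scope="session")
def collider_spec():
    """One parent X1 with an intervened child X2 (collider opener)."""
    adjacency = np.zeros((3, 3))
    adjacency[0, 2] = 1.2
    adjacency[0, 1] = 0.8
    return icp.SCMSpec(
        names=["X1", "X2"],
        adjacency=adjacency,
        interventions={1: [("X2", "shift", 1.0)]},
    )


@pytest.fixture(scope="session")
def scm_dataset(strong_spec):
    return icp.simulate_scm(strong_spec, n_per_env=1500, seed=11)


@pytest.fixture(scope="session")
def default_study_schema():
    return icp.default_schema()


@pytest.fixture(scope="session")
def big_cohort(default_study_schema):
    """One large emulated cohort shared by the fidelity checks."""
    return icp.generate_study_like(default_study_schema, n=100_000, seed=20)


@pytest.fixture(scope="session")
def small_cohort(default_study_schema):
    return icp.generate_study_like(default_study_schema, n=2744, seed=5)
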