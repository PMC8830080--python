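import dataclasses

import pytest

from staplercma import (default_profile, generate_cohort, generate_costs,
                        load_reference_coefficients, reference_scenarios,
                        GroundTruth)


@pytest.fixture(scope="session")
def equations():
    """The shipped reference coefficient table."""
    return load_reference_coefficients()


@pytest.fixture(scope="session")
def profile():
    return default_profile()


@pytest.fixture(scope="session")
def small_profile(profile):
    """Scaled-down two-group profile for fast generator tests."""
    groups = {name: dataclasses.replace(g, n=30 if name == "powered" else 10)
              for name, g in profile.groups.items()}
    return dataclasses.replace(profile, groups=groups)


@pytest.fixture(scope="session")
def cohort(profile, equations):
    """Full-size (296/92) synthetic cohort with gamma cost noise."""
    truth = GroundTruth(equations=equations, profile=profile, seed=11)
    patients = generate_cohort(profile, 11)
    costs = generate_costs(patients, truth)
    return patients, costs, truth


@pytest.fixture(scope="session")
def scenarios():
    """(powered, ECHELON manual, Victor) aggregate-calibrated scenario specs."""
    return reference_scenarios()
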