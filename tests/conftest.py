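import numpy as np
import pytest

import planpilot as pp


@pytest.fixture(scope="session")
def study_spec():
    """The canonical 64x64 study phantom: one PTV, two OARs, 16 beams."""
    return pp.standard_phantom_spec()


@pytest.fixture(scope="session")
def study_case(study_spec):
    sset, influence, rx = pp.generate_phantom(study_spec)
    return pp.PlanningCase("query", "phantom", sset, influence, rx, spec=study_spec)


@pytest.fixture(scope="session")
def study_params(study_case):
    return pp.default_plan_parameters(study_case.structures, study_case.prescription)


@pytest.fixture(scope="session")
def self_reference(study_spec):
    """A reference whose geometry and plan are identical to the study case's."""
    return pp.generate_reference_library(study_spec, 1, 0.0, seed=5)[0]


@pytest.fixture(scope="session")
def autopilot_sweep(study_spec, study_case):
    """Ten autopilot runs against achievable references jittered by <= 2 mm."""
    results = []
    for seed in range(1, 11):
        reference = pp.generate_reference_library(study_spec, 1, 2.0, seed=seed)[0]
        result = pp.run_autopilot(study_case, reference)
        results.append((reference, result))
    return results


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
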