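import numpy as np
import pytest

from ioqsp import ModelParameters, PopulationSpec, build_population
from ioqsp.population import VirtualPatient


@pytest.fixture(scope="session")
def default_params() -> ModelParameters:
    return ModelParameters()


@pytest.fixture(scope="session")
def default_spec() -> PopulationSpec:
    return PopulationSpec()


@pytest.fixture(scope="session")
def small_cohort(default_spec):
    """30 LHS patients for smoke-level cohort checks."""
    patients, _ = build_population(30, default_spec, seed=123)
    return patients


def make_patient(pid: int = 0, **overrides) -> VirtualPatient:
    return VirtualPatient(id=pid, params=ModelParameters().replace(**overrides))


class FakeTrajectory:
    """Minimal stand-in carrying the assessment fields used by RECIST."""

    def __init__(self, assess_t, assess_diameter, patient_id=0):
        self.assess_t = np.asarray(assess_t, dtype=float)
        self.assess_diameter = np.asarray(assess_diameter, dtype=float)
        self.patient_id = patient_id
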