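import numpy as np
import pytest

from iliacshear.cohort import control_template, make_virtual_patient
from iliacshear.hemodynamics import SolverOptions, simulate_patient
from iliacshear.rheology import BLOOD, RheologyParams


@pytest.fixture(scope="session")
def blood():
    return BLOOD


@pytest.fixture(scope="session")
def newtonian():
    return RheologyParams.newtonian(0.0035)


@pytest.fixture(scope="session")
def symmetric_template():
    """Mirror-symmetric control: equal leg flows, equal CIV areas, no noise."""
    return control_template(
        right_leg_flow=(0.9, 0.9),
        left_leg_flow=(0.9, 0.9),
        baseline_areas={
            "IVC": 250.0, "RCIV": 130.0, "LCIV": 130.0,
            "REIV": 110.0, "LEIV": 110.0, "RIIV": 60.0, "LIIV": 60.0,
        },
        period_range=(3.2, 3.2),
        noise_cv=0.0,
    )


@pytest.fixture(scope="session")
def steady_newtonian_solution(symmetric_template, newtonian):
    """Steady (zero-phasicity) Newtonian run on the symmetric patient —
    every station is a textbook Poiseuille tube."""
    tmpl = symmetric_template
    patient = make_virtual_patient(
        type(tmpl)(**{**tmpl.__dict__, "phasicity": 0.0}), seed=5
    )
    options = SolverOptions(rheology=newtonian)
    return patient, simulate_patient(patient, options), options


@pytest.fixture(scope="session")
def phasic_newtonian_solution(symmetric_template, newtonian):
    patient = make_virtual_patient(symmetric_template, seed=5)
    options = SolverOptions(rheology=newtonian)
    return patient, simulate_patient(patient, options), options


def poiseuille_wall_shear(q: float, radius: float) -> float:
    """Closed-form Newtonian wall shear rate 4Q/(πR³)."""
    return 4.0 * q / (np.pi * radius**3)
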