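import numpy as np
import pytest

import brainpk as bp
from brainpk.parameters import DoseRegimen


@pytest.fixture(scope="session")
def male_drug():
    return bp.load_drug(bp.data_path("letrozole_male.yaml"))


@pytest.fixture(scope="session")
def female_drug():
    return bp.load_drug(bp.data_path("letrozole_female.yaml"))


@pytest.fixture(scope="session")
def rat():
    return bp.load_physiology(bp.data_path("rat_250g.yaml"))


@pytest.fixture(scope="session")
def male_kp(male_drug):
    return bp.predict_kp(male_drug)


@pytest.fixture(scope="session")
def male_single_dose(male_drug, rat, male_kp):
    """Simulated male single-dose study: 4 mg/kg, 0-72 h."""
    regimen = DoseRegimen(dose_mg_per_kg=4.0, n_doses=1, simulation_end_h=72.0)
    model = bp.PBPKModel(male_drug, rat, regimen, male_kp)
    return model.simulate()


@pytest.fixture(scope="session")
def female_single_dose(female_drug, rat):
    regimen = DoseRegimen(dose_mg_per_kg=4.0, n_doses=1, simulation_end_h=72.0)
    model = bp.PBPKModel(female_drug, rat, regimen)
    return model.simulate()


@pytest.fixture()
def mono_profile():
    """Noise-free mono-exponential profile C(t) = 1000 e^(-0.1 t)."""
    t = np.linspace(0.0, 24.0, 49)
    return bp.ConcentrationTimeProfile("plasma_total", t, 1000.0 * np.exp(-0.1 * t))
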