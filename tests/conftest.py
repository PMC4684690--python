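import numpy as np
import pytest

import previnc as pv

#: "True incidence" reference values of the dementia example at ages
#: 62.5, 65, ..., 97.5 (exp(-12.8 + 0.11 a), printed to 7 decimals).
DEMENTIA_TRUE_INCIDENCE = np.array([
    0.0026718, 0.0035175, 0.0046309, 0.0060967, 0.0080266,
    0.0105672, 0.0139120, 0.0183156, 0.0241131, 0.0317456,
    0.0417941, 0.0550232, 0.0724398, 0.0953692, 0.1255564,
])


@pytest.fixture(scope="session")
def dementia():
    return pv.dementia_rates()


@pytest.fixture(scope="session")
def default_spec():
    return pv.ExperimentSpec()


@pytest.fixture(scope="session")
def dementia_cross_sections(default_spec):
    return pv.generate_cross_sections(default_spec)


@pytest.fixture(scope="session")
def recovery_table():
    return pv.run_recovery_study()
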