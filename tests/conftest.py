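import numpy as np
import pytest

from romap.model import Label, MenopausalStatus, PatientRecord


@pytest.fixture
def rng():
    return np.random.default_rng(20160111)


@pytest.fixture
def toy_patients():
    """Six hand-built patients spanning strata and both classes."""
    return [
        PatientRecord("p1", 18, MenopausalStatus.PRE, 40.0, 15.0, Label.BENIGN),
        PatientRecord("p2", 34, MenopausalStatus.PRE, 47.0, 30.0, Label.BENIGN),
        PatientRecord("p3", 45, MenopausalStatus.PRE, 90.0, 260.0, Label.MALIGNANT),
        PatientRecord("p4", 55, MenopausalStatus.POST, 440.0, 500.0, Label.MALIGNANT),
        PatientRecord("p5", 68, MenopausalStatus.POST, 60.0, 16.0, Label.BENIGN),
        PatientRecord("p6", 84, MenopausalStatus.POST, 870.0, 780.0, Label.MALIGNANT),
    ]
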