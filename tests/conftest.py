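import numpy as np
import pytest

import pacinian as pc


@pytest.fixture(scope="session")
def printed3_curve():
    """3-layer printable design on the 20 Hz - 3 kHz measurement band."""
    model = pc.TransferModel.from_design(pc.printed(3))
    return pc.frequency_response(model, pc.default_grid(20, 3000, 400))


@pytest.fixture(scope="session")
def printed5_curve():
    """5-layer printable design evaluated up to 10 kHz."""
    model = pc.TransferModel.from_design(pc.printed(5))
    return pc.frequency_response(model, pc.default_grid(1, 10000, 400))


@pytest.fixture(scope="session")
def biological_curve():
    """Typical biological corpuscle on a wide band."""
    model = pc.TransferModel.from_design(pc.biological())
    return pc.frequency_response(model, pc.default_grid(1, 3e5, 400))


@pytest.fixture
def one_pole_curve():
    """Analytic one-pole high-pass with a 400 Hz corner."""
    f = pc.default_grid(10, 10000, 400)
    h = (f / 400.0) / np.sqrt(1.0 + (f / 400.0) ** 2)
    return pc.ResponseCurve(frequencies=f, transmittance=h.astype(complex))
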