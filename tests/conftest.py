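import math

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import muscledti as m

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def phantom15():
    """Noiseless 15-degree slab phantom: ground truth field, ROI, record."""
    spec = m.PhantomSpec(pennation_true=15.0, thickness_true=13.0)
    tfield, roi, truth = m.make_phantom(spec)
    return spec, tfield, roi, truth


@pytest.fixture(scope="session")
def fitted15(phantom15):
    """Tensor field fitted from noiseless simulated DWI of the phantom."""
    spec, tfield, roi, truth = phantom15
    dwi = m.simulate_dwi(tfield, roi, m.default_scheme())
    fit = m.fit_tensor(dwi, np.ones(roi.mask.shape, dtype=bool))
    return fit, roi, truth


@pytest.fixture(scope="session")
def raw_tracts15(fitted15):
    """Deterministic raw tract set over the noiseless phantom."""
    fit, roi, truth = fitted15
    return m.track_muscle(fit, roi, m.TrackingParams())
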