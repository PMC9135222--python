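from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import pkreplay as pr

settings.register_profile(
    "ci", derandomize=True, max_examples=50, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture
def params():
    """Synthetic oral-kinase-inhibitor-like parameters (Tmax ~ 1.9 h)."""
    return pr.PKParameters(ka=1.2, ke=0.18, scale=0.0604)


@pytest.fixture
def device():
    return pr.DeviceConfig(working_volume=1000.0, residual_volume=50.0,
                           flow_rate=500.0)


@pytest.fixture
def qd_curve(params):
    """Continuous single-dose curve for 50 dose units, as a callable."""
    return lambda t: np.asarray(pr.concentration_single_dose(params, 50.0, t))


@pytest.fixture
def thirteen_step_profile(params, qd_curve):
    """The canonical 13-step once-daily profile (1-h steps over the first
    2 h, 2-h steps after)."""
    tiling = pr.tile_cycle(24.0, 1.0, 2.0, 2.0)
    return pr.discretize(qd_curve, tiling, drug="erki")
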