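import logging

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from dermasim import franz, presets

logging.getLogger("dermasim").setLevel(logging.ERROR)

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def ivpt_results():
    """Full-preset IVPT runs (36 h, reference sampling grid) per vehicle."""
    out = {}
    for veh in ("cream", "ointment"):
        exp = presets.build_experiment(presets.default_config("ivpt", veh))
        out[veh] = franz.run_ivpt(exp)
    return out


@pytest.fixture(scope="session")
def ivrt_results():
    """Full-preset IVRT runs (24 h) per vehicle."""
    out = {}
    for veh in ("cream", "ointment"):
        exp = presets.build_experiment(presets.default_config("ivrt", veh))
        out[veh] = franz.run_ivrt(exp)
    return out


@pytest.fixture()
def coarse_ivrt_config():
    """Reduced-resolution ointment IVRT config for optimizer-loop tests."""
    return presets.default_config("ivrt", "ointment", vehicle_cells=20,
                                  membrane_cells=6)


def closure_error(result):
    total = result.total_in_system()
    return float(np.abs(total - result.initial_mass).max() / result.initial_mass)
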