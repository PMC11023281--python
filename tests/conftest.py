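import numpy as np
import pytest

import koalapk as kp


@pytest.fixture
def noise_free_params():
    """Deterministic study-design parameters (no residual noise)."""
    return kp.SimulationParams(cv=0.0, seed=0)


@pytest.fixture
def noise_free_profile(noise_free_params):
    return kp.simulate_profile(noise_free_params)


@pytest.fixture
def exact_exponential_profile():
    """10 * 2^(-(t-8)/4) at 8/12/24 h: exactly log-linear, ke = ln2/4."""
    return kp.ConcentrationTimeProfile(
        subject_id="EXP",
        route="oral",
        dose=15.0,
        times=np.array([8.0, 12.0, 24.0]),
        concentrations=np.array([10.0, 5.0, 0.625]),
    )


def make_profile(times, concs, lloq=1e-6, **kwargs):
    """Profile helper with an LLOQ low enough to keep every point usable."""
    defaults = dict(subject_id="T", route="oral", dose=15.0, lloq=lloq)
    defaults.update(kwargs)
    return kp.ConcentrationTimeProfile(
        times=np.asarray(times, dtype=float),
        concentrations=np.asarray(concs, dtype=float),
        **defaults,
    )


@pytest.fixture
def profile_factory():
    return make_profile
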