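import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import albind as ab

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def binding_scenario():
    return ab.default_scenario()


@pytest.fixture
def structure_scenario():
    return ab.StructureScenario(noise_sigma=0.0)


@pytest.fixture
def noiseless_series(binding_scenario):
    return ab.simulate_titration(binding_scenario, 297.0)


def make_series(Ksv=1e5, F0=1000.0, conc=None, temperature=297.0, marker="none"):
    """Titration lying exactly on the Stern-Volmer line F0/F = 1 + Ksv*[Q]."""
    if conc is None:
        conc = np.linspace(2e-7, 2e-6, 10)
    points = [ab.TitrationPoint(0.0, F0)]
    for q in conc:
        points.append(ab.TitrationPoint(float(q), F0 / (1.0 + Ksv * q)))
    return ab.TitrationSeries(
        temperature=temperature, points=points, marker=marker
    )
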