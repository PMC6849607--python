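import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from thermocompete import MetabolicTraits, celsius_to_kelvin
from thermocompete.synthetic import default_panel

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

T15 = celsius_to_kelvin(15.0)
T25 = celsius_to_kelvin(25.0)


@pytest.fixture(scope="session")
def panel():
    return default_panel()


@pytest.fixture(scope="session")
def traits_dict(panel):
    return {sp.name: sp.traits for sp in panel}


def random_traits(rng: np.random.Generator) -> MetabolicTraits:
    """A random but physically plausible trait set."""
    return MetabolicTraits(
        B0=rng.uniform(0.2, 2.0),
        E_mu=rng.uniform(-0.2, 1.5),
        K0=rng.uniform(0.02, 5.0),
        E_K=rng.uniform(-0.2, 1.5),
        T_ref_K=T15,
    )
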