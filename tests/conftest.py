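import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from irpsim import (
    ThermoConfig,
    build_parameter_set,
    load_fixtures,
)

settings.register_profile(
    "deterministic",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def bundle():
    return load_fixtures()


@pytest.fixture(scope="session")
def thermo():
    return ThermoConfig()


@pytest.fixture(scope="session")
def params_for(bundle, thermo):
    """Factory: derived parameter set for (variant_name, drug_name), cached."""
    cache = {}

    def build(variant_name: str, drug_name: str):
        key = (variant_name, drug_name)
        if key not in cache:
            drug = bundle.drugs[drug_name]
            wt_key = (bundle.wild_type.name, drug_name)
            if wt_key not in cache:
                cache[wt_key] = build_parameter_set(bundle.wild_type, drug, thermo)
            if variant_name == bundle.wild_type.name:
                return cache[wt_key]
            cache[key] = build_parameter_set(
                bundle.variants[variant_name], drug, thermo, wt_reference=cache[wt_key]
            )
        return cache[key]

    return build


def equilibration_time(generator: np.ndarray, decades: float = 12.0) -> float:
    """Time (min) for the slowest transient of a rate generator to decay.

    The slowest nonzero eigenvalue sets the relaxation rate; ``decades``
    e-foldings reduce the transient below any tolerance used in the tests.
    """
    eig = np.linalg.eigvals(generator)
    rates = np.abs(eig.real)
    gap = rates[rates > 1e-9 * rates.max()].min()
    return decades * np.log(10.0) / gap
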