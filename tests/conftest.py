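import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import fruitrelax as fr

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

NOISELESS = fr.NoiseSpec(force_sd=0.0, param_scale=0.0, seed=0)


def _mean_fruit(family: str) -> fr.FruitSample:
    params = fr.TOMATO_MAXWELL_MEAN if family == "maxwell" else fr.TOMATO_CAPUTO_MEAN
    return fr.FruitSample(
        id=f"{family}_mean", radius_mm=35.0, size_class="medium", position="locule",
        poisson_ratio=0.49, true_params=params,
    )


@pytest.fixture(scope="session")
def maxwell_fruit():
    """R = 35 mm fruit carrying the population-mean Maxwell parameters."""
    return _mean_fruit("maxwell")


@pytest.fixture(scope="session")
def caputo_fruit():
    return _mean_fruit("caputo")


def noiseless_curve(sample: fr.FruitSample, protocol=None) -> fr.RelaxationCurve:
    """Generate, trim and Hertz-convert one noiseless trace."""
    protocol = protocol or fr.CompressionProtocol()
    trace = fr.generate_force_trace(sample, protocol, NOISELESS)
    return fr.force_to_stress(fr.trim_relaxation(trace), sample,
                              protocol.target_deformation_mm)


@pytest.fixture(scope="session")
def maxwell_curve(maxwell_fruit):
    return noiseless_curve(maxwell_fruit)


@pytest.fixture(scope="session")
def caputo_curve(caputo_fruit):
    return noiseless_curve(caputo_fruit)
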