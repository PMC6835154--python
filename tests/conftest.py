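import numpy as np
import pytest

from geoapportion.qpcr import StandardCurve
from geoapportion.simulate import DensitySpec, SimConfig, simulate_farm_system


@pytest.fixture
def perfect_curve() -> StandardCurve:
    """Perfect doubling chemistry: slope -3.3219, 100% efficiency."""
    return StandardCurve(slope=-3.3219, intercept=40.0, r2=1.0)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(42)


def zero_noise_config(seed: int = 0, **overrides) -> SimConfig:
    """Simulator config with every stochastic term switched off."""
    means_p = {"water": 500.0, "mucous": 2.0e5, "digesta": 1.5e3, "fin": 8.0e4}
    means_t = {"water": 2.0e5, "mucous": 1.0e8, "digesta": 7.0e5, "fin": 4.0e7}
    defaults = dict(
        producer_density={c: DensitySpec(m, 0.0) for c, m in means_p.items()},
        total16s_density={c: DensitySpec(m, 0.0) for c, m in means_t.items()},
        cq_noise_sd=0.0,
        measurement_noise_rel=0.0,
        seed=seed,
    )
    defaults.update(overrides)
    return SimConfig(**defaults)


@pytest.fixture
def zero_noise_dataset():
    return simulate_farm_system(zero_noise_config())
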