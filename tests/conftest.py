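import numpy as np
import pytest

import pondwatch as pw


@pytest.fixture(scope="session")
def typical_params() -> pw.EcosystemParams:
    """Typical-value parameterisation with base saturation 10 mg/L."""
    return pw.EcosystemParams(Osat_base=10.0)


@pytest.fixture(scope="session")
def typical_state() -> np.ndarray:
    return np.array([1.5, 0.8, 0.3, 9.0])


@pytest.fixture(scope="session")
def forcing() -> pw.TemperatureForcing:
    return pw.TemperatureForcing(T_mean=18.0, amplitude=8.0, period=25.0)


@pytest.fixture(scope="session")
def bloom_trajectory(typical_params, typical_state, forcing) -> pw.Trajectory:
    """Noiseless 50-day reference trajectory (shared; integration is costly)."""
    return pw.integrate(typical_state, typical_params, forcing, t_span=50.0, dt=0.01)


def near_zero_params(**overrides) -> pw.EcosystemParams:
    """Parameter set with all rates negligibly small (dynamics ~frozen).

    Exact zeros are rejected by validation, so tests that need 'switched
    off' biology use 1e-12 rates, far below every tolerance they assert.
    """
    eps = 1e-12
    base = dict(
        rP=eps, K=5.0, gZ=eps, gF=eps, hP=0.5, hZ=0.3, eZ=eps, eF=eps,
        mP=eps, mZ=eps, mF=eps, aP=eps, bR=eps, k2=eps, Osat_base=10.0,
    )
    base.update(overrides)
    return pw.EcosystemParams(**base)


@pytest.fixture(scope="session")
def constant_forcing() -> pw.TemperatureForcing:
    return pw.TemperatureForcing(T_mean=20.0, amplitude=0.0, period=25.0)
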