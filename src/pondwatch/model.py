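"""Deterministic P-Z-F-O pond-ecosystem dynamics.

The model couples phytoplankton (P), zooplankton (Z) and fish (F) biomass
(g/m^3) with dissolved oxygen O (mg/L) through logistic growth,
Michaelis-Menten (saturating) trophic responses and an oxygen balance with
temperature-dependent reaeration:

    dP/dt = rP*P*(1 - P/K) - gZ*P*Z/(hP + P) - mP*P
    dZ/dt = eZ*gZ*P*Z/(hP + P) - gF*Z*F/(hZ + Z) - mZ*Z
    dF/dt = eF*gF*Z*F/(hZ + Z) - mF*F
    dO/dt = aP*P - bR*(P + Z + F) + k2*(Osat(T) - O)

with Osat(T) = Osat_base * (1 - 0.02*(T - 20)) the oxygen saturation level
at water temperature T (degC).  All rates are per day; time is measured in
days throughout the package.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields
from typing import NamedTuple

import numpy as np

from .errors import ConfigError, IntegrationDivergedError, OutOfRangeError

STATE_NAMES = ("P", "Z", "F", "O")

#: (low, high) bounds of the normal range for each ecosystem parameter.
PARAM_RANGES = {
    "rP": (0.5, 2.0),
    "K": (3.0, 8.0),
    "hP": (0.1, 1.0),
    "mP": (0.05, 0.2),
    "gZ": (0.3, 1.0),
    "eZ": (0.3, 0.6),
    "hZ": (0.1, 0.5),
    "mZ": (0.05, 0.15),
    "gF": (0.1, 0.5),
    "eF": (0.2, 0.4),
    "mF": (0.02, 0.1),
    "aP": (0.1, 0.5),
    "bR": (0.05, 0.2),
    "k2": (0.1, 0.3),
    "Osat_base": (8.0, 10.0),
}


@dataclass(frozen=True)
class EcosystemParams:
    """Rate and saturation constants of the P-Z-F-O model.

    Defaults are the typical literature values for a temperate fish pond.
    Units: rates 1/day, biomass constants g/m^3, oxygen terms mg/(L*day),
    Osat_base mg/L at 20 degC; eZ and eF are dimensionless efficiencies.
    """

    rP: float = 0.8       # phytoplankton growth rate
    K: float = 5.0        # carrying capacity
    gZ: float = 0.6       # zooplankton grazing rate
    gF: float = 0.3       # fish predation rate
    hP: float = 0.5       # phytoplankton half-saturation
    hZ: float = 0.3       # zooplankton half-saturation
    eZ: float = 0.4       # zooplankton assimilation efficiency
    eF: float = 0.3       # fish assimilation efficiency
    mP: float = 0.1       # phytoplankton mortality
    mZ: float = 0.08      # zooplankton mortality
    mF: float = 0.05      # fish mortality
    aP: float = 0.3       # oxygen production per unit phytoplankton
    bR: float = 0.1       # oxygen consumption per unit biomass
    k2: float = 0.15      # reaeration coefficient
    Osat_base: float = 9.1  # DO saturation at 20 degC

    def __post_init__(self):
        for f in fields(self):
            v = getattr(self, f.name)
            if not (isinstance(v, (int, float)) and math.isfinite(v)):
                raise ConfigError(f"{f.name} must be a finite number, got {v!r}")
            if v <= 0:
                raise ConfigError(f"{f.name} must be strictly positive, got {v}")
        for name in ("eZ", "eF"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ConfigError(f"{name} must lie in (0, 1), got {v}")

    def validate_ranges(self, override: bool = False) -> list[str]:
        """Check every parameter against its normal range.

        Returns the list of violation messages; raises ``ConfigError`` unless
        ``override`` is set.
        """
        violations = []
        for name, (lo, hi) in PARAM_RANGES.items():
            v = getattr(self, name)
            if not lo <= v <= hi:
                violations.append(f"{name}={v} outside normal range [{lo}, {hi}]")
        if violations and not override:
            raise ConfigError("; ".join(violations))
        return violations


@dataclass(frozen=True)
class TemperatureForcing:
    """Sinusoidal water-temperature forcing T(t) = mean + A*sin(2*pi*t/period + phase)."""

    T_mean: float = 18.0   # degC
    amplitude: float = 8.0  # degC
    period: float = 25.0   # days
    phase: float = 0.0     # radians

    def __post_init__(self):
        if self.period <= 0:
            raise ConfigError(f"period must be positive, got {self.period}")
        if self.amplitude < 0:
            raise ConfigError(f"amplitude must be >= 0, got {self.amplitude}")

    def __call__(self, t):
        return self.T_mean + self.amplitude * np.sin(
            2.0 * np.pi * np.asarray(t) / self.period + self.phase
        )


class Trajectory(NamedTuple):
    """Times (days) and state matrix (n, 4) ordered P, Z, F, O."""

    times: np.ndarray
    states: np.ndarray

    def to_dataframe(self):
        import pandas as pd

        df = pd.DataFrame(self.states, columns=list(STATE_NAMES))
        df.insert(0, "time_d", self.times)
        return df


def validate_state(x) -> np.ndarray:
    """Coerce to a length-4 float array and check biomass nonnegativity."""
    x = np.asarray(x, dtype=float)
    if x.shape != (4,):
        raise ConfigError(f"state must have 4 components (P, Z, F, O), got shape {x.shape}")
    if not np.all(np.isfinite(x)):
        raise ConfigError(f"state contains non-finite values: {x}")
    if np.any(x[:3] < 0):
        raise ConfigError(f"biomasses must be nonnegative, got {x[:3]}")
    return x


def saturation_oxygen(T: float, Osat_base: float) -> float:
    """Oxygen saturation (mg/L) at water temperature T (degC).

    Linearised around the 20 degC reference: Osat_base * (1 - 0.02*(T - 20)).
    Only the range 0-40 degC is supported; the linear form has not been
    validated outside it.
    """
    if Osat_base <= 0:
        raise ConfigError(f"Osat_base must be positive, got {Osat_base}")
    T = np.asarray(T, dtype=float)
    if np.any(T < 0.0) or np.any(T > 40.0):
        raise OutOfRangeError(f"temperature {T} degC outside supported range [0, 40]")
    out = Osat_base * (1.0 - 0.02 * (T - 20.0))
    return float(out) if out.ndim == 0 else out


def rhs(x, params: EcosystemParams, T: float) -> np.ndarray:
    """Right-hand side of the P-Z-F-O system (per-day rates)."""
    P, Z, F, O = np.asarray(x, dtype=float)
    p = params
    graze = p.gZ * P * Z / (p.hP + P)
    pred = p.gF * Z * F / (p.hZ + Z)
    osat = saturation_oxygen(T, p.Osat_base)
    return np.array(
        [
            p.rP * P * (1.0 - P / p.K) - graze - p.mP * P,
            p.eZ * graze - pred - p.mZ * Z,
            p.eF * pred - p.mF * F,
            p.aP * P - p.bR * (P + Z + F) + p.k2 * (osat - O),
        ]
    )


def jacobian(x, params: EcosystemParams, T: float) -> np.ndarray:
    """Closed-form Jacobian d(rhs)/dX evaluated at state ``x``.

    The oxygen row is state-independent: [aP - bR, -bR, -bR, -k2].
    """
    P, Z, F, _O = np.asarray(x, dtype=float)
    p = params
    dP = p.hP + P
    dZ = p.hZ + Z
    J = np.zeros((4, 4))
    J[0, 0] = p.rP * (1.0 - 2.0 * P / p.K) - p.gZ * Z * p.hP / dP**2 - p.mP
    J[0, 1] = -p.gZ * P / dP
    J[1, 0] = p.eZ * p.gZ * Z * p.hP / dP**2
    J[1, 1] = p.eZ * p.gZ * P / dP - p.gF * F * p.hZ / dZ**2 - p.mZ
    J[1, 2] = -p.gF * Z / dZ
    J[2, 1] = p.eF * p.gF * F * p.hZ / dZ**2
    J[2, 2] = p.eF * p.gF * Z / dZ - p.mF
    J[3, :] = [p.aP - p.bR, -p.bR, -p.bR, -p.k2]
    return J


def rk4_step(x, t: float, dt: float, params: EcosystemParams, forcing) -> np.ndarray:
    """One classical Runge-Kutta step of length ``dt`` from time ``t`` (days).

    ``forcing`` is a callable t -> temperature (degC).
    """
    k1 = rhs(x, params, forcing(t))
    k2 = rhs(x + 0.5 * dt * k1, params, forcing(t + 0.5 * dt))
    k3 = rhs(x + 0.5 * dt * k2, params, forcing(t + 0.5 * dt))
    k4 = rhs(x + dt * k3, params, forcing(t + dt))
    return x + dt / 6.0 * (k1 + 2.0 * k2 + 2.0 * k3 + k4)


def integrate(
    x0,
    params: EcosystemParams,
    forcing: TemperatureForcing,
    t_span: float,
    dt: float = 0.01,
) -> Trajectory:
    """Fixed-step RK4 integration over ``t_span`` days.

    After each step the state is projected onto the physically valid region
    (all components clipped to >= 0); biomasses driven to zero therefore stay
    at zero rather than going negative.
    """
    if dt <= 0:
        raise ConfigError(f"dt must be positive, got {dt}")
    if t_span <= 0:
        raise ConfigError(f"t_span must be positive, got {t_span}")
    x = validate_state(x0)
    n = int(round(t_span / dt))
    times = np.arange(n + 1) * dt
    states = np.empty((n + 1, 4))
    states[0] = x
    for i in range(n):
        x = rk4_step(x, times[i], dt, params, forcing)
        if not np.all(np.isfinite(x)):
            raise IntegrationDivergedError(i + 1, times[i + 1])
        x = np.maximum(x, 0.0)
        states[i + 1] = x
    return Trajectory(times=times, states=states)
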