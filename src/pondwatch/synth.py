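"""Synthetic truth trajectories and sensor streams.

Stands in for field data: simulates the P-Z-F-O system with optional
per-sample process noise, then renders realistic sensor records -- hourly
dissolved-oxygen readings with Gaussian noise, noise-free temperature,
sparse chlorophyll-a derived from the effective phytoplankton biomass, and
optional injected outlier spikes.  Every stochastic operation is a pure
function of its inputs and the seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import datetime, timedelta
from typing import NamedTuple, Optional, Sequence

import numpy as np

from .dataio import MeasurementRecord
from .errors import ConfigError, IntegrationDivergedError
from .indirect import IndirectCoeffs, predict_indirect
from .model import (
    EcosystemParams,
    TemperatureForcing,
    Trajectory,
    rk4_step,
    validate_state,
)

DEFAULT_START = datetime(2025, 9, 1, 0, 0, 0)


def reference_scenario(
    duration_d: float = 50.0, seed: int = 0
) -> tuple[EcosystemParams, TemperatureForcing, NoiseSpec, np.ndarray, SamplingSchedule]:
    """The package's standard bloom scenario.

    A temperate pond with base oxygen saturation 10 mg/L, sinusoidal
    temperature (mean 18 degC, amplitude 8 degC, period 25 days), hourly DO
    sampling with measurement noise 0.08 mg/L and per-step process noise
    0.02, started from X0 = [1.5, 0.8, 0.3, 9.0].  Used by the worked
    example, the filter benchmarks and the CLI demo.
    """
    params = EcosystemParams(Osat_base=10.0)
    forcing = TemperatureForcing(T_mean=18.0, amplitude=8.0, period=25.0)
    noise = NoiseSpec(meas_std_do=0.08, process_std=0.02, seed=seed)
    x0 = np.array([1.5, 0.8, 0.3, 9.0])
    schedule = SamplingSchedule(do_interval_h=1.0, chl_interval_d=3.0, duration_d=duration_d)
    return params, forcing, noise, x0, schedule


@dataclass(frozen=True)
class NoiseSpec:
    """Noise settings of the simulated sensor chain.

    ``process_std`` is the per-state, per-sampling-step standard deviation of
    the additive Gaussian perturbation applied to the true trajectory (the
    same convention under which the DO measurement noise 0.08 mg/L is a
    standard deviation).
    """

    meas_std_do: float = 0.08     # mg/L
    process_std: float = 0.02     # per state, per sampling step
    chl_noise_std: float = 0.3    # ug/L
    outlier_rate: float = 0.0     # probability per DO sample
    outlier_magnitude: float = 10.0  # mg/L
    seed: int = 0

    def __post_init__(self):
        for name in ("meas_std_do", "process_std", "chl_noise_std", "outlier_magnitude"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        if not 0 <= self.outlier_rate <= 1:
            raise ConfigError("outlier_rate must lie in [0, 1]")


@dataclass(frozen=True)
class SamplingSchedule:
    """Sampling cadence: hourly DO, chlorophyll once every 3 days by default."""

    do_interval_h: float = 1.0
    chl_interval_d: float = 3.0
    duration_d: float = 30.0

    def __post_init__(self):
        if self.do_interval_h <= 0 or self.chl_interval_d <= 0:
            raise ConfigError("sampling intervals must be positive")
        if self.duration_d <= 0:
            raise ConfigError("duration must be positive")

    @property
    def do_interval_d(self) -> float:
        return self.do_interval_h / 24.0


class SimResult(NamedTuple):
    """Ground truth at sample times: times (days), states (n,4), temperatures."""

    times: np.ndarray
    states: np.ndarray
    temperatures: np.ndarray

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "time_d": self.times,
                "P": self.states[:, 0],
                "Z": self.states[:, 1],
                "F": self.states[:, 2],
                "O": self.states[:, 3],
                "T": self.temperatures,
            }
        )


def temperature_series(forcing: TemperatureForcing, times) -> np.ndarray:
    """Evaluate the temperature sinusoid at the given times (days)."""
    times = np.asarray(times, dtype=float)
    if times.size and (np.any(np.diff(times) < 0) or times[0] < 0):
        raise ConfigError("times must be sorted and nonnegative")
    return np.asarray(forcing(times), dtype=float)


def simulate_truth(
    params: EcosystemParams,
    forcing: TemperatureForcing,
    noise: NoiseSpec,
    x0,
    schedule: SamplingSchedule,
    n_substeps: int = 4,
) -> SimResult:
    """Integrate the ecosystem over the schedule, optionally with process noise.

    Between consecutive sample times the deterministic dynamics are advanced
    with ``n_substeps`` RK4 steps (each substep clipped to the valid region,
    exactly as :func:`pondwatch.model.integrate` does); if ``process_std`` is
    positive, a zero-mean Gaussian perturbation is then added to every state
    component and the state re-projected.  With ``process_std == 0`` the
    result is identical to ``integrate`` evaluated with the same step size.
    """
    x = validate_state(x0)
    rng = np.random.default_rng(noise.seed)
    dt = schedule.do_interval_d
    h = dt / n_substeps
    n = int(round(schedule.duration_d / dt))
    times = np.arange(n + 1) * dt
    states = np.empty((n + 1, 4))
    states[0] = x
    for i in range(n):
        t = times[i]
        for j in range(n_substeps):
            x = rk4_step(x, t + j * h, h, params, forcing)
            if not np.all(np.isfinite(x)):
                raise IntegrationDivergedError(i + 1, t)
            x = np.maximum(x, 0.0)
        if noise.process_std > 0:
            x = x + rng.normal(0.0, noise.process_std, size=4)
            x = np.maximum(x, 0.0)
        states[i + 1] = x
    return SimResult(times=times, states=states, temperatures=temperature_series(forcing, times))


def sample_measurements(
    sim: SimResult,
    coeffs: Optional[IndirectCoeffs],
    noise: NoiseSpec,
    schedule: SamplingSchedule,
    start_time: datetime = DEFAULT_START,
    source_id: str = "node-0",
) -> list[MeasurementRecord]:
    """Render sensor records from a truth trajectory.

    DO is sampled at every schedule step with Gaussian noise; temperature is
    copied noise-free.  Chlorophyll-a records appear every ``chl_interval_d``
    days (starting at day 0), computed from the true P and Z through the
    effective-biomass proxy, plus chlorophyll noise.  The first record (t=0)
    is the initial state.
    """
    if schedule.duration_d > sim.times[-1] + 1e-9:
        raise ConfigError("schedule exceeds simulated duration")
    rng = np.random.default_rng(noise.seed + 1)  # independent of process noise
    records = []
    chl_every = max(1, int(round(schedule.chl_interval_d / schedule.do_interval_d)))
    n = int(round(schedule.duration_d / schedule.do_interval_d))
    for i in range(n + 1):
        t = sim.times[i]
        do = float(sim.states[i, 3])
        if noise.meas_std_do > 0:
            do += rng.normal(0.0, noise.meas_std_do)
        chl = None
        if i % chl_every == 0:
            _s, chl = predict_indirect(
                sim.states[i, 0], sim.states[i, 1], coeffs or IndirectCoeffs(),
                warn=False,
            )
            if noise.chl_noise_std > 0:
                chl += rng.normal(0.0, noise.chl_noise_std)
            chl = float(max(chl, 0.0))
        records.append(
            MeasurementRecord(
                timestamp=start_time + timedelta(days=float(t)),
                do_mg_l=max(do, 0.0),
                temp_c=float(sim.temperatures[i]),
                chl_ug_l=chl,
                source_id=source_id,
            )
        )
    return records


def inject_outliers(
    records: Sequence[MeasurementRecord], noise: NoiseSpec
) -> tuple[list[MeasurementRecord], list[int]]:
    """Spike DO readings by +/- ``outlier_magnitude`` with prob. ``outlier_rate``.

    Returns the modified records and the list of true outlier indices (for
    test assertions).  Seeded independently of measurement noise.
    """
    rng = np.random.default_rng(noise.seed + 2)
    out = []
    idx = []
    for i, r in enumerate(records):
        if r.do_mg_l is not None and noise.outlier_rate > 0 and rng.random() < noise.outlier_rate:
            sign = 1.0 if rng.random() < 0.5 else -1.0
            out.append(
                MeasurementRecord(
                    timestamp=r.timestamp,
                    do_mg_l=r.do_mg_l + sign * noise.outlier_magnitude,
                    temp_c=r.temp_c,
                    chl_ug_l=r.chl_ug_l,
                    secchi_m=r.secchi_m,
                    ph_surface=r.ph_surface,
                    ph_bottom=r.ph_bottom,
                    source_id=r.source_id,
                )
            )
            idx.append(i)
        else:
            out.append(r)
    return out, idx
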