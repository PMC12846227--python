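"""Constrained, adaptive Extended Kalman Filter for the P-Z-F-O model.

Only dissolved oxygen is measured (H = [0, 0, 0, 1]); phytoplankton,
zooplankton and fish biomass are reconstructed through the model coupling.
Each cycle is predict -> anomaly gate -> update -> constraint projection ->
noise adaptation:

* Prediction propagates the estimate with RK4 substeps and composes the
  discrete transition matrix F1 = prod(I + J*h) along the propagated state.
* The innovation is gated on its Mahalanobis distance against the
  chi-squared quantile at ``chi2_level``; rejected measurements are skipped
  (prediction-only step, "simple prognosis" fallback) and, beyond a short
  streak, the covariance is inflated so a genuine regime change can
  re-capture the filter instead of locking it out.
* After every accepted update the state is projected onto the physically
  valid region (biomasses >= 0, O within [Omin, Omax]).
* Q and R are adapted from innovation statistics with exponential
  forgetting: R tracks max(C_hat - H P- H', R_floor) where C_hat is the
  smoothed squared innovation, and Q is the initial diagonal scaled by the
  smoothed, clipped ratio of observed to model-implied innovation variance.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from typing import NamedTuple, Optional, Sequence

import numpy as np
from scipy.stats import chi2 as _chi2

from .errors import (
    ConfigError,
    FilterDivergedError,
    NumericalDegeneracyError,
    PondwatchError,
    UndefinedIndexError,
)
from .model import EcosystemParams, TemperatureForcing, jacobian, rk4_step, STATE_NAMES

#: DO-only observation row.
H_DO = np.array([[0.0, 0.0, 0.0, 1.0]])


@dataclass(frozen=True)
class ObservationModel:
    """Linear observation row(s); default selects dissolved oxygen."""

    H: np.ndarray = field(default_factory=lambda: H_DO.copy())

    def __post_init__(self):
        H = np.atleast_2d(np.asarray(self.H, dtype=float))
        object.__setattr__(self, "H", H)


@dataclass(frozen=True)
class FilterConfig:
    """Tunables of the constrained adaptive EKF.

    ``alpha`` and ``xi_max`` parameterise the initial process-noise diagonal
    q_ii = (alpha_i * xi_max_i * dt)^2: alpha_i is the dimensionless
    uncertainty coefficient (0.05-0.15 for this class of model) and xi_max_i
    the expected dynamic scale of state i over one sampling step.  The
    default xi_max of 5 for every component matches the carrying-capacity
    scale of the biomasses and the few-mg/L scale of daily DO excursions.

    ``r_floor`` defaults to (0.05)^2: optical DO probes do not resolve
    better than ~0.05 mg/L, so adaptation never trusts the sensor beyond
    that physical bound.
    """

    dt: float = 1.0 / 24.0            # sampling interval, days
    alpha: tuple = (0.1, 0.1, 0.1, 0.1)
    xi_max: tuple = (5.0, 5.0, 5.0, 5.0)
    o_min: float = 0.0                # mg/L
    o_max: float = 20.0               # mg/L
    chi2_level: float = 0.90
    adapt_lambda: float = 0.05        # forgetting factor
    r_floor: float = 0.05**2
    q_floor: float = 0.0
    n_substeps: int = 4
    q_scale_bounds: tuple = (0.1, 10.0)
    reject_streak_limit: int = 5      # consecutive rejections before inflation
    reject_inflation: float = 1.2     # covariance multiplier per further rejection
    cov_ceiling_factor: float = 2.0   # diag capped at (factor * xi_max_i)^2
    p0_diag: Optional[tuple] = None   # initial covariance diagonal, if known
    adapt: bool = True
    validate_alpha: bool = True

    def __post_init__(self):
        if self.dt <= 0:
            raise ConfigError("dt must be positive")
        if self.validate_alpha and any(not 0.05 <= a <= 0.15 for a in self.alpha):
            raise ConfigError(
                f"alpha entries {self.alpha} outside [0.05, 0.15]; "
                "set validate_alpha=False to override"
            )
        if any(x <= 0 for x in self.xi_max):
            raise ConfigError("xi_max entries must be positive")
        if not 0 < self.chi2_level < 1:
            raise ConfigError("chi2_level must lie in (0, 1)")
        if not 0 < self.adapt_lambda <= 1:
            raise ConfigError("adapt_lambda must lie in (0, 1]")
        if self.r_floor <= 0:
            raise ConfigError("r_floor must be positive")
        if self.o_min >= self.o_max:
            raise ConfigError("o_min must be below o_max")


class InnovationRecord(NamedTuple):
    Y: float
    S: float


@dataclass
class FilterState:
    """Full internal state of the filter at one step."""

    x_hat: np.ndarray           # (4,) estimate
    P_cov: np.ndarray           # (4,4) covariance
    Q: np.ndarray               # (4,4) process-noise covariance
    R: float                    # scalar measurement-noise variance (DO-only)
    k: int = 0                  # step index
    t: float = 0.0              # current time, days
    Q0: np.ndarray = None       # initial Q (adaptation reference)
    c_hat: Optional[float] = None   # smoothed squared innovation
    rho: float = 1.0            # smoothed Q scale factor
    reject_streak: int = 0
    innovation_history: list = field(default_factory=list)

    def __post_init__(self):
        self.x_hat = np.asarray(self.x_hat, dtype=float).copy()
        self.P_cov = _symmetrize(np.asarray(self.P_cov, dtype=float))
        self.Q = np.asarray(self.Q, dtype=float).copy()
        if self.Q0 is None:
            self.Q0 = self.Q.copy()
        if self.R <= 0:
            raise ConfigError("R must be positive")

    def copy(self) -> "FilterState":
        fs = copy.copy(self)
        fs.x_hat = self.x_hat.copy()
        fs.P_cov = self.P_cov.copy()
        fs.Q = self.Q.copy()
        fs.Q0 = self.Q0.copy()
        fs.innovation_history = list(self.innovation_history)
        return fs


def _symmetrize(P: np.ndarray) -> np.ndarray:
    return 0.5 * (P + P.T)


def _apply_cov_ceiling(P: np.ndarray, config: FilterConfig) -> np.ndarray:
    """Cap each diagonal entry at (ceiling_factor * xi_max_i)^2.

    Uncertainty larger than the squared physical range of a state carries no
    information but produces destabilising gains; rows/columns are rescaled
    jointly so the matrix stays positive semidefinite.
    """
    cap = (config.cov_ceiling_factor * np.asarray(config.xi_max, dtype=float)) ** 2
    d = np.diag(P)
    over = d > cap
    if not np.any(over):
        return P
    scale = np.ones_like(d)
    scale[over] = np.sqrt(cap[over] / d[over])
    return _symmetrize(P * np.outer(scale, scale))


def init_noise(config: FilterConfig, meas_std: float) -> tuple[np.ndarray, float]:
    """Initial (Q0, R0): R0 = meas_std^2, q_ii = (alpha_i * xi_max_i * dt)^2."""
    if meas_std <= 0:
        raise ConfigError("meas_std must be positive")
    alpha = np.asarray(config.alpha, dtype=float)
    xi = np.asarray(config.xi_max, dtype=float)
    if np.any(xi <= 0):
        raise ConfigError("xi_max must be positive")
    q = (alpha * xi * config.dt) ** 2
    return np.diag(np.maximum(q, config.q_floor)), float(meas_std**2)


def default_initial_cov(config: FilterConfig, meas_std: float) -> np.ndarray:
    """Default P0 for a field start with unobserved biomasses.

    Diagonal (0.5*xi_max)^2 for P and Z, four times that for the weakly
    observable F, and the measurement variance for the directly observed O.
    """
    xi = np.asarray(config.xi_max, dtype=float)
    d = (0.5 * xi) ** 2
    d[2] *= 4.0
    d[3] = meas_std**2
    return np.diag(d)


def make_filter_state(
    x0,
    config: FilterConfig,
    meas_std: float = 0.08,
    P0: Optional[np.ndarray] = None,
    t0: float = 0.0,
) -> FilterState:
    Q0, R0 = init_noise(config, meas_std)
    if P0 is None:
        if config.p0_diag is not None:
            P0 = np.diag(np.asarray(config.p0_diag, dtype=float))
        else:
            P0 = default_initial_cov(config, meas_std)
    return FilterState(
        x_hat=np.asarray(x0, dtype=float),
        P_cov=np.asarray(P0, dtype=float),
        Q=Q0,
        R=max(R0, config.r_floor),
        t=t0,
    )


def predict(
    fs: FilterState,
    params: EcosystemParams,
    forcing: TemperatureForcing,
    config: FilterConfig,
    dt: Optional[float] = None,
) -> FilterState:
    """A-priori step: propagate estimate over ``dt`` and P <- F1 P F1' + Q.

    The transition matrix is composed as F1 = prod_j (I + J(x_j) h) over the
    RK4 substeps, with the Jacobian evaluated along the propagated state.
    """
    fs = fs.copy()
    dt = config.dt if dt is None else dt
    h = dt / config.n_substeps
    x = fs.x_hat
    F1 = np.eye(4)
    for j in range(config.n_substeps):
        t = fs.t + j * h
        J = jacobian(x, params, forcing(t))
        x = rk4_step(x, t, h, params, forcing)
        if not np.all(np.isfinite(x)):
            raise FilterDivergedError(f"prediction diverged at t={t:g} d")
        F1 = (np.eye(4) + J * h) @ F1
    fs.x_hat = x
    fs.P_cov = _symmetrize(F1 @ fs.P_cov @ F1.T + fs.Q)
    fs.t += dt
    fs.k += 1
    return fs


def update(
    fs: FilterState, z_do: float, obs: ObservationModel = ObservationModel()
) -> tuple[FilterState, InnovationRecord]:
    """A-posteriori step from one DO measurement (standard EKF algebra)."""
    fs = fs.copy()
    H = obs.H
    x = fs.x_hat
    P = fs.P_cov
    y = float(z_do - (H @ x)[0])
    s = float((H @ P @ H.T)[0, 0] + fs.R)
    if s <= 0:
        raise NumericalDegeneracyError(f"innovation variance S={s} <= 0")
    K = (P @ H.T / s)[:, 0]
    fs.x_hat = x + K * y
    fs.P_cov = _symmetrize((np.eye(4) - np.outer(K, H[0])) @ P)
    rec = InnovationRecord(Y=y, S=s)
    fs.innovation_history.append(rec)
    return fs, rec


def project_constraints(x, config: FilterConfig) -> np.ndarray:
    """Clip P, Z, F to [0, inf) and O to [o_min, o_max]."""
    x = np.asarray(x, dtype=float).copy()
    x[:3] = np.maximum(x[:3], 0.0)
    x[3] = np.clip(x[3], config.o_min, config.o_max)
    return x


def chi2_threshold(config: FilterConfig, dof: int = 1) -> float:
    return float(_chi2.ppf(config.chi2_level, dof))


def anomaly_gate(Y, S, config: FilterConfig) -> tuple[float, bool]:
    """Mahalanobis gate: accept iff D^2 = Y' S^-1 Y <= chi2(level, dof)."""
    Y = np.atleast_1d(np.asarray(Y, dtype=float))
    S = np.atleast_2d(np.asarray(S, dtype=float))
    d2 = float(Y @ np.linalg.solve(S, Y))
    return d2, d2 <= chi2_threshold(config, dof=Y.size)


def check_physical_anomaly(x, config: FilterConfig) -> tuple[bool, list[str]]:
    """Flag states violating physical limits (before projection)."""
    x = np.asarray(x, dtype=float)
    violations = []
    for i, name in enumerate(STATE_NAMES[:3]):
        if x[i] < 0:
            violations.append(f"{name} < 0")
    if x[3] < config.o_min:
        violations.append("O < Omin")
    if x[3] > config.o_max:
        violations.append("O > Omax")
    return bool(violations), violations


def adapt_noise(
    fs: FilterState, config: FilterConfig, S_prior: Optional[float] = None
) -> FilterState:
    """Innovation-based Q/R adaptation with exponential forgetting.

    C_hat tracks E[Y^2]; the model-consistent decomposition S = H P- H' + R
    gives R <- max(C_hat - H P- H', r_floor).  Q is Q0 scaled by the
    smoothed ratio C_hat-implied/model-implied innovation variance, clipped
    to ``q_scale_bounds``.
    """
    if not fs.innovation_history:
        raise PondwatchError("no innovations recorded yet")
    fs = fs.copy()
    y, s = fs.innovation_history[-1]
    if S_prior is None:
        S_prior = s
    lam = config.adapt_lambda
    fs.c_hat = s if fs.c_hat is None else (1.0 - lam) * fs.c_hat + lam * y * y
    hph = S_prior - fs.R  # prior H P- H'
    fs.R = max(fs.c_hat - hph, config.r_floor)
    lo, hi = config.q_scale_bounds
    fs.rho = (1.0 - lam) * fs.rho + lam * float(np.clip(y * y / S_prior, lo, hi))
    fs.Q = fs.Q0 * float(np.clip(fs.rho, lo, hi))
    return fs


class FilterRun(NamedTuple):
    """Per-step outputs of :func:`run_filter` (arrays aligned with records)."""

    times: np.ndarray          # days since first record
    x_pred: np.ndarray         # a-priori estimates (n, 4)
    x_post: np.ndarray         # a-posteriori estimates (n, 4)
    P_diag: np.ndarray         # posterior covariance diagonal (n, 4)
    innovation: np.ndarray     # Y_k (nan when no DO record)
    S: np.ndarray              # innovation variance
    d2: np.ndarray             # Mahalanobis distance
    accepted: np.ndarray       # gate decision (bool)
    R_hist: np.ndarray
    Q_trace: np.ndarray
    final_state: FilterState

    @property
    def predicted_do(self) -> np.ndarray:
        """One-step-ahead DO predictions (a-priori O component)."""
        return self.x_pred[:, 3]

    def to_dataframe(self):
        import pandas as pd

        df = pd.DataFrame(
            {
                "time_d": self.times,
                "predicted_O": self.predicted_do,
                "est_P": self.x_post[:, 0],
                "est_Z": self.x_post[:, 1],
                "est_F": self.x_post[:, 2],
                "est_O": self.x_post[:, 3],
                "innovation": self.innovation,
                "d2": self.d2,
                "accepted": self.accepted,
                "R": self.R_hist,
                "trace_Q": self.Q_trace,
            }
        )
        return df


def run_filter(
    records: Sequence,
    params: EcosystemParams,
    forcing: TemperatureForcing,
    config: FilterConfig,
    x0,
    P0: Optional[np.ndarray] = None,
    meas_std: float = 0.08,
) -> FilterRun:
    """Full predict -> gate -> update -> project -> adapt cycle over records.

    ``records`` may be MeasurementRecord objects (time taken from
    timestamps) or (t_days, do) pairs.  Measurements flagged by the gate or
    by the physical-limits check are skipped: the step keeps the prediction
    only, and after ``reject_streak_limit`` consecutive rejections the
    covariance is inflated each further rejected step so the filter can
    re-acquire after a genuine regime change.
    """
    if len(records) == 0:
        raise ConfigError("empty record sequence")
    times, dos = _extract_do_series(records)
    fs = make_filter_state(x0, config, meas_std=meas_std, P0=P0, t0=times[0])
    n = len(times)
    out = {
        "x_pred": np.empty((n, 4)),
        "x_post": np.empty((n, 4)),
        "P_diag": np.empty((n, 4)),
        "innovation": np.full(n, np.nan),
        "S": np.full(n, np.nan),
        "d2": np.full(n, np.nan),
        "accepted": np.zeros(n, dtype=bool),
        "R_hist": np.empty(n),
        "Q_trace": np.empty(n),
    }
    gate_thresh = chi2_threshold(config, dof=1)
    prev_t = times[0]
    for i in range(n):
        dt = times[i] - prev_t
        prev_t = times[i]
        if dt > 0:
            fs = predict(fs, params, forcing, config, dt=dt)
            fs.P_cov = _apply_cov_ceiling(fs.P_cov, config)
        out["x_pred"][i] = fs.x_hat
        z = dos[i]
        accept = z is not None and np.isfinite(z)
        if accept:
            # a measured DO outside physical bounds is itself anomalous
            flagged, _ = check_physical_anomaly(np.array([0.0, 0.0, 0.0, z]), config)
            s_prior = float(fs.P_cov[3, 3] + fs.R)
            y = float(z - fs.x_hat[3])
            d2 = y * y / s_prior
            out["innovation"][i] = y
            out["S"][i] = s_prior
            out["d2"][i] = d2
            accept = (not flagged) and d2 <= gate_thresh
        if accept:
            fs, _rec = update(fs, z)
            fs.x_hat = project_constraints(fs.x_hat, config)
            if config.adapt:
                fs = adapt_noise(fs, config, S_prior=s_prior)
            fs.reject_streak = 0
            out["accepted"][i] = True
        else:
            fs.reject_streak += 1
            if fs.reject_streak > config.reject_streak_limit:
                fs.P_cov = _apply_cov_ceiling(
                    _symmetrize(fs.P_cov * config.reject_inflation), config)
        out["x_post"][i] = fs.x_hat
        out["P_diag"][i] = np.diag(fs.P_cov)
        out["R_hist"][i] = fs.R
        out["Q_trace"][i] = np.trace(fs.Q)
        if not np.all(np.isfinite(fs.x_hat)):
            raise FilterDivergedError(f"estimate diverged at step {i}")
    return FilterRun(
        times=np.asarray(times),
        final_state=fs,
        **out,
    )


def _extract_do_series(records):
    first = records[0]
    if hasattr(first, "timestamp"):
        t0 = first.timestamp
        times = np.array(
            [(r.timestamp - t0).total_seconds() / 86400.0 for r in records]
        )
        dos = [r.do_mg_l for r in records]
    else:
        times = np.array([float(r[0]) for r in records])
        dos = [float(r[1]) for r in records]
    if np.any(np.diff(times) < 0):
        raise ConfigError("records must be time-sorted")
    return times, dos


def open_loop(
    records: Sequence,
    params: EcosystemParams,
    forcing: TemperatureForcing,
    config: FilterConfig,
    x0,
) -> np.ndarray:
    """Model propagation with no measurement updates (reference for RMSE)."""
    times, _ = _extract_do_series(records)
    x = np.asarray(x0, dtype=float).copy()
    out = np.empty((len(times), 4))
    prev_t = times[0]
    for i, t in enumerate(times):
        dt = t - prev_t
        prev_t = t
        if dt > 0:
            h = dt / config.n_substeps
            for j in range(config.n_substeps):
                x = rk4_step(x, t - dt + j * h, h, params, forcing)
            x = np.maximum(x, 0.0)
        out[i] = x
    return out


def rmse(truth, estimate, component: Optional[int] = None) -> float:
    """Root of the mean squared per-step state error.

    With ``component=None`` the squared Euclidean norm over all state
    components is averaged; otherwise a single component is scored.
    """
    truth = np.asarray(truth, dtype=float)
    estimate = np.asarray(estimate, dtype=float)
    if truth.shape != estimate.shape:
        raise ConfigError(f"shape mismatch: {truth.shape} vs {estimate.shape}")
    err = truth - estimate
    if err.ndim == 1:
        return float(np.sqrt(np.mean(err**2)))
    if component is not None:
        return float(np.sqrt(np.mean(err[:, component] ** 2)))
    return float(np.sqrt(np.mean(np.sum(err**2, axis=1))))


def stability_index(states, window: Optional[slice] = None) -> float:
    """SI = 1 - mean_i(std_i / mean_i) over the given window of states.

    Near 1 for a quiescent system; decreases as fluctuations grow relative
    to the mean levels.  Undefined when any component mean is ~0.
    """
    states = np.atleast_2d(np.asarray(states, dtype=float))
    if window is not None:
        states = states[window]
    if states.shape[0] == 0:
        raise ConfigError("empty window")
    m = states.mean(axis=0)
    if np.any(np.abs(m) < 1e-9):
        raise UndefinedIndexError(f"component mean(s) ~0: {m}")
    s = states.std(axis=0)
    return float(1.0 - np.mean(s / m))
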