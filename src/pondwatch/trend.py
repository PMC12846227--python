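"""Operative short-term layer: cleaning, trend fitting and fish-kill decisions.

Hourly sensor data are cleaned (isolated-spike elimination or median-filter
interpolation), segmented into day (06:00-21:00) and night regimes so each
segment is close to monotone, and extrapolated with one of three
least-squares curve families:

    linear       f(t) = a1 + a2*t
    exponential  f(t) = a1 * exp(a2*t)     (fitted by log-linearisation)
    cubic        f(t) = a1 + a2*t + a3*t^2 + a4*t^3

A fit is trusted only when the Pearson correlation r between fitted and
observed values reaches ``r_min`` (default 0.85, within the accepted
0.8-0.9 band).  For a trusted fit, the time at which the extrapolated
parameter crosses its species-specific critical value (Tcrit) is computed;
corrective action is initiated when the remaining lead time is shorter than
the preset margin (default 4 h, within the recommended 3-5 h window).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from datetime import datetime, time as dtime
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .errors import (
    ConfigError,
    SingularDesignError,
    TooFewPointsError,
    UndefinedCorrelationError,
    UnfittableError,
)

CURVE_TYPES = ("linear", "exponential", "cubic")

#: phytoplankton biomass above which an algal bloom is likely, g/m^3
BLOOM_THRESHOLD = 2.5
#: fish biomass below which the stock is considered in danger, g/m^3
FISH_DANGER_THRESHOLD = 0.1
#: surface DO at/above which stratification (unmixed water) is suspected, mg/L
SURFACE_DO_STRATIFICATION = 10.0


# ---------------------------------------------------------------------------
# Species limits (winter respiratory-depression / death DO levels)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SpeciesLimits:
    """Critical DO and pH levels for one fish species.

    ``resp_hi``/``resp_lo`` bound the respiratory-depression DO range
    (mg/L); ``death_do`` is the upper endpoint of the death range, used as a
    conservative alarm threshold.  pH limits default to the carp-pond norm
    6.5-8.5; salmonids use 8.0 as the upper bound.
    """

    species: str = "carp"
    resp_hi: float = 3.0
    resp_lo: float = 2.0
    death_do: float = 0.5
    ph_low: float = 6.5
    ph_high: float = 8.5
    ph_ratio_limit: float = 1.05

    def __post_init__(self):
        if not self.death_do < self.resp_lo <= self.resp_hi:
            raise ConfigError(
                f"{self.species}: need death_do < resp_lo <= resp_hi, got "
                f"{self.death_do}, {self.resp_lo}, {self.resp_hi}"
            )
        if not self.ph_low < self.ph_high:
            raise ConfigError("ph_low must be below ph_high")


def _sp(name, resp, death, salmonid=False):
    return SpeciesLimits(
        species=name,
        resp_hi=resp[0],
        resp_lo=resp[1],
        death_do=death[0],
        ph_high=8.0 if salmonid else 8.5,
    )


#: Reference winter DO limits per species (respiratory depression range,
#: death level; upper endpoints used as alarm thresholds).
SPECIES_TABLE = {
    s.species: s
    for s in [
        _sp("nelma", (7.5, 6.0), (4.5, 4.0), salmonid=True),
        _sp("sterlet", (7.5, 6.0), (3.5, 3.5)),
        _sp("muksun", (4.5, 3.0), (2.0, 1.5), salmonid=True),
        _sp("peled", (4.5, 3.0), (1.5, 1.0), salmonid=True),
        _sp("common dace", (4.5, 3.0), (1.2, 0.8)),
        _sp("european perch", (4.5, 3.0), (1.1, 0.6)),
        _sp("ide", (4.5, 3.0), (0.5, 0.5)),
        _sp("roach", (3.0, 2.0), (0.7, 0.7)),
        _sp("northern pike", (3.0, 2.0), (0.6, 0.3)),
        _sp("crucian carp", (2.0, 1.0), (0.1, 0.1)),
    ]
}


# ---------------------------------------------------------------------------
# Outlier handling and aggregation
# ---------------------------------------------------------------------------

def eliminate_outliers(
    points: Sequence,
    abs_low: Optional[float] = None,
    abs_high: Optional[float] = None,
    neighbor_delta: Optional[float] = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Distance-based outlier flagging on a time-sorted (t, y) sequence.

    A point is an outlier if its value leaves the [abs_low, abs_high] band,
    or if it is an isolated spike: the absolute difference to *both*
    neighbours exceeds ``neighbor_delta`` (endpoints use their single
    neighbour).  Returns (kept points (m,2), outlier mask (n,)).
    """
    pts = np.asarray(points, dtype=float)
    if pts.size == 0 or len(pts) < 3:
        raise TooFewPointsError(f"need at least 3 points, got {len(pts)}")
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ConfigError("points must be an (n, 2) array of (t, y)")
    n = len(pts)
    if np.any(np.diff(pts[:, 0]) < 0):
        raise ConfigError("points must be time-sorted")
    y = pts[:, 1]
    mask = np.zeros(n, dtype=bool)
    if abs_low is not None:
        mask |= y < abs_low
    if abs_high is not None:
        mask |= y > abs_high
    if neighbor_delta is not None:
        for i in range(n):
            diffs = []
            if i > 0:
                diffs.append(abs(y[i] - y[i - 1]))
            if i < n - 1:
                diffs.append(abs(y[i] - y[i + 1]))
            if diffs and all(d > neighbor_delta for d in diffs):
                mask[i] = True
    return pts[~mask], mask


def median_filter_clean(series, window: int = 5, n_dev: float = 3.0) -> np.ndarray:
    """Replace median-filter outliers by linear interpolation of neighbours.

    A point is anomalous when it deviates from its centred rolling median by
    more than ``n_dev`` times the rolling median absolute deviation.
    """
    y = np.asarray(series, dtype=float)
    if window < 3 or window % 2 == 0:
        raise ConfigError("window must be odd and >= 3")
    if window > len(y):
        raise ConfigError("window longer than series")
    s = pd.Series(y)
    med = s.rolling(window, center=True, min_periods=1).median().to_numpy()
    dev = np.abs(y - med)
    mad = pd.Series(dev).rolling(window, center=True, min_periods=1).median().to_numpy()
    bad = dev > n_dev * mad
    if not np.any(bad):
        return y.copy()
    out = y.copy()
    good = ~bad
    if not np.any(good):
        return out
    out[bad] = np.interp(np.flatnonzero(bad), np.flatnonzero(good), y[good])
    return out


def daily_stats(records) -> pd.DataFrame:
    """Per-calendar-day minimum and maximum of each numeric channel."""
    df = _records_frame(records)
    df["date"] = df["timestamp"].dt.date
    numeric = [c for c in df.columns if c not in ("timestamp", "date", "source_id")]
    agg = df.groupby("date")[numeric].agg(["min", "max"])
    agg.columns = [f"{c}_{stat}" for c, stat in agg.columns]
    return agg


def segment_day_night(records, day_start: int = 6, night_start: int = 21) -> list[str]:
    """Label each record 'day' (06:00 <= t < 21:00) or 'night'.

    The inclusive-start convention means 06:00 itself is day and 21:00 is
    night.
    """
    labels = []
    for r in records:
        ts = r if isinstance(r, (datetime, dtime)) else r.timestamp
        t = ts.time() if isinstance(ts, datetime) else ts
        labels.append("day" if dtime(day_start) <= t < dtime(night_start) else "night")
    return labels


def _records_frame(records) -> pd.DataFrame:
    if isinstance(records, pd.DataFrame):
        df = records.copy()
        df["timestamp"] = pd.to_datetime(df["timestamp"])
        return df
    rows = []
    for r in records:
        rows.append(
            {
                "timestamp": pd.Timestamp(r.timestamp),
                "do_mg_l": r.do_mg_l,
                "temp_c": r.temp_c,
                "chl_ug_l": r.chl_ug_l,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Curve fitting
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CurveFit:
    """One least-squares trend fit: family, coefficients, fit quality."""

    curve_type: str
    coefficients: tuple
    r: float
    n_points: int

    def __post_init__(self):
        expected = {"linear": 2, "exponential": 2, "cubic": 4}[self.curve_type]
        if len(self.coefficients) != expected:
            raise ConfigError(
                f"{self.curve_type} fit needs {expected} coefficients, "
                f"got {len(self.coefficients)}"
            )

    def __call__(self, t):
        t = np.asarray(t, dtype=float)
        a = self.coefficients
        if self.curve_type == "linear":
            return a[0] + a[1] * t
        if self.curve_type == "exponential":
            return a[0] * np.exp(a[1] * t)
        return a[0] + a[1] * t + a[2] * t**2 + a[3] * t**3


def fit_curve(points: Sequence, curve_type: str) -> CurveFit:
    """Least-squares fit of one curve family to (t, y) points.

    The exponential family is fitted by log-linearisation (requires y > 0);
    deterministic and adequate on the near-monotone day/night segments the
    fits are applied to.
    """
    if curve_type not in CURVE_TYPES:
        raise ConfigError(f"unknown curve type {curve_type!r}")
    pts = np.asarray(points, dtype=float)
    t, y = pts[:, 0], pts[:, 1]
    n = len(t)
    min_n = 5 if curve_type == "cubic" else 3
    if n < min_n:
        raise TooFewPointsError(f"{curve_type} fit needs >= {min_n} points, got {n}")
    if np.ptp(t) == 0:
        raise SingularDesignError("all abscissae equal")
    if curve_type == "linear":
        a2, a1 = np.polyfit(t, y, 1)
        coeffs = (float(a1), float(a2))
    elif curve_type == "exponential":
        if np.any(y <= 0):
            raise UnfittableError("exponential fit requires strictly positive y")
        b1, b0 = np.polyfit(t, np.log(y), 1)
        coeffs = (float(np.exp(b0)), float(b1))
    else:
        c = np.polyfit(t, y, 3)  # descending powers
        coeffs = tuple(float(v) for v in c[::-1])
    fit = CurveFit(curve_type=curve_type, coefficients=coeffs, r=0.0, n_points=n)
    r = correlation(fit, pts)
    return CurveFit(curve_type=curve_type, coefficients=coeffs, r=r, n_points=n)


def correlation(fit: CurveFit, points) -> float:
    """Pearson correlation between fitted values and observations."""
    pts = np.asarray(points, dtype=float)
    if len(pts) < 2:
        raise TooFewPointsError("correlation needs >= 2 points")
    t, y = pts[:, 0], pts[:, 1]
    yhat = fit(t)
    if np.std(y) == 0 or np.std(yhat) == 0:
        raise UndefinedCorrelationError("zero variance in observed or fitted values")
    num = np.mean((yhat - yhat.mean()) * (y - y.mean()))
    return float(num / (np.std(yhat) * np.std(y)))


def best_fit(points: Sequence) -> CurveFit:
    """Fit all three families and keep the highest r.

    Ties (within 1e-12) are broken by simplicity: linear, then exponential,
    then cubic.  Families that cannot be fitted are skipped.
    """
    fits = []
    for ct in CURVE_TYPES:
        try:
            fits.append(fit_curve(points, ct))
        except (UnfittableError, TooFewPointsError, UndefinedCorrelationError):
            continue
    if not fits:
        raise UnfittableError("no curve family could be fitted")
    best = fits[0]
    for f in fits[1:]:
        if f.r > best.r + 1e-12:
            best = f
    return best


def time_to_critical(
    fit: CurveFit,
    critical: float,
    t_now: float,
    horizon: float = 24.0,
) -> Optional[tuple[float, float]]:
    """Earliest t > t_now with f(t) = critical within [t_now, t_now+horizon].

    Returns (absolute crossing time, lead time) in the units of t, or None
    when the extrapolated curve never reaches the critical value inside the
    window.  Linear and exponential families are solved in closed form; the
    cubic by sign-change bracketing plus Brent root refinement.
    """
    a = fit.coefficients
    t_end = t_now + horizon
    if fit.curve_type == "linear":
        if a[1] == 0:
            return None
        tc = (critical - a[0]) / a[1]
        return (tc, tc - t_now) if t_now < tc <= t_end else None
    if fit.curve_type == "exponential":
        if a[1] == 0 or a[0] == 0 or critical / a[0] <= 0:
            return None
        tc = math.log(critical / a[0]) / a[1]
        return (tc, tc - t_now) if t_now < tc <= t_end else None
    # cubic: dense sampling to bracket the first sign change
    grid = np.linspace(t_now, t_end, 2001)
    g = fit(grid) - critical
    if g[0] == 0:  # already at critical "now": not a future crossing
        g = g[1:]
        grid = grid[1:]
    sign_change = np.flatnonzero(np.sign(g[:-1]) * np.sign(g[1:]) <= 0)
    for i in sign_change:
        lo, hi = grid[i], grid[i + 1]
        if g[i] == 0:
            tc = float(lo)
        else:
            tc = float(brentq(lambda t: fit(t) - critical, lo, hi, xtol=1e-10))
        if tc > t_now:
            return tc, tc - t_now
    return None


# ---------------------------------------------------------------------------
# Decision procedure
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Decision:
    """Outcome of the MakeDecision procedure for one parameter."""

    action: str                      # "initiate" | "none"
    reason: str                      # "reliable-and-imminent" | "not-imminent" | "unreliable-fit"
    r: Optional[float] = None
    t_crit: Optional[float] = None   # absolute crossing time (t units of input)
    lead_time: Optional[float] = None
    preset_lead: float = 4.0
    fit: Optional[CurveFit] = None

    def to_dict(self) -> dict:
        return {
            "action": self.action,
            "reason": self.reason,
            "r": self.r,
            "t_crit": self.t_crit,
            "lead_time_h": self.lead_time,
            "preset_lead_h": self.preset_lead,
            "curve_type": self.fit.curve_type if self.fit else None,
        }


def make_decision(
    points: Sequence,
    curve_type: Optional[str],
    critical: float,
    preset_lead: float = 4.0,
    r_min: float = 0.85,
    abs_low: Optional[float] = None,
    abs_high: Optional[float] = None,
    neighbor_delta: Optional[float] = None,
    horizon: float = 24.0,
    validate_r_min: bool = True,
) -> Decision:
    """Outlier elimination -> fit -> correlation gate -> Tcrit -> action.

    Corrective action is initiated only for a reliable fit (r >= r_min)
    whose predicted critical crossing is closer than ``preset_lead`` time
    units.  Any stage failure yields a no-action decision flagged
    unreliable-fit.  Times are in hours for hourly sensor data.
    """
    if validate_r_min and not 0.8 <= r_min <= 0.9:
        raise ConfigError(
            f"r_min={r_min} outside the accepted band [0.8, 0.9]; "
            "set validate_r_min=False to override"
        )
    try:
        kept, _mask = eliminate_outliers(
            points, abs_low=abs_low, abs_high=abs_high, neighbor_delta=neighbor_delta
        )
        fit = best_fit(kept) if curve_type is None else fit_curve(kept, curve_type)
    except (TooFewPointsError, UnfittableError, SingularDesignError,
            UndefinedCorrelationError):
        return Decision(action="none", reason="unreliable-fit", preset_lead=preset_lead)
    if fit.r < r_min:
        return Decision(
            action="none", reason="unreliable-fit", r=fit.r,
            preset_lead=preset_lead, fit=fit,
        )
    t_now = float(np.asarray(kept)[-1, 0])
    crossing = time_to_critical(fit, critical, t_now, horizon=horizon)
    if crossing is None:
        return Decision(
            action="none", reason="not-imminent", r=fit.r,
            preset_lead=preset_lead, fit=fit,
        )
    tc, lead = crossing
    if lead < preset_lead:
        return Decision(
            action="initiate", reason="reliable-and-imminent", r=fit.r,
            t_crit=tc, lead_time=lead, preset_lead=preset_lead, fit=fit,
        )
    return Decision(
        action="none", reason="not-imminent", r=fit.r,
        t_crit=tc, lead_time=lead, preset_lead=preset_lead, fit=fit,
    )


# ---------------------------------------------------------------------------
# Condition checks and event resets
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Alert:
    rule: str
    message: str
    value: float
    threshold: float

    def to_dict(self):
        return {
            "rule": self.rule, "message": self.message,
            "value": self.value, "threshold": self.threshold,
        }


def check_conditions(
    limits: SpeciesLimits,
    do_mg_l: Optional[float] = None,
    P: Optional[float] = None,
    F: Optional[float] = None,
    do_surface: Optional[float] = None,
    ph_surface: Optional[float] = None,
    ph_bottom: Optional[float] = None,
    bloom_threshold: float = BLOOM_THRESHOLD,
    fish_danger_threshold: float = FISH_DANGER_THRESHOLD,
) -> list[Alert]:
    """Evaluate all critical-condition rules against estimates/forecasts.

    Emits alerts for: DO at or below the species death level; DO within or
    below the respiratory-depression range; surface DO >= 10 mg/L (unmixed
    water column, stratification risk); algal bloom (P above threshold);
    fish stock in danger (F below threshold); pH outside the species band;
    and surface/bottom pH ratio above the stratification limit.
    """
    alerts = []
    if do_mg_l is not None:
        if do_mg_l <= limits.death_do:
            alerts.append(Alert(
                "fish-death", f"DO {do_mg_l} mg/L at or below {limits.species} "
                f"death level", do_mg_l, limits.death_do))
        elif do_mg_l <= limits.resp_hi:
            alerts.append(Alert(
                "respiratory-depression", f"DO {do_mg_l} mg/L within "
                f"{limits.species} respiratory-depression range", do_mg_l,
                limits.resp_hi))
    if do_surface is not None and do_surface >= SURFACE_DO_STRATIFICATION:
        alerts.append(Alert(
            "stratification-mixing", "surface DO >= 10 mg/L suggests unmixed "
            "water; mixing advised", do_surface, SURFACE_DO_STRATIFICATION))
    if P is not None and P > bloom_threshold:
        alerts.append(Alert(
            "algal-bloom", f"phytoplankton {P} g/m^3 above bloom threshold",
            P, bloom_threshold))
    if F is not None and F < fish_danger_threshold:
        alerts.append(Alert(
            "fish-danger", f"fish biomass {F} g/m^3 below danger threshold",
            F, fish_danger_threshold))
    for label, ph in (("surface", ph_surface), ("bottom", ph_bottom)):
        if ph is not None and not limits.ph_low <= ph <= limits.ph_high:
            alerts.append(Alert(
                "ph-range", f"{label} pH {ph} outside [{limits.ph_low}, "
                f"{limits.ph_high}]", ph, limits.ph_low if ph < limits.ph_low
                else limits.ph_high))
    if ph_surface is not None and ph_bottom is not None and ph_bottom > 0:
        ratio = ph_surface / ph_bottom
        if ratio > limits.ph_ratio_limit:
            alerts.append(Alert(
                "ph-stratification", f"surface/bottom pH ratio {ratio:.3f} "
                f"above {limits.ph_ratio_limit} (fish-kill risk)", ratio,
                limits.ph_ratio_limit))
    return alerts


def reset_on_event(history: Sequence, event_time) -> list:
    """Drop all points recorded before a pond-altering event.

    After chemical treatment, aeration, heavy rain or fish transfer the
    pre-event record no longer predicts the new regime; subsequent fits use
    post-event data only.
    """
    out = []
    for p in history:
        t = p.timestamp if hasattr(p, "timestamp") else (p[0] if not np.isscalar(p) else p)
        if t >= event_time:
            out.append(p)
    return out
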