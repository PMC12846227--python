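"""Empirical links between plankton biomass and indirect observations.

Secchi clarity S and chlorophyll-a concentration Cchl are linear proxies for
the *effective* phytoplankton biomass Peff = P - alpha*Z, the part of the
standing stock "visible" through optics after accounting for grazing by
zooplankton (alpha grams of phytoplankton consumed per gram of zooplankton):

    S    = cS * Peff (+ noise)
    Cchl = kchl * Peff

With Z small this reduces to the classic Cchl = kchl * P proxy.  The linear
model is invertible for Z whenever alpha > 0, which is how sparse
chlorophyll samples constrain the zooplankton state at initialization time.

The coefficients depend on pond morphometry and must be calibrated per
pond; the defaults here are placeholders for simulation work.  The sign and
units of cS are treated as a signed linear coefficient (clarity decreasing
with biomass corresponds to negative cS under a depth-in-metres reading).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

from .errors import ConfigError, NonInvertibleError
from .model import saturation_oxygen

#: Defaults are simulation placeholders, not field calibrations.
DEFAULT_KCHL = 4.0
DEFAULT_ALPHA = 0.3


@dataclass(frozen=True)
class IndirectCoeffs:
    """Calibration of the biomass <-> optics proxy model."""

    cS: float = -0.5      # m per g/m^3 (signed; see module docstring)
    kchl: float = DEFAULT_KCHL   # ug/L chlorophyll-a per g/m^3 phytoplankton
    alpha: float = DEFAULT_ALPHA  # g phytoplankton consumed per g zooplankton
    epsS_std: float = 0.0  # Secchi noise std, m

    def __post_init__(self):
        if self.kchl <= 0:
            raise ConfigError(f"kchl must be positive, got {self.kchl}")
        if self.alpha < 0:
            raise ConfigError(f"alpha must be >= 0, got {self.alpha}")
        if self.epsS_std < 0:
            raise ConfigError(f"epsS_std must be >= 0, got {self.epsS_std}")

    def warn_if_default(self):
        if self.kchl == DEFAULT_KCHL and self.alpha == DEFAULT_ALPHA:
            warnings.warn(
                "IndirectCoeffs uses placeholder defaults; calibrate kchl/alpha per pond",
                stacklevel=2,
            )


def predict_indirect(
    P: float, Z: float, coeffs: IndirectCoeffs, warn: bool = True
) -> tuple[float, float]:
    """Forward proxy model: (Secchi clarity, chlorophyll-a) from P and Z.

    Negative effective biomass (grazing pressure exceeding stock) is floored
    at zero, with a warning unless ``warn`` is disabled -- the proxy model
    is not calibrated in that regime.
    """
    if P < 0 or Z < 0:
        raise ConfigError("biomasses must be nonnegative")
    peff = P - coeffs.alpha * Z
    if peff < 0:
        if warn:
            warnings.warn(
                f"effective biomass P - alpha*Z = {peff:.4g} < 0; floored at 0",
                stacklevel=2,
            )
        peff = 0.0
    return coeffs.cS * peff, coeffs.kchl * peff


def invert_for_Z(Cchl: float, P: float, coeffs: IndirectCoeffs) -> float:
    """Solve the proxy model for zooplankton biomass, clipped to >= 0."""
    if coeffs.alpha == 0:
        raise NonInvertibleError("alpha = 0: chlorophyll carries no zooplankton signal")
    z = (P - Cchl / coeffs.kchl) / coeffs.alpha
    return max(z, 0.0)


def init_state(
    Cchl: float,
    coeffs: IndirectCoeffs,
    defaults,
    T: float = 20.0,
    Osat_base: float = 10.0,
    first_do: Optional[float] = None,
):
    """Build a filter initial state from a chlorophyll sample.

    P0 comes from the chlorophyll proxy; Z0 and F0 from configured defaults
    (e.g. stocking records); O0 from the first DO measurement when present,
    otherwise the temperature-dependent saturation level.
    """
    import numpy as np

    if Cchl < 0:
        raise ConfigError("Cchl must be >= 0")
    if coeffs.kchl <= 0:
        raise ConfigError("kchl must be positive")
    defaults = np.asarray(defaults, dtype=float)
    p0 = Cchl / coeffs.kchl
    o0 = first_do if first_do is not None else saturation_oxygen(T, Osat_base)
    return np.array([p0, defaults[1], defaults[2], o0])
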