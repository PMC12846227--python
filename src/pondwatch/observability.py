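"""Local observability of the P-Z-F-O model from DO-only measurements.

With h(X) = O the only measurement, local observability is assessed by
stacking the gradients of successive Lie derivatives of h along the vector
field f:

    row 0: grad h            = [0, 0, 0, 1]
    row 1: grad L_f h        = [aP - bR, -bR, -bR, -k2]
    row 2: grad L_f^2 h      (nonlinear combinations through P, Z, F dynamics)
    row 3: grad L_f^3 h      (optional)

and computing the numerical rank of the stacked matrix.  Gradients are
generated once by exact symbolic differentiation of the composed dynamics
(finite differences at third order are too noisy for rank decisions); a
finite-difference cross-check of the symbolic rows is available for tests.
Temperature is held fixed during the differentiation: Osat is a constant
with respect to the state, matching a time-frozen analysis.

Fish biomass enters the output only at second order and with small
coefficients, so the ratio of the F-column norm to the P-column norm across
the gradient rows quantifies its weak observability.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass, fields as _dc_fields

import numpy as np
import sympy as sp

from .errors import ConfigError, UndefinedRatioError
from .model import EcosystemParams, saturation_oxygen

_MAX_ORDER = 3

_PARAM_NAMES = [f.name for f in _dc_fields(EcosystemParams) if f.name != "Osat_base"]


@functools.lru_cache(maxsize=1)
def _symbolic_gradients():
    """Lambdified gradient rows of L_f^j h for j = 0..3 (built once)."""
    P, Z, F, O = sp.symbols("P Z F O", real=True)
    osat = sp.Symbol("Osat", real=True)  # constant w.r.t. state
    par = {name: sp.Symbol(name, positive=True) for name in _PARAM_NAMES}
    state = (P, Z, F, O)
    f = sp.Matrix(
        [
            par["rP"] * P * (1 - P / par["K"])
            - par["gZ"] * P * Z / (par["hP"] + P)
            - par["mP"] * P,
            par["eZ"] * par["gZ"] * P * Z / (par["hP"] + P)
            - par["gF"] * Z * F / (par["hZ"] + Z)
            - par["mZ"] * Z,
            par["eF"] * par["gF"] * Z * F / (par["hZ"] + Z) - par["mF"] * F,
            par["aP"] * P - par["bR"] * (P + Z + F) + par["k2"] * (osat - O),
        ]
    )
    h = O
    rows = []
    lie = h
    args = list(state) + [par[n] for n in _PARAM_NAMES] + [osat]
    for _order in range(_MAX_ORDER + 1):
        grad = sp.Matrix([sp.diff(lie, s) for s in state]).T
        rows.append(sp.lambdify(args, grad, modules="numpy"))
        lie = (grad * f)[0, 0]  # next Lie derivative L_f(lie)
    return rows


def _eval_args(x, params: EcosystemParams, T: float):
    x = np.asarray(x, dtype=float)
    osat = saturation_oxygen(T, params.Osat_base)
    return list(x) + [getattr(params, n) for n in _PARAM_NAMES] + [osat]


@dataclass(frozen=True)
class ObservabilityReport:
    """Stacked Lie-gradient rows and their rank analysis at one state."""

    state: np.ndarray
    temperature: float
    gradients: np.ndarray       # (order+1, 4)
    singular_values: np.ndarray  # descending
    rank: int
    f_sensitivity: float        # |F column| / |P column|
    tol: float

    def to_dict(self) -> dict:
        return {
            "state": self.state.tolist(),
            "temperature": self.temperature,
            "gradient_rows": self.gradients.tolist(),
            "singular_values": self.singular_values.tolist(),
            "rank": int(self.rank),
            "f_sensitivity": self.f_sensitivity,
            "tolerance": self.tol,
        }


def lie_gradients(x, params: EcosystemParams, T: float, order: int = 2) -> np.ndarray:
    """Gradient rows of L_f^j h for j = 0..order, evaluated at ``x``."""
    if order not in (1, 2, 3):
        raise ConfigError(f"order must be 1, 2 or 3, got {order}")
    funcs = _symbolic_gradients()
    args = _eval_args(x, params, T)
    return np.vstack([np.asarray(funcs[j](*args), dtype=float) for j in range(order + 1)])


def lie_derivative_value(x, params: EcosystemParams, T: float, order: int) -> float:
    """Scalar L_f^order h at ``x`` (used by finite-difference cross-checks)."""
    from .model import rhs

    if order == 0:
        return float(np.asarray(x, dtype=float)[3])
    grad = lie_gradients(x, params, T, order=min(order, _MAX_ORDER))[order - 1]
    return float(grad @ rhs(x, params, T))


def observability_rank(
    x, params: EcosystemParams, T: float, tol: float = 1e-8, order: int = 3
) -> ObservabilityReport:
    """Numerical rank of the stacked gradient matrix via singular values.

    ``tol`` is relative to the largest singular value.  The report names its
    evaluation point: local observability claims only hold state-by-state.
    """
    if tol <= 0:
        raise ConfigError("tol must be positive")
    G = lie_gradients(x, params, T, order=order)
    sv = np.linalg.svd(G, compute_uv=False)
    rank = int(np.sum(sv > tol * sv[0])) if sv[0] > 0 else 0
    p_norm = np.linalg.norm(G[:, 0])
    f_ratio = float(np.linalg.norm(G[:, 2]) / p_norm) if p_norm > 0 else np.nan
    return ObservabilityReport(
        state=np.asarray(x, dtype=float),
        temperature=float(T),
        gradients=G,
        singular_values=sv,
        rank=rank,
        f_sensitivity=f_ratio,
        tol=tol,
    )


def f_sensitivity(x, params: EcosystemParams, T: float, order: int = 3) -> float:
    """Norm ratio of the F column to the P column of the stacked gradients.

    Below 1 at typical states: fish biomass influences the DO output more
    weakly than phytoplankton does.
    """
    G = lie_gradients(x, params, T, order=order)
    p_norm = np.linalg.norm(G[:, 0])
    if p_norm == 0:
        raise UndefinedRatioError("P column is identically zero at this state")
    return float(np.linalg.norm(G[:, 2]) / p_norm)


def column_ratio(x, params: EcosystemParams, T: float, col: int, ref: int, order: int = 3) -> float:
    """Generic column-norm ratio of the stacked gradient matrix."""
    G = lie_gradients(x, params, T, order=order)
    ref_norm = np.linalg.norm(G[:, ref])
    if ref_norm == 0:
        raise UndefinedRatioError(f"reference column {ref} is zero")
    return float(np.linalg.norm(G[:, col]) / ref_norm)
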