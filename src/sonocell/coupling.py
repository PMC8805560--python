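"""Electromechanical coupling: deflection -> membrane area -> capacitance.

A deflected clamped membrane is longer than a flat one; the arc measure

    A = int_0^d 2 pi sqrt(1 + (du/dx)^2) dx

grows quadratically with deflection amplitude at leading order.  Treating
the bilayer as a dielectric slab between charged surfaces, capacitance is
proportional to area, so the specific capacitance is driven through the
dimensionless ratio ``Cm(t) = Cm0 * A(t)/A(0)`` — insensitive to the 2*pi
line-integral prefactor, which avoids committing to an unstated
three-dimensional geometry.  The absolute parallel-plate value
``eps0 * eps_r * A / L`` is reported alongside for reference.

The neuron model consumes ``Cm(t)`` and its derivative through the
capacitive current ``I_app = Vm * dCm/dt``.  The derivative is estimated by
a Savitzky-Golay local-polynomial filter on the uniform slow-time grid,
which is tolerant of residual carrier leakage in the filtered deflection.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import TYPE_CHECKING
import warnings

import numpy as np
from scipy.constants import epsilon_0
from scipy.integrate import simpson
from scipy.signal import savgol_filter

from .membrane import ParameterError

if TYPE_CHECKING:  # pragma: no cover
    from .membrane import DeflectionTrace

__all__ = [
    "CouplingParams",
    "CapacitanceTrace",
    "membrane_area",
    "area_series",
    "capacitance_trace",
    "capacitive_current",
]


@dataclass(frozen=True)
class CouplingParams:
    """Bilayer dielectric parameters.

    L      : bilayer thickness [m]; physiological band 4-9 nm (warned if outside)
    eps_r  : relative permittivity of the bilayer (dimensionless)
    Cm0    : baseline specific capacitance [uF/cm^2]
    """

    L: float = 5.0e-9
    eps_r: float = 2.0
    Cm0: float = 1.0

    def __post_init__(self) -> None:
        if self.L <= 0 or self.eps_r <= 0 or self.Cm0 <= 0:
            raise ParameterError("L, eps_r and Cm0 must be strictly positive")
        if not (4.0e-9 <= self.L <= 9.0e-9):
            warnings.warn(
                f"bilayer thickness L={self.L:g} m is outside the 4-9 nm "
                "physiological band",
                RuntimeWarning,
            )


def membrane_area(x, u) -> float:
    """Arc measure A = int 2 pi sqrt(1 + u_x^2) dx of one displacement profile.

    ``u_x`` is taken by central differences; for a flat profile the result
    is exactly 2 pi d.
    """
    x = np.asarray(x, dtype=float)
    u = np.asarray(u, dtype=float)
    if x.size < 3:
        raise ParameterError("membrane_area requires at least 3 grid points")
    ux = np.gradient(u, x)
    return float(simpson(2.0 * np.pi * np.sqrt(1.0 + ux * ux), x=x))


def area_series(x, u_field) -> np.ndarray:
    """Arc measure per time column of a (nx, nt) displacement field."""
    x = np.asarray(x, dtype=float)
    u = np.asarray(u_field, dtype=float)
    if x.size < 3:
        raise ParameterError("area_series requires at least 3 grid points")
    ux = np.gradient(u, x, axis=0)
    return simpson(2.0 * np.pi * np.sqrt(1.0 + ux * ux), x=x, axis=0)


@dataclass
class CapacitanceTrace:
    """Slow-time membrane area and capacitance with derivative.

    t_s     : times [s]
    A       : arc measure [m * rad]
    A_rel   : A(t)/A(0), >= 1 (a deflected clamped membrane is never shorter
              than flat)
    Cm      : specific capacitance Cm0 * A_rel [uF/cm^2]
    dCm_dt  : Savitzky-Golay derivative [uF cm^-2 ms^-1]
    C_abs_per_length : parallel-plate value eps0*eps_r*A/L [F/m], reference only
    """

    t_s: np.ndarray
    A: np.ndarray
    A_rel: np.ndarray
    Cm: np.ndarray
    dCm_dt: np.ndarray
    C_abs_per_length: np.ndarray
    meta: dict = field(default_factory=dict)

    @property
    def t_ms(self) -> np.ndarray:
        return self.t_s * 1.0e3


def capacitance_trace(
    trace: "DeflectionTrace",
    params: CouplingParams,
    *,
    savgol_window: int = 7,
    savgol_order: int = 3,
) -> CapacitanceTrace:
    """Convert a slow-time deflection field into a capacitance drive.

    The field in ``trace.u`` is expected to already be the slow-time
    (carrier-free) displacement; the capacitance follows the area ratio,
    Cm(t) = Cm0 * A(t)/A(0) with A(0) the flat reference 2 pi d.
    """
    t = np.asarray(trace.t_grid, dtype=float)
    if t.size < savgol_window:
        raise ParameterError("time grid shorter than the derivative window")
    dts = np.diff(t)
    if np.any(dts <= 0):
        raise ParameterError("time grid must be strictly increasing")
    if not np.allclose(dts, dts[0], rtol=1.0e-6):
        raise ParameterError("capacitance_trace requires a uniform time grid")
    dt_ms = float(dts[0]) * 1.0e3

    A = area_series(trace.x_grid, trace.u)
    d = float(trace.x_grid[-1] - trace.x_grid[0])
    A0 = 2.0 * np.pi * d
    A_rel = A / A0
    Cm = params.Cm0 * A_rel
    dCm_dt = savgol_filter(Cm, window_length=savgol_window, polyorder=savgol_order,
                           deriv=1, delta=dt_ms)
    C_abs = epsilon_0 * params.eps_r * A / params.L
    return CapacitanceTrace(
        t_s=t, A=A, A_rel=A_rel, Cm=Cm, dCm_dt=dCm_dt, C_abs_per_length=C_abs,
        meta={
            "Cm0": params.Cm0, "L": params.L, "eps_r": params.eps_r,
            "savgol_window": savgol_window, "savgol_order": savgol_order,
            "A0": A0,
        },
    )


def capacitive_current(Vm_mV, dCm_dt):
    """I_app = Vm * dCm/dt [uA/cm^2] (mV * uF cm^-2 ms^-1)."""
    return np.asarray(Vm_mV) * np.asarray(dCm_dt)
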