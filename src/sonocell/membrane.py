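"""Clamped, viscously damped membrane under sinusoidal ultrasound forcing.

The membrane section between two anchor points (adhesion zones) of length
``d`` is modelled as a one-dimensional interface clamped at both ends,
immersed in a viscous fluid and restored by surface tension.  Its vertical
displacement ``u(x, t)`` obeys a damped wave equation

    d2u/dt2 = c1 * d3u/dx2dt + c0 * d2u/dx2 + f(t)

with ``c1 = 2 eta / rho`` (viscous damping), ``c0 = 2 pi gamma / (rho d)``
(surface-tension restoring) and a spatially uniform forcing
``f(t) = g(d) * P_US(t) / rho`` driven by the incident ultrasound pressure
``P_US(t) = P0 sin(omega (t - t_on))`` gated over the burst window.  The
prefactor ``g(d)`` is configurable (``geometry_factor``); the default
``pi/d`` is the reading consistent with both the modal stiffness above and
a pressure gradient's units.

The equation is solved by eigenfunction expansion on the sine basis
``phi_n(x) = sin(n pi x / d)``.  Each odd mode obeys a damped harmonic
oscillator ODE whose response to the gated sinusoid is evaluated in closed
form (no time stepping of the MHz carrier), so the field can be sampled at
arbitrary times cheaply.  Even modes receive no net forcing and vanish.

Unforced modes ring only when viscous damping is weak relative to
inertio-capillary effects, quantified by the Ohnesorge number
``Oh = eta / sqrt(rho gamma d)``; the fundamental mode oscillates iff
``Oh < sqrt(2/pi) ~= 0.798``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
from scipy import signal
from scipy.optimize import brentq

__all__ = [
    "MembraneParams",
    "UltrasoundBurst",
    "ModalSolution",
    "DeflectionTrace",
    "OhnesorgeReport",
    "SweepResult",
    "ParameterError",
    "DegenerateModeError",
    "modal_coefficients",
    "forcing_projection",
    "mode_response",
    "reconstruct_deflection",
    "slow_time_envelope",
    "lowpass",
    "ohnesorge_number",
    "critical_ohnesorge",
    "peak_center_deflection",
    "sweep_peak_deflection",
    "mechanical_index",
    "odd_modes",
]

CRITICAL_OH_CLOSED_FORM = float(np.sqrt(2.0 / np.pi))


class ParameterError(ValueError):
    """A physical parameter is outside its admissible range."""


class DegenerateModeError(RuntimeError):
    """The modal characteristic roots coincide (critically damped mode)."""


# --------------------------------------------------------------------------
# parameter containers


@dataclass(frozen=True)
class MembraneParams:
    """Physical parameters of the membrane-fluid system (SI units).

    d      : anchor length between adhesion points [m]
    gamma  : surface tension of the membrane-media interface [N/m]
    rho    : density of the surrounding fluid [kg/m^3] (water default)
    eta    : dynamic viscosity of the surrounding fluid [Pa s] (water default)
    """

    d: float
    gamma: float
    rho: float = 1000.0
    eta: float = 1.0e-3

    def __post_init__(self) -> None:
        for name in ("d", "gamma", "rho", "eta"):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise ParameterError(f"{name} must be strictly positive, got {v!r}")

    @property
    def c1(self) -> float:
        """Viscous damping coefficient 2*eta/rho [m^2/s]."""
        return 2.0 * self.eta / self.rho

    @property
    def c0(self) -> float:
        """Surface-tension restoring coefficient 2*pi*gamma/(rho*d) [m^2/s^2]."""
        return 2.0 * np.pi * self.gamma / (self.rho * self.d)


@dataclass(frozen=True)
class UltrasoundBurst:
    """Gated sinusoidal pressure stimulus.

    P0    : peak pressure amplitude [Pa]
    f     : carrier frequency [Hz]
    t_on  : burst start [s]
    t_dur : burst duration [s]
    """

    P0: float
    f: float
    t_on: float = 0.0
    t_dur: float = 5.0e-3

    def __post_init__(self) -> None:
        if self.P0 < 0:
            raise ParameterError(f"P0 must be >= 0, got {self.P0!r}")
        if self.f <= 0:
            raise ParameterError(f"f must be > 0, got {self.f!r}")
        if self.t_dur <= 0:
            raise ParameterError(f"t_dur must be > 0, got {self.t_dur!r}")
        if self.t_on < 0:
            raise ParameterError(f"t_on must be >= 0, got {self.t_on!r}")

    @property
    def omega(self) -> float:
        """Angular carrier frequency 2*pi*f [rad/s]."""
        return 2.0 * np.pi * self.f

    @property
    def t_off(self) -> float:
        return self.t_on + self.t_dur

    def pressure(self, t):
        """P_US(t) = P0 sin(omega (t - t_on)) inside the burst window, else 0."""
        t = np.asarray(t, dtype=float)
        s = t - self.t_on
        on = (s >= 0.0) & (s <= self.t_dur)
        return np.where(on, self.P0 * np.sin(self.omega * s), 0.0)


def _geometry_factor(name: str, d: float) -> float:
    if name == "pi_over_d":
        return np.pi / d
    if name == "pi_d":
        return np.pi * d
    if name == "unity":
        return 1.0
    raise ParameterError(
        f"unknown geometry_factor {name!r}; expected 'pi_over_d', 'pi_d' or 'unity'"
    )


def odd_modes(n_modes: int) -> np.ndarray:
    """The first ``n_modes`` odd mode indices 1, 3, 5, ..."""
    if n_modes < 1:
        raise ParameterError("n_modes must be >= 1")
    return np.arange(1, 2 * n_modes, 2)


# --------------------------------------------------------------------------
# modal solution


@dataclass(frozen=True)
class ModalSolution:
    """Coefficients of the n-th modal oscillator h'' + b1 h' + b0 h = f_n(t).

    Characteristic roots r_pm = (-b1 +/- sqrt(b1^2 - 4 b0)) / 2 are complex
    conjugates when the mode is oscillatory.  ``a_plus_h``/``a_minus_h`` are
    the homogeneous coefficients for initial amplitude ``h0`` and zero
    initial velocity.
    """

    n: int
    k_n: float
    chi_n: float
    b1_n: float
    b0_n: float
    r_plus: complex
    r_minus: complex
    a_plus_h: complex
    a_minus_h: complex
    h0: float
    params: MembraneParams

    @property
    def discriminant(self) -> float:
        return self.b1_n**2 - 4.0 * self.b0_n

    @property
    def is_oscillatory(self) -> bool:
        return self.discriminant < 0.0

    @property
    def ring_frequency(self) -> float:
        """Frequency of the decaying free oscillation [Hz] (0 if overdamped)."""
        return abs(self.r_plus.imag) / (2.0 * np.pi)


def modal_coefficients(params: MembraneParams, n: int, h0: float = 0.0) -> ModalSolution:
    """Build the modal oscillator for odd mode ``n``.

    Raises ``ParameterError`` for even or non-positive ``n`` (even modes
    receive no forcing from a uniform pressure and vanish identically).
    """
    if n < 1 or n % 2 == 0:
        raise ParameterError(f"mode index must be odd and >= 1, got {n}")
    k = n * np.pi / params.d
    chi = k * k
    b1 = params.c1 * chi
    b0 = params.c0 * chi
    disc = b1 * b1 - 4.0 * b0
    sq = np.sqrt(complex(disc))
    r_plus = (-b1 + sq) / 2.0
    r_minus = (-b1 - sq) / 2.0
    if r_plus == r_minus:
        # critically damped double root; representable, but mode_response
        # refuses to evaluate it (degenerate two-exponential basis)
        a_plus, a_minus = complex(h0), 0.0 + 0.0j
    else:
        a_plus = r_minus / (r_minus - r_plus) * h0
        a_minus = r_plus / (r_plus - r_minus) * h0
    return ModalSolution(
        n=n, k_n=k, chi_n=chi, b1_n=b1, b0_n=b0,
        r_plus=complex(r_plus), r_minus=complex(r_minus),
        a_plus_h=complex(a_plus), a_minus_h=complex(a_minus),
        h0=float(h0), params=params,
    )


def forcing_projection(
    burst: UltrasoundBurst,
    params: MembraneParams,
    n: int,
    t,
    geometry_factor: str = "pi_over_d",
):
    """Modal forcing f_n(t) = 2(1-(-1)^n)/(n pi) * g(d) * P_US(t) / rho.

    Zero for even modes (sine-basis projection of a uniform load vanishes).
    """
    if n < 1:
        raise ParameterError(f"mode index must be >= 1, got {n}")
    t = np.asarray(t, dtype=float)
    if n % 2 == 0:
        return np.zeros_like(t)
    g = _geometry_factor(geometry_factor, params.d)
    coef = (2.0 * (1.0 - (-1.0) ** n) / (n * np.pi)) * g / params.rho
    return coef * burst.pressure(t)


def _forcing_amplitude(sol: ModalSolution, burst: UltrasoundBurst, geometry_factor: str) -> float:
    g = _geometry_factor(geometry_factor, sol.params.d)
    return (4.0 / (sol.n * np.pi)) * g * burst.P0 / sol.params.rho


def _free_coeffs(h0: complex, v0: complex, rp: complex, rm: complex):
    """Two-exponential coefficients for free decay from state (h0, v0)."""
    bp = (v0 - rm * h0) / (rp - rm)
    return bp, h0 - bp


def _eval_free(h0, v0, rp, rm, s):
    bp, bm = _free_coeffs(h0, v0, rp, rm)
    ep, em = np.exp(rp * s), np.exp(rm * s)
    return bp * ep + bm * em, bp * rp * ep + bm * rm * em


def mode_response(
    sol: ModalSolution,
    burst: UltrasoundBurst,
    h0: float | None = None,
    t_grid=None,
    *,
    geometry_factor: str = "pi_over_d",
    component: str = "full",
    return_velocity: bool = False,
):
    """Closed-form modal time series h_n(t) for the gated sinusoidal burst.

    The response is assembled piecewise: free decay of the initial amplitude
    before the burst, particular (carrier-frequency) solution plus matched
    homogeneous correction during the burst, and free decay of the burst-end
    state afterwards.  ``component`` selects ``"full"``, the ``"carrier"``
    part (the steady sinusoid at the drive frequency, zero outside the
    burst), or the ``"transient"`` remainder — the slowly ringing content
    that survives low-pass filtering.

    Raises ``DegenerateModeError`` for coincident characteristic roots.
    """
    if sol.r_plus == sol.r_minus:
        raise DegenerateModeError(
            f"mode n={sol.n}: characteristic roots coincide at r={sol.r_plus}; "
            "the two-exponential closed form is undefined at exact critical damping"
        )
    if component not in ("full", "carrier", "transient"):
        raise ParameterError(f"unknown component {component!r}")
    if h0 is None:
        h0 = sol.h0
    t = np.atleast_1d(np.asarray(t_grid, dtype=float))
    rp, rm = sol.r_plus, sol.r_minus
    w = burst.omega
    F = _forcing_amplitude(sol, burst, geometry_factor)
    H = F / (sol.b0_n - w * w + 1j * sol.b1_n * w)
    hp0, vp0 = H.imag, w * H.real  # particular solution state at burst onset

    h = np.zeros(t.shape, dtype=complex)
    v = np.zeros(t.shape, dtype=complex)
    carrier = np.zeros(t.shape, dtype=complex)
    carrier_v = np.zeros(t.shape, dtype=complex)

    # state at burst onset from free decay of the initial amplitude
    if burst.t_on > 0.0:
        h_on, v_on = _eval_free(complex(h0), 0.0 + 0j, rp, rm, burst.t_on)
    else:
        h_on, v_on = complex(h0), 0.0 + 0j

    pre = t < burst.t_on
    if np.any(pre):
        h[pre], v[pre] = _eval_free(complex(h0), 0.0 + 0j, rp, rm, t[pre])

    during = (t >= burst.t_on) & (t <= burst.t_off)
    if np.any(during):
        s = t[during] - burst.t_on
        e = np.exp(1j * w * s)
        carrier[during] = (H * e).imag
        carrier_v[during] = (1j * w * H * e).imag
        hh, vv = _eval_free(h_on - hp0, v_on - vp0, rp, rm, s)
        h[during] = carrier[during] + hh
        v[during] = carrier_v[during] + vv

    post = t > burst.t_off
    if np.any(post) or True:
        # burst-end state (needed for post-window free decay)
        T = burst.t_dur
        eT = np.exp(1j * w * T)
        hcT, vcT = (H * eT).imag, (1j * w * H * eT).imag
        hhT, vvT = _eval_free(h_on - hp0, v_on - vp0, rp, rm, T)
        hT, vT = hcT + hhT, vcT + vvT
    if np.any(post):
        h[post], v[post] = _eval_free(hT, vT, rp, rm, t[post] - burst.t_off)

    if component == "carrier":
        out_h, out_v = carrier, carrier_v
    elif component == "transient":
        out_h, out_v = h - carrier, v - carrier_v
    else:
        out_h, out_v = h, v

    scale = max(np.max(np.abs(out_h)), 1.0e-300)
    if np.max(np.abs(out_h.imag)) > 1.0e-9 * scale:
        raise RuntimeError(f"mode n={sol.n}: response has non-negligible imaginary part")
    if return_velocity:
        return out_h.real, out_v.real
    return out_h.real


# --------------------------------------------------------------------------
# field reconstruction


@dataclass
class DeflectionTrace:
    """Space-time displacement field of the membrane section.

    ``u`` is indexed position x time [m]; ``u_center`` is the midpoint
    series; ``u_center_slow`` is filled by :func:`slow_time_envelope`.
    """

    x_grid: np.ndarray
    t_grid: np.ndarray
    u: np.ndarray
    u_center: np.ndarray
    u_center_slow: np.ndarray | None = None
    meta: dict = field(default_factory=dict)


def _hydrostatic_modal_amplitudes(ns: np.ndarray, params: MembraneParams, P0_static: float) -> np.ndarray:
    # sine coefficients of u0(x) = P0 x (d - x) / (4 gamma)
    return (P0_static / (4.0 * params.gamma)) * 8.0 * params.d**2 / (ns.astype(float) ** 3 * np.pi**3)


def reconstruct_deflection(
    params: MembraneParams,
    burst: UltrasoundBurst,
    t_grid,
    x_grid=None,
    n_modes: int = 101,
    *,
    geometry_factor: str = "pi_over_d",
    hydrostatic_P0: float | None = None,
    component: str = "full",
    convergence_check: bool = True,
) -> DeflectionTrace:
    """Sum the odd-mode closed forms into u(x, t) = sum_n h_n(t) sin(n pi x / d).

    Clamped boundary values are exactly zero by construction.  If
    ``hydrostatic_P0`` is given, the modes start from the parabolic static
    profile u0 = P0 x(d-x)/(4 gamma); the default is start-from-rest.
    A convergence warning is emitted if halving the mode count moves the
    peak midpoint deflection by more than 1%.
    """
    t = np.atleast_1d(np.asarray(t_grid, dtype=float))
    if x_grid is None:
        x_grid = np.linspace(0.0, params.d, 201)
    x = np.asarray(x_grid, dtype=float)

    ns = odd_modes(n_modes)
    if hydrostatic_P0 is not None:
        h0s = _hydrostatic_modal_amplitudes(ns, params, hydrostatic_P0)
    else:
        h0s = np.zeros(ns.shape)

    H = np.empty((ns.size, t.size))
    for i, n in enumerate(ns):
        sol = modal_coefficients(params, int(n), h0=float(h0s[i]))
        H[i] = mode_response(sol, burst, t_grid=t, geometry_factor=geometry_factor,
                             component=component)

    k = ns[:, None] * np.pi / params.d
    S = np.sin(k * x[None, :])          # (n_modes, nx)
    S[:, np.isclose(x, 0.0)] = 0.0
    S[:, np.isclose(x, params.d)] = 0.0
    u = S.T @ H                          # (nx, nt)
    center_signs = np.sin(ns * np.pi / 2.0)  # (-1)^k for n = 2k+1
    u_center = center_signs @ H

    meta = {
        "n_modes": n_modes,
        "geometry_factor": geometry_factor,
        "burst": burst,
        "params": params,
        "component": component,
    }
    if convergence_check and n_modes >= 2:
        half = center_signs[: n_modes // 2] @ H[: n_modes // 2]
        peak = np.max(np.abs(u_center))
        if peak > 0:
            rel = abs(np.max(np.abs(half)) - peak) / peak
            meta["truncation_rel_change"] = rel
            if rel > 0.01:
                warnings.warn(
                    f"mode truncation not converged: halving modes changes peak "
                    f"midpoint deflection by {rel:.1%}",
                    RuntimeWarning,
                )
    return DeflectionTrace(x_grid=x, t_grid=t, u=u, u_center=u_center, meta=meta)


# --------------------------------------------------------------------------
# slow-time filtering


def lowpass(y, dt: float, cutoff: float, order: int = 4):
    """Zero-phase Butterworth low-pass along the last axis of ``y``."""
    nyq = 0.5 / dt
    if cutoff >= nyq:
        raise ParameterError(f"cutoff {cutoff:g} Hz is at or above Nyquist {nyq:g} Hz")
    sos = signal.butter(order, cutoff / nyq, btype="low", output="sos")
    return signal.sosfiltfilt(sos, y, axis=-1)


def slow_time_envelope(trace: DeflectionTrace, cutoff: float = 1.0e5) -> np.ndarray:
    """Low-pass the midpoint displacement to expose the slow-time response.

    ``cutoff`` must sit well below the carrier (enforced: < carrier/2).
    The filtered series is stored on the trace (``u_center_slow``) and the
    cutoff recorded in its metadata.
    """
    burst: UltrasoundBurst | None = trace.meta.get("burst")
    if burst is not None and cutoff >= burst.f / 2.0:
        raise ParameterError(
            f"cutoff {cutoff:g} Hz must be below half the carrier {burst.f:g} Hz"
        )
    t = trace.t_grid
    dts = np.diff(t)
    if t.size < 2 or not np.allclose(dts, dts[0], rtol=1.0e-6):
        raise ParameterError("slow_time_envelope requires a uniform time grid")
    filtered = lowpass(trace.u_center, float(dts[0]), cutoff)
    trace.u_center_slow = filtered
    trace.meta["slow_cutoff_hz"] = cutoff
    return filtered


# --------------------------------------------------------------------------
# oscillation criterion


@dataclass(frozen=True)
class OhnesorgeReport:
    """Ohnesorge number, oscillatory odd-mode count, and critical threshold."""

    Oh: float
    n_oscillatory: int
    critical_Oh: float


def critical_ohnesorge(params: MembraneParams | None = None) -> float:
    """Oh at which the fundamental mode's discriminant vanishes.

    Found by a numeric sign-change search on the discriminant as a function
    of Oh (holding rho, gamma, d fixed and scaling eta); the result is the
    parameter-independent constant sqrt(2/pi) ~= 0.798.
    """
    if params is None:
        params = MembraneParams(d=10.0e-6, gamma=1.0e-3)

    def disc(oh: float) -> float:
        eta = oh * np.sqrt(params.rho * params.gamma * params.d)
        p = replace(params, eta=eta)
        sol = modal_coefficients(p, 1)
        # normalize to keep brentq well-scaled
        return sol.discriminant / (4.0 * sol.b0_n)

    return float(brentq(disc, 1.0e-4, 1.0e2, xtol=1.0e-12, rtol=1.0e-14))


def ohnesorge_number(params: MembraneParams) -> OhnesorgeReport:
    """Oh = eta / sqrt(rho gamma d) and the count of oscillatory odd modes.

    A mode is oscillatory when its discriminant b1^2 - 4 b0 < 0; the
    discriminant grows monotonically with mode number, so the count is the
    run of low odd modes below the sign change.
    """
    oh = params.eta / np.sqrt(params.rho * params.gamma * params.d)
    count = 0
    n = 1
    while True:
        sol = modal_coefficients(params, n)
        if sol.discriminant >= 0.0:
            break
        count += 1
        n += 2
    return OhnesorgeReport(Oh=float(oh), n_oscillatory=count,
                           critical_Oh=critical_ohnesorge(params))


# --------------------------------------------------------------------------
# derived quantities


def peak_center_deflection(
    params: MembraneParams,
    burst: UltrasoundBurst,
    n_modes: int = 101,
    geometry_factor: str = "pi_over_d",
) -> float:
    """Peak |u(d/2, t)| over the burst window [m].

    The midpoint series is the sum of a steady carrier phasor (amplitude
    known analytically) and decaying transients excited at burst onset; the
    transient window is sampled at carrier resolution and the maximum taken
    against the analytic steady amplitude.
    """
    if burst.P0 == 0.0:
        return 0.0
    ns = odd_modes(n_modes)
    w = burst.omega
    sols = [modal_coefficients(params, int(n)) for n in ns]
    signs = np.sin(ns * np.pi / 2.0)
    M = 0.0 + 0.0j
    for sgn, sol in zip(signs, sols):
        F = _forcing_amplitude(sol, burst, geometry_factor)
        M += sgn * F / (sol.b0_n - w * w + 1j * sol.b1_n * w)
    steady_amp = abs(M)

    slowest_decay = min(-sol.r_plus.real for sol in sols)
    t_win = min(burst.t_dur, max(12.0 / slowest_decay, 10.0 / burst.f))
    dt = 1.0 / (16.0 * burst.f)
    nt = min(int(np.ceil(t_win / dt)) + 1, 2_000_000)
    s = burst.t_on + np.linspace(0.0, t_win, nt)
    u = np.zeros(nt)
    for sgn, sol in zip(signs, sols):
        u += sgn * mode_response(sol, burst, t_grid=s, geometry_factor=geometry_factor)
    return float(max(np.max(np.abs(u)), steady_amp))


@dataclass
class SweepResult:
    """Peak midpoint deflection over a (d, gamma) grid."""

    d_values: np.ndarray
    gamma_values: np.ndarray
    peak: np.ndarray  # (len(d), len(gamma)) [m]
    burst: UltrasoundBurst
    meta: dict = field(default_factory=dict)

    def to_dataframe(self):
        import pandas as pd

        rows = [
            {"d_um": d * 1e6, "gamma_mN_m": g * 1e3,
             "peak_deflection_nm": self.peak[i, j] * 1e9}
            for i, d in enumerate(self.d_values)
            for j, g in enumerate(self.gamma_values)
        ]
        return pd.DataFrame(rows)


def sweep_peak_deflection(
    d_range: Sequence[float],
    gamma_range: Sequence[float],
    burst: UltrasoundBurst,
    n_points: tuple[int, int] = (10, 10),
    *,
    rho: float = 1000.0,
    eta: float = 1.0e-3,
    n_modes: int = 101,
    geometry_factor: str = "pi_over_d",
) -> SweepResult:
    """Peak midpoint deflection on a grid of anchor length and surface tension."""
    nd, ng = n_points
    if nd < 2 or ng < 2:
        raise ParameterError("sweep grid must be at least 2x2")
    d_values = np.linspace(float(d_range[0]), float(d_range[-1]), nd)
    gamma_values = np.linspace(float(gamma_range[0]), float(gamma_range[-1]), ng)
    peak = np.empty((nd, ng))
    for i, d in enumerate(d_values):
        for j, g in enumerate(gamma_values):
            try:
                p = MembraneParams(d=float(d), gamma=float(g), rho=rho, eta=eta)
                peak[i, j] = peak_center_deflection(
                    p, burst, n_modes=n_modes, geometry_factor=geometry_factor
                )
            except Exception as exc:  # attach grid coordinates, then propagate
                raise RuntimeError(
                    f"sweep cell (d={d:.3g} m, gamma={g:.3g} N/m) failed: {exc}"
                ) from exc
    meta = {"rho": rho, "eta": eta, "n_modes": n_modes,
            "geometry_factor": geometry_factor}
    return SweepResult(d_values=d_values, gamma_values=gamma_values, peak=peak,
                       burst=burst, meta=meta)


def mechanical_index(p0_mpa: float, f_mhz: float) -> float:
    """MI = peak pressure [MPa] / sqrt(frequency [MHz])."""
    if f_mhz <= 0:
        raise ParameterError(f"frequency must be positive, got {f_mhz!r}")
    if p0_mpa < 0:
        raise ParameterError(f"pressure must be non-negative, got {p0_mpa!r}")
    return p0_mpa / np.sqrt(f_mhz)
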