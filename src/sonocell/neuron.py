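"""Modified Hodgkin-Huxley neuron driven by a time-varying capacitance.

The conductance set is a regular-spiking cortical variant: a transient Na+
current (gating m, h), a delayed-rectifier K+ current (n), a slow
non-inactivating K+ current (p) that produces spike-frequency adaptation,
and an ohmic leak:

    dVm/dt = -(1/Cm) * (I_app + I_Na + I_Kd + I_M + I_leak)

Units are mV, ms, mS/cm^2, uF/cm^2 and uA/cm^2 throughout.  Mechanical
drive enters through the capacitive current ``I_app = Vm * dCm/dt``: an
area-driven rise in membrane capacitance at fixed charge depolarizes the
cell.  A conventional injected current (positive = depolarizing) is also
supported; with constant Cm and no injection the system is the standard
conductance model and sits at its resting point (-71.9 mV for the default
parameter set).

Rate functions follow the printed forms with removable 0/0 singularities
(e.g. alpha_m at Vm = Vth + 13 mV) replaced by their analytic limits.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import NamedTuple

import numpy as np
from scipy.integrate import solve_ivp
from scipy.interpolate import PchipInterpolator
from scipy.optimize import brentq

from .coupling import CapacitanceTrace
from .membrane import ParameterError

__all__ = [
    "HHParams",
    "HHState",
    "GatingRates",
    "VoltageTrace",
    "SpikeSummary",
    "Drive",
    "ConstantCurrentDrive",
    "CapacitanceDrive",
    "gating_rates",
    "gating_steady",
    "steady_state",
    "integrate",
    "detect_spikes",
]


@dataclass(frozen=True)
class HHParams:
    """Conductances [mS/cm^2], reversal potentials [mV], kinetics constants.

    Defaults are the regular-spiking cortical set: gNa 56, gKd 6, gM 0.075,
    gLeak 0.0205 mS/cm^2; ENa 50, EK -90, ELeak -70.3 mV; Vth -56.2 mV;
    tau_max 608 ms; baseline capacitance Cm0 1 uF/cm^2.
    """

    gNa_bar: float = 56.0
    ENa: float = 50.0
    Vth: float = -56.2
    gKd_bar: float = 6.0
    EK: float = -90.0
    gM_bar: float = 0.075
    tau_max: float = 608.0
    gLeak_bar: float = 0.0205
    ELeak: float = -70.3
    Cm0: float = 1.0

    def __post_init__(self) -> None:
        for name in ("gNa_bar", "gKd_bar", "gM_bar", "gLeak_bar", "Cm0"):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be >= 0")
        if self.Cm0 <= 0:
            raise ParameterError("Cm0 must be > 0")
        for name in ("ENa", "EK", "ELeak", "Vth"):
            if not np.isfinite(getattr(self, name)):
                raise ParameterError(f"{name} must be finite")
        if self.tau_max <= 0:
            raise ParameterError("tau_max must be > 0")


@dataclass
class HHState:
    """Membrane potential [mV] and gating variables (each in [0, 1])."""

    Vm: float
    m: float
    h: float
    n: float
    p: float

    def as_array(self) -> np.ndarray:
        return np.array([self.Vm, self.m, self.h, self.n, self.p], dtype=float)


class GatingRates(NamedTuple):
    alpha_m: float
    beta_m: float
    alpha_h: float
    beta_h: float
    alpha_n: float
    beta_n: float
    p_inf: float
    tau_p: float


def _vtrap(x, k):
    """x / (1 - exp(-x/k)) with the analytic limit k at x -> 0."""
    x = np.asarray(x, dtype=float)
    small = np.abs(x) < 1.0e-7
    safe = np.where(small, 1.0, x)
    out = np.where(small, k + x / 2.0, safe / (-np.expm1(-safe / k)))
    return out


def gating_rates(Vm, params: HHParams = HHParams()) -> GatingRates:
    """Voltage-dependent rate constants [1/ms] and the slow-K+ pair (p_inf, tau_p).

    Removable singularities of the ratio forms (alpha_m at Vth+13, beta_m at
    Vth+40, alpha_n at Vth+15) are evaluated by their limits.
    """
    V = np.asarray(Vm, dtype=float)
    if not np.all(np.isfinite(V)):
        raise ParameterError("Vm must be finite")
    u = V - params.Vth
    alpha_m = 0.32 * _vtrap(u - 13.0, 4.0)
    beta_m = 0.28 * _vtrap(-(u - 40.0), 5.0)
    alpha_h = 0.128 * np.exp(-(u - 17.0) / 18.0)
    beta_h = 4.0 / (1.0 + np.exp(-(u - 40.0) / 5.0))
    alpha_n = 0.032 * _vtrap(u - 15.0, 5.0)
    beta_n = 0.5 * np.exp(-(u - 10.0) / 40.0)
    p_inf = 1.0 / (1.0 + np.exp(-(V + 35.0) / 10.0))
    tau_p = params.tau_max / (
        3.3 * np.exp((V + 35.0) / 20.0) + np.exp(-(V + 35.0) / 20.0)
    )
    return GatingRates(alpha_m, beta_m, alpha_h, beta_h, alpha_n, beta_n, p_inf, tau_p)


def gating_steady(Vm, params: HHParams = HHParams()):
    """Gating fixed points m0, h0, n0, p0 at a given voltage."""
    r = gating_rates(Vm, params)
    return (
        r.alpha_m / (r.alpha_m + r.beta_m),
        r.alpha_h / (r.alpha_h + r.beta_h),
        r.alpha_n / (r.alpha_n + r.beta_n),
        r.p_inf,
    )


def _ionic_current(V, m, h, n, p, params: HHParams):
    INa = params.gNa_bar * m**3 * h * (V - params.ENa)
    IKd = params.gKd_bar * n**4 * (V - params.EK)
    IM = params.gM_bar * p * (V - params.EK)
    IL = params.gLeak_bar * (V - params.ELeak)
    return INa + IKd + IM + IL


def steady_state(params: HHParams = HHParams(), v_window=(-100.0, 0.0)) -> HHState:
    """Resting state: root of the total ionic current with gating at its
    voltage-dependent fixed points.

    The most hyperpolarized root inside ``v_window`` is returned (the rest
    point).  Raises if no sign change exists in the window, which signals
    corrupted parameters.
    """

    def total(V):
        m, h, n, p = gating_steady(V, params)
        return _ionic_current(V, m, h, n, p, params)

    lo, hi = v_window
    grid = np.linspace(lo, hi, 401)
    vals = np.array([total(v) for v in grid])
    sign_change = np.nonzero(np.diff(np.sign(vals)) != 0)[0]
    if sign_change.size == 0:
        raise ParameterError(
            f"no resting potential in [{lo}, {hi}] mV: total ionic current has "
            "no zero crossing (check conductances and reversal potentials)"
        )
    i = sign_change[0]
    V_rest = brentq(total, grid[i], grid[i + 1], xtol=1.0e-10)
    m, h, n, p = gating_steady(V_rest, params)
    return HHState(Vm=float(V_rest), m=float(m), h=float(h), n=float(n), p=float(p))


# --------------------------------------------------------------------------
# drives


class Drive:
    """Interface: capacitance [uF/cm^2], its derivative [uF cm^-2 ms^-1] and
    injected current [uA/cm^2] as functions of time in ms."""

    def capacitance(self, t_ms: float) -> float:
        raise NotImplementedError

    def dcm_dt(self, t_ms: float) -> float:
        raise NotImplementedError

    def injected_current(self, t_ms: float) -> float:
        return 0.0

    def covers(self, t0_ms: float, t1_ms: float) -> bool:
        return True

    #: hint for the integrator's max step [ms]; None = no constraint
    max_step_ms: float | None = None


@dataclass
class ConstantCurrentDrive(Drive):
    """Constant injected current step (positive = depolarizing) with fixed Cm."""

    amplitude: float  # uA/cm^2
    t_on_ms: float = 0.0
    t_dur_ms: float = float("inf")
    Cm0: float = 1.0
    max_step_ms: float | None = None

    def capacitance(self, t_ms):
        return self.Cm0

    def dcm_dt(self, t_ms):
        return 0.0

    def injected_current(self, t_ms):
        on = (t_ms >= self.t_on_ms) & (t_ms <= self.t_on_ms + self.t_dur_ms)
        return np.where(on, self.amplitude, 0.0)


class CapacitanceDrive(Drive):
    """Capacitance time course from the electromechanical coupling stage.

    Cm(t) and dCm/dt are bridged onto the integrator's adaptive time points
    with shape-preserving cubics (PCHIP), which cannot overshoot between
    samples of the slow-time grid.
    """

    def __init__(self, trace: CapacitanceTrace):
        t_ms = trace.t_ms
        if t_ms.size < 2:
            raise ParameterError("capacitance drive needs at least 2 samples")
        self._t0, self._t1 = float(t_ms[0]), float(t_ms[-1])
        self._cm = PchipInterpolator(t_ms, trace.Cm, extrapolate=False)
        self._dcm = PchipInterpolator(t_ms, trace.dCm_dt, extrapolate=False)
        dt = float(t_ms[1] - t_ms[0])
        # resolve the drive's own sampling so fast capacitance swings are
        # not stepped over
        self.max_step_ms = max(2.0 * dt, 1.0e-3)
        self.trace = trace

    def covers(self, t0_ms, t1_ms):
        return (t0_ms >= self._t0 - 1e-9) and (t1_ms <= self._t1 + 1e-9)

    def capacitance(self, t_ms):
        return self._cm(np.clip(t_ms, self._t0, self._t1))

    def dcm_dt(self, t_ms):
        return self._dcm(np.clip(t_ms, self._t0, self._t1))


# --------------------------------------------------------------------------
# integration


@dataclass
class SpikeSummary:
    spike_times_ms: np.ndarray
    first_spike_latency_ms: float | None
    spike_count: int
    mean_rate_hz: float


@dataclass
class VoltageTrace:
    """Simulated membrane potential with gating trajectories and spike summary."""

    t_ms: np.ndarray
    Vm: np.ndarray
    m: np.ndarray
    h: np.ndarray
    n: np.ndarray
    p: np.ndarray
    Cm: np.ndarray
    I_app: np.ndarray
    spike_times_ms: np.ndarray
    first_spike_latency_ms: float | None
    spike_count: int
    mean_rate_hz: float
    stimulus_onset_ms: float
    meta: dict = field(default_factory=dict)


def detect_spikes(
    t_ms,
    Vm,
    threshold: float = 0.0,
    refractory_ms: float = 2.0,
    stimulus_onset_ms: float = 0.0,
) -> SpikeSummary:
    """Upward threshold crossings with a refractory gap.

    A spike is an upward crossing of ``threshold`` (default 0 mV); crossings
    within ``refractory_ms`` of the previous spike are ignored.  Latency is
    the first spike time minus the stimulus onset.
    """
    t = np.asarray(t_ms, dtype=float)
    v = np.asarray(Vm, dtype=float)
    if t.size != v.size:
        raise ParameterError("t_ms and Vm must have the same length")
    up = np.nonzero((v[:-1] < threshold) & (v[1:] >= threshold))[0]
    times = []
    for i in up:
        # linear interpolation of the crossing instant
        frac = (threshold - v[i]) / (v[i + 1] - v[i])
        tc = t[i] + frac * (t[i + 1] - t[i])
        if not times or tc - times[-1] >= refractory_ms:
            times.append(tc)
    times = np.asarray(times)
    latency = float(times[0] - stimulus_onset_ms) if times.size else None
    span_s = (t[-1] - t[0]) * 1.0e-3
    rate = times.size / span_s if span_s > 0 else 0.0
    return SpikeSummary(
        spike_times_ms=times,
        first_spike_latency_ms=latency,
        spike_count=int(times.size),
        mean_rate_hz=float(rate),
    )


def integrate(
    params: HHParams,
    drive: Drive,
    t_span_ms: tuple[float, float],
    initial: HHState | None = None,
    *,
    rtol: float = 1.0e-6,
    atol: float = 1.0e-8,
    t_eval_dt_ms: float = 0.01,
    max_step_ms: float | None = None,
    spike_threshold: float = 0.0,
    refractory_ms: float = 2.0,
    stimulus_onset_ms: float | None = None,
    method: str = "LSODA",
) -> VoltageTrace:
    """Integrate the conductance model under the given drive.

    Uses an adaptive stiff-capable method (LSODA) with the drive's sampling
    interval as a step-size ceiling, so sub-millisecond capacitance swings
    are resolved.  Starts from the computed resting state unless ``initial``
    is given.  Gating variables are checked to remain in [0, 1].
    """
    t0, t1 = float(t_span_ms[0]), float(t_span_ms[1])
    if t1 <= t0:
        raise ParameterError("t_span must be increasing")
    if not drive.covers(t0, t1):
        raise ParameterError("drive does not cover the integration span")
    if initial is None:
        initial = steady_state(params)

    if max_step_ms is None:
        max_step_ms = drive.max_step_ms if drive.max_step_ms else np.inf

    p_ = params

    def rhs(t, y):
        V, m, h, n, p = y
        r = gating_rates(V, p_)
        Cm = float(drive.capacitance(t))
        I_app = V * float(drive.dcm_dt(t)) - float(drive.injected_current(t))
        dV = -(I_app + _ionic_current(V, m, h, n, p, p_)) / Cm
        dm = r.alpha_m * (1.0 - m) - r.beta_m * m
        dh = r.alpha_h * (1.0 - h) - r.beta_h * h
        dn = r.alpha_n * (1.0 - n) - r.beta_n * n
        dp = (r.p_inf - p) / r.tau_p
        return (dV, dm, dh, dn, dp)

    t_eval = np.arange(t0, t1 + 0.5 * t_eval_dt_ms, t_eval_dt_ms)
    sol = solve_ivp(
        rhs, (t0, t_eval[-1]), initial.as_array(), method=method,
        rtol=rtol, atol=atol, max_step=max_step_ms, t_eval=t_eval,
    )
    if not sol.success:
        raise RuntimeError(f"integration failed: {sol.message}")
    V, m, h, n, p = sol.y
    gate_tol = 1.0e-6
    for name, g in (("m", m), ("h", h), ("n", n), ("p", p)):
        if g.min() < -gate_tol or g.max() > 1.0 + gate_tol:
            raise RuntimeError(
                f"gating variable {name} left [0, 1]: range "
                f"[{g.min():.3e}, {g.max():.3e}]"
            )
    Cm = np.array([float(drive.capacitance(t)) for t in sol.t])
    dcm = np.array([float(drive.dcm_dt(t)) for t in sol.t])
    I_app = V * dcm

    onset = stimulus_onset_ms if stimulus_onset_ms is not None else t0
    spikes = detect_spikes(sol.t, V, threshold=spike_threshold,
                           refractory_ms=refractory_ms, stimulus_onset_ms=onset)
    return VoltageTrace(
        t_ms=sol.t, Vm=V, m=m, h=h, n=n, p=p, Cm=Cm, I_app=I_app,
        spike_times_ms=spikes.spike_times_ms,
        first_spike_latency_ms=spikes.first_spike_latency_ms,
        spike_count=spikes.spike_count,
        mean_rate_hz=spikes.mean_rate_hz,
        stimulus_onset_ms=onset,
        meta={"rtol": rtol, "atol": atol, "method": method,
              "max_step_ms": None if np.isinf(max_step_ms) else max_step_ms},
    )
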