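"""Independent reference solutions used to cross-check the closed forms."""

from __future__ import annotations

import numpy as np
from scipy.integrate import solve_ivp

from sonocell.membrane import MembraneParams, UltrasoundBurst, _geometry_factor


def finite_difference_deflection(
    params: MembraneParams,
    burst: UltrasoundBurst,
    t_end: float,
    nx: int = 201,
    geometry_factor: str = "pi_over_d",
    n_store: int = 200,
    safety: float = 0.4,
):
    """Explicit finite-difference integration of the damped membrane PDE.

    Second-order central differences in space, leapfrog in time with the
    viscous term lagged one level; clamped ends, start from rest.  Returns
    (t_stored, x, U) with U of shape (nx, n_stored).
    """
    d = params.d
    x = np.linspace(0.0, d, nx)
    dx = x[1] - x[0]
    c1, c0 = params.c1, params.c0
    g = _geometry_factor(geometry_factor, d)

    dt = safety * min(dx * dx / (2.0 * c1), dx / np.sqrt(c0), 1.0 / (40.0 * burst.f))
    nsteps = int(np.ceil(t_end / dt))
    dt = t_end / nsteps
    store_every = max(1, nsteps // n_store)

    u_prev = np.zeros(nx)
    u_curr = np.zeros(nx)
    stored_t, stored_u = [0.0], [u_curr.copy()]

    inv_dx2 = 1.0 / (dx * dx)

    def lap(u):
        return (u[:-2] - 2.0 * u[1:-1] + u[2:]) * inv_dx2

    lap_prev = lap(u_prev)
    for step in range(1, nsteps + 1):
        t_n = (step - 1) * dt
        f = g * float(burst.pressure(t_n)) / params.rho
        lap_curr = lap(u_curr)
        u_next = np.zeros(nx)
        u_next[1:-1] = (
            2.0 * u_curr[1:-1]
            - u_prev[1:-1]
            + dt * dt * (c1 * (lap_curr - lap_prev) / dt + c0 * lap_curr + f)
        )
        u_prev, u_curr = u_curr, u_next
        lap_prev = lap_curr
        if step % store_every == 0:
            stored_t.append(step * dt)
            stored_u.append(u_curr.copy())

    return np.array(stored_t), x, np.stack(stored_u, axis=-1)


def modal_ode_reference(b1, b0, F, omega, t_dur, t_eval, rtol=1e-11, atol=1e-24):
    """High-accuracy adaptive integration of h'' + b1 h' + b0 h = F sin(w t)
    gated over [0, t_dur], from rest."""

    def rhs(t, y):
        f = F * np.sin(omega * t) if 0.0 <= t <= t_dur else 0.0
        return [y[1], f - b1 * y[1] - b0 * y[0]]

    sol = solve_ivp(
        rhs, (float(t_eval[0]), float(t_eval[-1])), [0.0, 0.0],
        method="LSODA", rtol=rtol, atol=atol, t_eval=t_eval,
        max_step=0.05 / omega * 2 * np.pi,
    )
    assert sol.success, sol.message
    return sol.y[0]
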