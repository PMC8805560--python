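"""Membrane solver: modal algebra, closed-form response, field properties."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from sonocell import (
    DegenerateModeError,
    MembraneParams,
    ParameterError,
    UltrasoundBurst,
    mechanical_index,
    modal_coefficients,
    mode_response,
    forcing_projection,
    ohnesorge_number,
    critical_ohnesorge,
    peak_center_deflection,
    reconstruct_deflection,
    slow_time_envelope,
    sweep_peak_deflection,
)
from sonocell.membrane import ModalSolution, odd_modes

from oracles import modal_ode_reference


# --------------------------------------------------------------------------
# modal coefficients


@pytest.mark.parametrize("n", [1, 3, 7])
def test_modal_coefficients_match_root_finder(water_membrane, n):
    """r_pm must be the roots of r^2 + b1 r + b0 found independently."""
    sol = modal_coefficients(water_membrane, n)
    k = n * np.pi / water_membrane.d
    assert sol.k_n == pytest.approx(k)
    assert sol.chi_n == pytest.approx(k * k)
    assert sol.b1_n == pytest.approx((2 * water_membrane.eta / water_membrane.rho) * k * k)
    assert sol.b0_n == pytest.approx(
        (2 * np.pi * water_membrane.gamma / (water_membrane.rho * water_membrane.d)) * k * k
    )
    ref = np.roots([1.0, sol.b1_n, sol.b0_n])
    got = sorted([sol.r_plus, sol.r_minus], key=lambda z: (z.real, z.imag))
    ref = sorted(ref, key=lambda z: (z.real, z.imag))
    for a, b in zip(got, ref):
        assert a == pytest.approx(b, rel=1e-12)
    # dissipative: decaying envelopes for all physical parameters
    assert sol.r_plus.real <= 0 and sol.r_minus.real <= 0


def test_undamped_limit_gives_purely_imaginary_roots():
    p = MembraneParams(d=10e-6, gamma=1e-3, eta=1e-30)
    sol = modal_coefficients(p, 1)
    assert abs(sol.r_plus.real) < 1e-12 * abs(sol.r_plus.imag)
    assert sol.r_plus.imag == pytest.approx(np.sqrt(sol.b0_n), rel=1e-9)


def test_even_or_invalid_mode_rejected(water_membrane):
    with pytest.raises(ParameterError):
        modal_coefficients(water_membrane, 2)
    with pytest.raises(ParameterError):
        modal_coefficients(water_membrane, 0)
    with pytest.raises(ParameterError):
        MembraneParams(d=-1e-6, gamma=1e-3)


def test_near_critical_damping_does_not_crash():
    # eta chosen so the fundamental discriminant is ~0: must still build
    d, gamma, rho = 10e-6, 1e-3, 1000.0
    chi = (np.pi / d) ** 2
    eta = rho * np.sqrt(2 * np.pi * gamma / (rho * d * chi))
    sol = modal_coefficients(MembraneParams(d=d, gamma=gamma, rho=rho, eta=eta), 1)
    assert abs(sol.discriminant) < 1e-6 * 4 * sol.b0_n
    assert sol.r_plus.real == pytest.approx(-sol.b1_n / 2, rel=1e-3)


def test_exactly_degenerate_roots_raise_in_mode_response(water_membrane, burst_7mhz):
    sol = modal_coefficients(water_membrane, 1)
    degenerate = ModalSolution(
        n=1, k_n=sol.k_n, chi_n=sol.chi_n, b1_n=sol.b1_n, b0_n=sol.b0_n,
        r_plus=-1.0 + 0j, r_minus=-1.0 + 0j, a_plus_h=0j, a_minus_h=0j,
        h0=0.0, params=water_membrane,
    )
    with pytest.raises(DegenerateModeError):
        mode_response(degenerate, burst_7mhz, t_grid=[0.0, 1e-6])


# --------------------------------------------------------------------------
# forcing projection


def test_forcing_projection_against_quadrature(water_membrane, burst_7mhz):
    from scipy.integrate import quad

    d = water_membrane.d
    g = np.pi / d
    t = burst_7mhz.t_on + 0.25 / burst_7mhz.f  # quarter period: sin = 1
    for n in (1, 3):
        f_t = g * float(burst_7mhz.pressure(t)) / water_membrane.rho
        ref, _ = quad(lambda x: (2 / d) * np.sin(n * np.pi * x / d) * f_t, 0, d)
        got = forcing_projection(burst_7mhz, water_membrane, n, t)
        assert got == pytest.approx(ref, rel=1e-10)
    assert forcing_projection(burst_7mhz, water_membrane, 1, t) == pytest.approx(
        (4 / np.pi) * (np.pi / d) * burst_7mhz.P0 / water_membrane.rho, rel=1e-12
    )


def test_forcing_outside_window_and_even_modes_vanish(water_membrane):
    burst = UltrasoundBurst(P0=1e6, f=7e6, t_on=1e-3, t_dur=5e-3)
    assert forcing_projection(burst, water_membrane, 1, 0.5e-3) == 0.0
    assert forcing_projection(burst, water_membrane, 1, 7e-3) == 0.0
    assert np.all(forcing_projection(burst, water_membrane, 2, [1.5e-3, 2e-3]) == 0.0)


# --------------------------------------------------------------------------
# closed-form mode response


def test_unforced_from_rest_is_zero(water_membrane):
    burst = UltrasoundBurst(P0=0.0, f=7e6, t_dur=5e-3)
    sol = modal_coefficients(water_membrane, 1)
    h = mode_response(sol, burst, t_grid=np.linspace(0, 1e-3, 100))
    assert np.all(h == 0.0)


def test_free_decay_matches_two_exponential_form(water_membrane):
    """P0 = 0, h0 != 0: response is a+ e^{r+t} + a- e^{r-t} exactly."""
    burst = UltrasoundBurst(P0=0.0, f=7e6, t_dur=5e-3)
    h0 = 1e-7
    sol = modal_coefficients(water_membrane, 1, h0=h0)
    t = np.linspace(0, 50e-6, 400)
    h = mode_response(sol, burst, t_grid=t)
    ref = (sol.a_plus_h * np.exp(sol.r_plus * t)
           + sol.a_minus_h * np.exp(sol.r_minus * t)).real
    np.testing.assert_allclose(h, ref, rtol=1e-10, atol=1e-18)
    # decaying oscillation at rate b1/2
    env = h0 * np.exp(sol.r_plus.real * t)
    assert np.all(np.abs(h) <= env * 1.6 + 1e-18)


def test_mode_response_matches_stiff_ode_oracle(water_membrane):
    """Closed form vs adaptive integration of the modal ODE over 5 ms."""
    burst = UltrasoundBurst(P0=1e6, f=2e5, t_dur=5e-3)  # reduced carrier
    sol = modal_coefficients(water_membrane, 1)
    t = np.linspace(0, 5e-3, 600)
    h = mode_response(sol, burst, t_grid=t)
    F = (4 / np.pi) * (np.pi / water_membrane.d) * burst.P0 / water_membrane.rho
    ref = modal_ode_reference(sol.b1_n, sol.b0_n, F, burst.omega, burst.t_dur, t)
    scale = np.max(np.abs(ref))
    assert scale > 0
    assert np.max(np.abs(h - ref)) / scale < 1e-6


def test_response_continues_smoothly_after_burst(water_membrane):
    burst = UltrasoundBurst(P0=1e6, f=2e5, t_on=0.5e-3, t_dur=1e-3)
    sol = modal_coefficients(water_membrane, 1)
    t = np.linspace(0, 3e-3, 1500)
    h = mode_response(sol, burst, t_grid=t)
    # oracle with the same burst gating (delayed onset, early cutoff)
    from scipy.integrate import solve_ivp

    F = (4 / np.pi) * (np.pi / water_membrane.d) * burst.P0 / water_membrane.rho

    def rhs(tt, y):
        f = F * np.sin(burst.omega * (tt - burst.t_on)) \
            if burst.t_on <= tt <= burst.t_off else 0.0
        return [y[1], f - sol.b1_n * y[1] - sol.b0_n * y[0]]

    ode = solve_ivp(rhs, (0, 3e-3), [0, 0], method="LSODA", rtol=1e-11,
                    atol=1e-24, t_eval=t, max_step=0.5 / burst.f)
    assert ode.success
    scale = np.max(np.abs(ode.y[0]))
    assert np.max(np.abs(h - ode.y[0])) / scale < 1e-6


def test_carrier_plus_transient_decomposition_sums_to_full(water_membrane, burst_7mhz):
    sol = modal_coefficients(water_membrane, 1)
    t = np.linspace(0, 0.2e-3, 2000)
    full = mode_response(sol, burst_7mhz, t_grid=t)
    parts = (mode_response(sol, burst_7mhz, t_grid=t, component="carrier")
             + mode_response(sol, burst_7mhz, t_grid=t, component="transient"))
    np.testing.assert_allclose(full, parts, rtol=0, atol=1e-12 * np.max(np.abs(full)))


# --------------------------------------------------------------------------
# field reconstruction


def test_boundaries_symmetry_and_null_field(water_membrane, burst_7mhz):
    t = np.linspace(0, 50e-6, 40)
    trace = reconstruct_deflection(water_membrane, burst_7mhz, t, n_modes=25)
    assert np.max(np.abs(trace.u[0, :])) == 0.0
    assert np.max(np.abs(trace.u[-1, :])) == 0.0
    # only odd sine modes: u(x) = u(d - x)
    np.testing.assert_allclose(trace.u, trace.u[::-1, :], rtol=1e-10,
                               atol=1e-12 * np.max(np.abs(trace.u)))
    null = reconstruct_deflection(
        water_membrane, UltrasoundBurst(P0=0.0, f=7e6, t_dur=5e-3), t, n_modes=25
    )
    assert np.all(null.u == 0.0)


def test_field_is_linear_in_pressure(water_membrane):
    t = np.linspace(0, 30e-6, 50)
    full = reconstruct_deflection(
        water_membrane, UltrasoundBurst(P0=1e6, f=7e6, t_dur=5e-3), t, n_modes=15)
    half = reconstruct_deflection(
        water_membrane, UltrasoundBurst(P0=0.5e6, f=7e6, t_dur=5e-3), t, n_modes=15)
    np.testing.assert_allclose(full.u, 2.0 * half.u, rtol=1e-12,
                               atol=1e-15 * np.max(np.abs(full.u)))


def test_modal_energy_dissipates_without_forcing(water_membrane):
    """Sum of h'^2 + b0 h^2 over modes is non-increasing when P0 = 0."""
    burst = UltrasoundBurst(P0=0.0, f=7e6, t_dur=5e-3)
    t = np.linspace(0, 60e-6, 500)
    E = np.zeros_like(t)
    for n, h0 in ((1, 1e-7), (3, 5e-8), (5, -3e-8)):
        sol = modal_coefficients(water_membrane, n, h0=h0)
        h, v = mode_response(sol, burst, t_grid=t, return_velocity=True)
        E += v * v + sol.b0_n * h * h
    assert np.all(np.diff(E) <= 1e-10 * E[0])


def test_mode_truncation_converged_at_default(water_membrane, burst_7mhz):
    t = np.linspace(0, 0.1e-3, 800)
    pk = {}
    for n_modes in (101, 202):
        trace = reconstruct_deflection(water_membrane, burst_7mhz, t, n_modes=n_modes)
        pk[n_modes] = np.max(np.abs(trace.u_center))
    assert abs(pk[202] - pk[101]) / pk[101] < 0.01


# --------------------------------------------------------------------------
# slow-time filter


def _uniform_trace(y, dt, f_carrier):
    from sonocell.membrane import DeflectionTrace

    t = np.arange(y.size) * dt
    return DeflectionTrace(
        x_grid=np.array([0.0, 0.5, 1.0]), t_grid=t,
        u=np.zeros((3, y.size)), u_center=y,
        meta={"burst": UltrasoundBurst(P0=1e6, f=f_carrier, t_dur=1.0)},
    )


def test_lowpass_dc_passthrough_and_carrier_rejection():
    dt = 1.0 / 33.6e6
    n = 10_000
    const = _uniform_trace(np.full(n, 3.7e-9), dt, 6.72e6)
    out = slow_time_envelope(const, cutoff=1e5)
    np.testing.assert_allclose(out, 3.7e-9, rtol=1e-9)

    t = np.arange(n) * dt
    carrier = _uniform_trace(np.sin(2 * np.pi * 6.72e6 * t), dt, 6.72e6)
    out = slow_time_envelope(carrier, cutoff=1e5)
    mid = out[n // 4: -n // 4]
    assert np.max(np.abs(mid)) < 10 ** (-40 / 20)  # >= 40 dB down


def test_lowpass_preserves_slow_component_amplitude():
    dt = 1.0 / 33.6e6
    t = np.arange(int(5e-3 / dt)) * dt
    y = np.sin(2 * np.pi * 1e3 * t) + np.sin(2 * np.pi * 6.72e6 * t)
    trace = _uniform_trace(y, dt, 6.72e6)
    out = slow_time_envelope(trace, cutoff=1e5)
    # project onto the 1 kHz quadrature pair
    c = np.cos(2 * np.pi * 1e3 * t)
    s = np.sin(2 * np.pi * 1e3 * t)
    amp = np.hypot(2 * np.mean(out * s), 2 * np.mean(out * c))
    assert amp == pytest.approx(1.0, rel=0.01)


def test_cutoff_validation(water_membrane, burst_7mhz):
    t = np.linspace(0, 1e-5, 64)
    trace = reconstruct_deflection(water_membrane, burst_7mhz, t, n_modes=5)
    with pytest.raises(ParameterError):
        slow_time_envelope(trace, cutoff=burst_7mhz.f / 2)


# --------------------------------------------------------------------------
# oscillation criterion


def test_ohnesorge_number_value():
    rep = ohnesorge_number(MembraneParams(d=5e-6, gamma=1e-3))
    assert rep.Oh == pytest.approx(1e-3 / np.sqrt(1000 * 1e-3 * 5e-6), rel=1e-12)
    assert rep.Oh == pytest.approx(0.447, abs=5e-4)


def test_critical_ohnesorge_is_sqrt_two_over_pi(water_membrane):
    crit = critical_ohnesorge(water_membrane)
    assert crit == pytest.approx(np.sqrt(2 / np.pi), rel=1e-9)
    # parameter independent
    assert critical_ohnesorge(MembraneParams(d=7e-6, gamma=9e-3, rho=900, eta=2e-3)) \
        == pytest.approx(crit, rel=1e-9)


def test_oscillatory_mode_count_flips_at_critical():
    d, gamma, rho = 10e-6, 1e-3, 1000.0
    crit = np.sqrt(2 / np.pi)
    scale = np.sqrt(rho * gamma * d)
    above = ohnesorge_number(MembraneParams(d=d, gamma=gamma, eta=1.01 * crit * scale))
    below = ohnesorge_number(MembraneParams(d=d, gamma=gamma, eta=0.99 * crit * scale))
    assert above.n_oscillatory == 0
    assert below.n_oscillatory >= 1
    # low-viscosity limit: many oscillatory modes
    inviscid_like = ohnesorge_number(MembraneParams(d=d, gamma=1.0, eta=1e-4))
    assert inviscid_like.Oh < 1e-2
    assert inviscid_like.n_oscillatory > 10


@given(st.floats(min_value=0.05, max_value=3.0))
@settings(max_examples=25, deadline=None)
def test_oscillation_iff_below_critical(oh):
    d, gamma = 10e-6, 1e-3
    p = MembraneParams(d=d, gamma=gamma, eta=oh * np.sqrt(1000 * gamma * d))
    rep = ohnesorge_number(p)
    assert (rep.n_oscillatory >= 1) == (rep.Oh < rep.critical_Oh)


# --------------------------------------------------------------------------
# sweep and mechanical index


def test_sweep_null_stimulus_and_single_cell_consistency(water_membrane):
    burst0 = UltrasoundBurst(P0=0.0, f=7e6, t_dur=5e-3)
    res = sweep_peak_deflection((5e-6, 20e-6), (1e-3, 14e-3), burst0,
                                n_points=(2, 2), n_modes=5)
    assert np.all(res.peak == 0.0)

    burst = UltrasoundBurst(P0=1e6, f=7e6, t_dur=5e-3)
    res = sweep_peak_deflection((10e-6, 12e-6), (1e-3, 2e-3), burst,
                                n_points=(2, 2), n_modes=31)
    direct = peak_center_deflection(water_membrane, burst, n_modes=31)
    assert res.peak[0, 0] == pytest.approx(direct, rel=1e-12)
    df = res.to_dataframe()
    assert set(df.columns) == {"d_um", "gamma_mN_m", "peak_deflection_nm"}


def test_peak_deflection_linear_in_pressure(water_membrane):
    full = peak_center_deflection(
        water_membrane, UltrasoundBurst(P0=1e6, f=7e6, t_dur=5e-3), n_modes=31)
    half = peak_center_deflection(
        water_membrane, UltrasoundBurst(P0=0.5e6, f=7e6, t_dur=5e-3), n_modes=31)
    assert full == pytest.approx(2 * half, rel=1e-9)


def test_mechanical_index_values():
    assert mechanical_index(1.0, 1.0) == 1.0
    assert mechanical_index(1.0, 7.0) == pytest.approx(0.378, abs=5e-4)
    assert mechanical_index(0.0, 7.0) == 0.0
    with pytest.raises(ParameterError):
        mechanical_index(1.0, 0.0)
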