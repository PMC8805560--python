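# Methods

`sonocell` simulates how a plane ultrasound burst deflects the anchored
membrane of an adherent cell and how the resulting area/capacitance change
drives a conductance-based neuron.  This note records the model, its
assumptions, the numerical choices, and — importantly — what the model does
and does not predict.

## Membrane mechanics

The membrane section between two adhesion points of length `d` is treated
as a one-dimensional clamped interface immersed in a viscous fluid (water:
ρ = 1000 kg m⁻³, η = 10⁻³ Pa s) and restored by surface tension γ.  Its
transverse displacement obeys

    ∂²u/∂t² = c₁ ∂³u/∂x²∂t + c₀ ∂²u/∂x² + g(d) P_US(t)/ρ,
    c₁ = 2η/ρ,   c₀ = 2πγ/(ρd),

with clamped ends u(0,t) = u(d,t) = 0 and start-from-rest initial
conditions (a hydrostatic parabolic initial profile u₀ = P₀x(d−x)/(4γ) is
available as an option but off by default: static pressure is orders of
magnitude below the radiation pressure and is discarded).  The incident
pressure is an imposed gated sinusoid P_US = P₀ sin(ω(t−t_on)); no acoustic
propagation, cavitation, or cytoskeletal restoring force is modelled.

**Forcing prefactor.** The pressure-gradient prefactor `g(d)` is
configurable (`geometry_factor`).  The default is `pi_over_d` (g = π/d),
the only choice that is dimensionally consistent, agrees with the stiffness
coefficient c₀ = 2πγ/(ρd), and places the steady carrier amplitude of the
fundamental mode, 4P₀/(ρdω²), at 414/207/104 nm for d = 5/10/20 μm at
1 MPa / 7 MHz — the 100–400 nm envelope that matches holographic
measurements of adherent cells.  `pi_d` and `unity` are retained so the
sensitivity to this reading can be assessed (they give ~10⁻⁸ nm and
~10⁻³ nm respectively, i.e. no observable deflection).

**Solution.** Eigenfunction expansion on sin(nπx/d).  A uniform pressure
projects only onto odd modes (even projections vanish identically); each
odd mode is a damped oscillator ḧ + b₁ḣ + b₀h = f̂(t) with
b₁ = c₁(nπ/d)², b₀ = c₀(nπ/d)², solved **in closed form** for the gated
sinusoid: particular (carrier) solution plus matched decaying exponentials
at the characteristic roots r± = (−b₁ ± √(b₁²−4b₀))/2, piecewise across
burst onset and offset.  This avoids Nyquist-limited time stepping of the
MHz carrier entirely; the field can be sampled at any time.  Exactly
critically damped roots raise an explicit error (physically they require
exact marginality never met in practice).  Default truncation is 101 odd
modes (n = 1…201) with an automatic convergence check (halving the mode
count must move the peak midpoint deflection by < 1%); high modes are
damped as n².  The closed form is cross-checked against a stiff adaptive
ODE integration (≤ 10⁻⁶ relative) and a brute-force finite-difference
integration of the PDE (≤ 5% relative L2; measured ~1.5 × 10⁻⁵).

**Oscillation criterion.** Unforced modes ring iff their discriminant
b₁² − 4b₀ is negative, i.e. iff n < √(2/π)/Oh with the Ohnesorge number
Oh = η/√(ργd).  The critical value for the fundamental mode is therefore
√(2/π) ≈ 0.798; the package computes it by a numeric sign-change search on
the discriminant rather than hard-coding the constant.

**Onset transient.** Switching a sinusoid on abruptly from rest excites the
slow free oscillation of each mode with amplitude ≈ f̂/(ω·ω_d), a factor
ω/ω_d (~200 at default geometry) larger than the steady carrier amplitude
f̂/ω².  At 1 MPa, d = 10 μm, γ = 1 mN/m this transient peaks near 22 μm
and decays with time constant 2/b₁ ≈ 10 μs (ringing at ~36 kHz).  The
steady response thereafter is the 207 nm carrier oscillation.  Peak
deflection statistics (the sweep) therefore reflect the transient, not the
steady envelope; both are physically part of the linear model under ideal
gating, but the transient depends entirely on the assumed zero rise time of
the burst, which real transducers do not achieve.  This is the model's
sharpest limitation and is discussed under "Limitations".

**Slow-time extraction.** The "observed" millisecond-scale response is the
low-pass filtered field (zero-phase 4th-order Butterworth, default cutoff
100 kHz, far below the 6.72 MHz carrier and above the slow ringing).  The
pipeline exploits the closed form's exact carrier/transient split: the
slow field is built from the transient components of the modes whose ring
frequency the slow grid can represent (the rest are > 40 dB inside the
filter stopband and are dropped, recorded per run), sampled at 1 μs.  A
10 μs grid would violate Nyquist for the 100 kHz cutoff, hence the finer
default.

## Electromechanical coupling

Deflection changes the arc measure A = ∫ 2π√(1+u_x²) dx (≥ 2πd always,
quadratic in amplitude at leading order, verified against a Taylor
expansion and adaptive quadrature).  Treating the bilayer (thickness
L = 5 nm, physiological band 4–9 nm, relative permittivity 2) as a
dielectric between charged surfaces, capacitance is proportional to area;
the neuron is driven through the dimensionless ratio

    Cm(t) = Cm0 · A(t)/A(0),   Cm0 = 1 μF cm⁻² by default,

which is insensitive to the line-integral prefactor and avoids committing
to an unstated three-dimensional geometry; the absolute parallel-plate
value ε₀ε_r A/L is reported for reference only.  dCm/dt is estimated by a
Savitzky–Golay local-cubic derivative (window 7 samples = 7 μs on the
default grid), tolerant of residual carrier leakage; for smooth drives the
derivative integrates back to Cm − Cm0 within 10⁻⁶ relative.

## Neuron model

A regular-spiking cortical conductance set: transient Na⁺ (ḡ = 56 mS cm⁻²,
E = 50 mV, threshold parameter V_th = −56.2 mV), delayed-rectifier K⁺
(6 mS cm⁻², E_K = −90 mV), slow non-inactivating K⁺ (0.075 mS cm⁻²,
τ_max = 608 ms) producing spike-frequency adaptation, and leak
(0.0205 mS cm⁻², −70.3 mV).  Units are mV/ms/mS cm⁻²/μF cm⁻²/μA cm⁻².
Rate-function 0/0 points (e.g. α_m at V_th+13 mV) use analytic limits.
The resting potential, found by root-finding the total ionic current with
gating at its fixed points, is −71.91 mV; the fixed-point residual is
< 10⁻⁹ μA cm⁻² and the state is stable over 500 ms of re-integration.

Mechanical drive enters as the capacitive current I_app = Vm·dCm/dt inside

    dVm/dt = −(I_app + I_Na + I_Kd + I_M + I_leak)/Cm(t),

with Cm(t) interpolated onto the adaptive integrator's time points by
shape-preserving cubics.  Integration uses LSODA (rtol 10⁻⁶, atol 10⁻⁸)
with the drive's sample interval as step-size ceiling.  Constant-current
drives use the conventional sign (positive injected current depolarizes).
Spikes are upward 0 mV crossings with a 2 ms refractory gap (the detection
rule is a package choice); latency is measured from burst onset.

## Synthetic profile recordings

The profile-stack generator emulates line-profile height recordings of an
adherent cell: a smooth ~1.5 μm dome, bounded uniform baseline noise
(half-range 20 nm by default; Gaussian available), a 25/50/25 ms
baseline/stimulus/post layout, and a stimulus-locked deflection — either a
synthetic 200 nm bump or a membrane-model field resampled onto the frame
clock.  The native 40 kHz frame rate is decimated to 4 kHz by default for
speed (factor recorded in metadata), and the injected ground truth is
stored alongside.  It does not emulate optical reconstruction artifacts,
drift, or spatially correlated noise, so passing round-trip tests show the
statistic is implemented correctly, not that it is robust to real
instrument systematics.  The max-over-(x, t) statistic carries the positive
bias of any extreme-value estimate over noise; it is reported uncorrected,
with the bias bounded in tests (mean recovered maximum within [truth,
truth + noise half-range] over 100 seeded replicates).

## Problem sizes and runtime choices

Closed-form evaluation makes the membrane stage cheap at any sampling; the
(d, γ) sweep uses a 10×10 grid with 101 odd modes per cell, sampling the
onset transient at 16 samples per carrier period and comparing against the
analytic steady amplitude.  Coupled runs sample the slow field at 1 μs
over (1 + 50 + 5) ms and integrate the neuron with a 2 μs step ceiling.
The finite-difference oracle uses a 201-point grid over the first 0.5 ms
(explicit scheme, stability-limited step ~2.5 × 10⁻¹⁰ s).

## Limitations and known discrepancies

- **Abrupt gating dominates the peak.** With an ideal zero-rise-time
  burst, the onset transient (~22 μm at defaults) exceeds the steady
  carrier amplitude by two orders of magnitude and exceeds measured
  deflections (hundreds of nm) as well.  The 100–400 nm envelope over
  d ∈ [5, 20] μm corresponds to the *steady* fundamental-mode amplitude
  4P₀/(ρdω²); the package's peak-deflection statistic, taken over the full
  from-rest solution, is therefore μm-scale.  A finite transducer rise
  time would suppress the transient, but is outside the present scope.
- **The coupled pipeline does not spike at these drive parameters.**  The
  capacitance drive the model produces consists of a violent but ~30 μs
  onset/offset swing (too fast for Na⁺ activation, τ_m ~ 0.1 ms: the charge
  borrowed during the Cm excursion is returned as Cm relaxes, leaving
  ~1 mV residual depolarization) plus a sustained steady-state area
  elevation of only ΔCm/Cm ≈ 5 × 10⁻⁴ at 1 MPa (≈ 0.04 mV).  Across
  d ∈ [5, 20] μm, γ ∈ [1, 14] mN/m, Cm0 ∈ [0.5, 1] μF cm⁻², 0.5–1 MPa and
  5–50 ms bursts — and under either reading of the voltage equation
  (time-varying or constant capacitance in the denominator) — no action
  potential is generated.  Reports of ultrasound-evoked spiking through
  this mechanism would require a sustained millisecond-scale capacitance
  modulation of rheobase-order dCm/dt that the printed mechanics does not
  supply; the corresponding pressure-threshold and latency checks in the
  acceptance suite fail and are intentionally left failing.
- The membrane model is linear; μm-scale transients violate the small-slope
  assumption behind both the wave equation and the quadratic area
  expansion (the code evaluates the full √(1+u_x²) integrand regardless).
- Single cell, single mechanism: no mechanosensitive channels, channel
  noise, temperature scaling, or multicompartment morphology.
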