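# sonocell

A coupled biophysical model of **ultrasound neuromodulation** for
computational neuroscientists and biophysicists: a plane ultrasound burst
deflects the anchored membrane of an adherent cell; the deflection changes
membrane area and hence capacitance; the capacitive current
`I_app = Vm·dCm/dt` drives a conductance-based neuron.  The package also
implements the line-profile statistics used to quantify such deflections in
high-speed holographic height recordings, together with a synthetic
recording generator so those statistics are testable without instrument
data.

## Model

The membrane section of length `d` between adhesion points, clamped at both
ends, immersed in water and restored by surface tension `γ`, obeys the
damped wave equation

    ∂²u/∂t² = (2η/ρ) ∂³u/∂x²∂t + (2πγ/ρd) ∂²u/∂x² + (π/d)·P₀ sin(ωt)/ρ

solved by eigenfunction expansion: each odd sine mode is a damped harmonic
oscillator whose response to the gated sinusoid is evaluated **in closed
form**, so the MHz carrier never has to be time-stepped.  Whether unforced
modes ring is governed by the Ohnesorge number `Oh = η/√(ργd)`; the
fundamental mode oscillates iff `Oh < √(2/π) ≈ 0.80`.

Deflection feeds the arc measure `A = ∫2π√(1+u_x²)dx`, capacitance follows
the area ratio `Cm = Cm0·A/A(0)`, and the neuron is a regular-spiking
cortical Hodgkin–Huxley variant (Na⁺, delayed-rectifier K⁺, slow
non-inactivating K⁺ for spike-frequency adaptation, leak; resting potential
−71.9 mV) integrated under the time-varying capacitance.

See `docs/methods.md` for assumptions, parameter defaults, numerical
choices and known limitations — including an analysis of the burst-onset
transient and of the coupled model's spiking behavior.

## Worked example

Oscillation criterion for a 10 μm membrane at 1 mN/m in water:

```sh
$ sonocell ohnesorge --d 10e-6 --gamma 1e-3
Oh = 0.3162  critical_Oh = 0.7979  oscillatory odd modes = 1
```

`Oh = 0.32 < 0.80`, so the unforced fundamental mode rings (at ~36 kHz for
this geometry) rather than creeping back; exactly one odd mode is
oscillatory.

Full coupled run, 1 MPa / 6.72 MHz / 5 ms preset:

```sh
$ sonocell coupled --preset short-high --outdir out/
peak slow deflection 22339.8 nm, peak dCm/Cm0 3.65, spikes 0, latency None ms
```

The slow-time (low-pass filtered) deflection peaks at ~22 μm — the ringing
excited by the burst's abrupt onset — and the membrane area transiently
rises 3.65-fold, but the excursion lasts only tens of μs and relaxes
without triggering an action potential (see the methods note on why this
drive cannot recruit Na⁺ channels).  `out/` receives the deflection,
capacitance and voltage traces as CSV, a spike summary, and the resolved
config for reproducibility.

In Python:

```python
from sonocell import MembraneParams, UltrasoundBurst, peak_center_deflection

p = MembraneParams(d=10e-6, gamma=1e-3)          # water by default
b = UltrasoundBurst(P0=1e6, f=7e6, t_dur=5e-3)
print(peak_center_deflection(p, b) * 1e9)        # -> 21934.5 (nm)
```

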