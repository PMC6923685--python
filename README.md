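# tmaskit

Modelling and analysis toolkit for **transcranial magneto-acoustic
stimulation (TMAS)**: focused ultrasound delivered inside a static magnetic
field so that the oscillatory ion motion of the wave produces a focused
Lorentz-force electric field at the acoustic focus. It is written for
researchers in ultrasound neuromodulation who need to (a) predict the
acoustic and electric focus of a bowl transducer, (b) report the dosimetry
of a pulsed protocol, and (c) quantify the electrophysiological outcome
(LTP / depotentiation of fEPSP slopes) of a stimulation experiment.

## The model

**Acoustic field.** A spherical-cap (bowl) transducer of curvature radius
*F* and aperture *D*, driven uniformly at carrier frequency *f*, radiates a
steady-state field obtained from the Rayleigh surface integral

> p(**r**) = −(i k p₀ / 2π) ∫∫ e^{ikR}/R dS,  k = 2πf/cₛ,

with p₀ = ρcₛu₀ the characteristic surface drive. The closed-form on-axis
solution of the uniformly vibrating bowl (O'Neil's solution) serves as an
independent oracle; at the geometric focus it reduces to |p(F)| = p₀·k·h,
with h the cap depth.

**Magneto-acoustic coupling.** For a plane wave, particle velocity is
V = P/(ρcₛ); in a static field **B₀** the induced field and current are

> **E** = **V** × **B₀**,  **J** = σ**E**,

so |E| = P·B₀/(ρcₛ) when **B₀** ⊥ beam: the E-field distribution is an
exact scalar multiple of the pressure distribution, and focusing the beam
focuses the electric stimulus.

**Dosimetry.** Duty cycle = PD·PRF, I_sppa = P²/(2ρcₛ),
I_spta = I_sppa·duty, MI = P[MPa]/√(f[MHz]).

**Electrophysiology.** Per-animal fEPSP slope series (1 sample/min; 30 min
baseline, theta-burst → 90 min LTP, low-frequency stim → 90 min
depotentiation) are normalized to the baseline mean (=100%), quantified by
the phase endpoint and last-10-min mean, summarized as mean ± SEM, and
contrasted with Welch's two-sided t-test.

Seeded synthetic generators emulate hydrophone scan maps, test-sample
voltage sweeps and fEPSP cohorts, so the whole pipeline is testable without
laboratory data.

## Worked example

```
$ python examples/couple_efield.py
particle velocity |V| : 2.069 m/s
induced E-field   |E| : 0.4138 V/m, direction [ 0.  0. -1.]
current density   |J| : 0.4138 A/m^2 (sigma = 1 S/m)
E vs P slope          : 1.379e-07 (V/m)/Pa, r^2 = 1.000
```

A 3 MPa focal pressure in a 0.2 T field induces ≈0.41 V/m, directed
perpendicular to both the beam (+y) and the magnet (+x); the sweep shows
the exactly proportional pressure→E-field relation.

```
$ python examples/simulate_beam.py
peak pressure        : 3.00 MPa (calibrated)
focal length         : 21.8 mm (axial peak position)
-6 dB focal width    : 1.89 mm (half-amplitude full width)
```

The 1 MHz, F = 23 mm bowl focuses into a ≈2 mm spot at ≈22 mm — slightly
upstream of the geometric focus, as diffraction predicts. Other examples
cover dosimetry (`dosimetry_report.py`: duty cycle 2×10⁻⁴,
I_spta ≈ 62 mW/cm²), scan-map analysis and the LTP pipeline.

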