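# Methods

## Acoustic field model

The transducer is a uniformly vibrating spherical cap (curvature radius
*F* = focal length, rim diameter *D*) in a homogeneous lossless medium.
Although the physical stimulus is a tone burst, each pulse carries ≥200
carrier cycles, so the field is modelled as monochromatic steady state
(Helmholtz regime) rather than by time-domain integration of the wave
equation. The complex pressure is the Rayleigh integral of point sources
over the cap surface with strength −(i k p₀/2π)·e^{ikR}/R, p₀ = ρcₛu₀.

**Discretisation.** The cap is sliced into latitude rings (midpoint rule in
the polar angle) and azimuthal elements, at least 6 elements per wavelength
in both surface directions (`ELEMENTS_PER_WAVELENGTH = 6`). Against the
closed-form on-axis solution this quadrature is accurate to ~0.15% away
from pressure nulls, and doubling the density changes the focal value by
<0.1% (a refinement test asserts <0.5%).

**Axisymmetric reduction.** The bowl field depends on a node only through
its axial coordinate y and its distance r = √(x²+z²) from the beam axis.
The solver evaluates the integral once per unique (r, y) pair of the
requested Cartesian grid and scatters the result to all matching nodes —
exact (no interpolation) and roughly two orders of magnitude cheaper on
symmetric grids, which is what makes the λ/4, 30×40×30 mm reference domain
(~765k nodes) run in well under a minute on one core.
`CartesianGrid.centered` builds x/z axes symmetric about the beam axis so
the axis itself is sampled exactly; grids coarser than λ/4 are refused (or
warned about, per `coarse_grid=`), and nodes within λ/8 of the cap surface
are an error.

**Closed-form oracle.** The on-axis magnitude of the uniformly driven bowl
is |p(y)| = 2p₀|sin(k(d−y)/2)|/|1−y/F| with d the rim distance; at y = F
the analytic limit p₀·k·h (h = cap depth) is substituted. For the default
fixture (1 MHz, F = 23 mm, D = 23.5 mm, cₛ = 1450 m/s) this gives a
focusing gain k·h ≈ 14.0.

**Fixture geometry.** The aperture is a configuration parameter with
default D = 23.5 mm, chosen so the predicted −6 dB focal width
≈1.41·λF/D matches the nominal 2 mm focus of the modelled transducer;
the true aperture of that device is not published. The axial peak of a
focused bowl sits upstream of the geometric focus — the simulation finds
≈21.8 mm for the fixture, within the 10% band around the nominal 23 mm.

**Units.** Strict SI internally; configuration files and `ScanMap`
coordinates use bench units (MHz/mm/MPa), converted on read.

## Lorentz coupling

Plane-wave relations pointwise: V = P/(ρcₛ) along the nominal beam axis,
E = V×B₀, J = σE. The vector convention ŷ×x̂ = −ẑ puts E along −z when B₀
is along +x; magnitudes are used for all comparisons since the scalar sign
depends on an arbitrary charge-sign convention. The local propagation
direction is approximated by the beam axis everywhere (the same plane-wave
assumption underlying V = P/(ρcₛ)); this is exact on axis and good
throughout the focal region of a weakly divergent beam. Default medium:
ρ = 1000 kg/m³, cₛ = 1450 m/s, σ = 1 S/m ("1 S" is interpreted as 1 S/m —
the only dimensionally consistent reading of J = σE). The ionic charge
cancels between the Lorentz force and the equivalent field and is not a
parameter. A zero B₀ degenerates to ultrasound-only stimulation: the
coupled map is zero and a warning is raised.

## Dosimetry

All metrics follow from PD, PRF, carrier frequency and the focal peak
pressure under the plane-wave intensity relation. The focal pressure is a
*measured input* (the 3 MPa intracranial operating point), not propagated
through skull — attenuation and heterogeneous media are out of scope.
Peak-negative pressure is taken equal to the peak (linear symmetric
waveform) for the mechanical index. Pulse counts use floor(duration·PRF)
with a 1 ns guard against float rounding. The "200 µs" pulse duration is
adopted for the reference protocol; it is the only reading consistent with
the ~60 mW/cm² temporal-average intensity at 3 MPa and 1 Hz.

## Beam metrics

"Focus size" is the −6 dB (half-amplitude) full width — the metrology
standard — of the profile through the map peak along a grid line (no
oblique resampling); crossings are linearly interpolated, which matters
when the scan step (2 mm) is comparable to the width itself. Focal length
is the axial argmax refined by a 3-point parabola (flat tops fall back to
the sample position; a boundary maximum is an error). Map agreement is the
Pearson correlation over matched nodes, always computed on normalized maps
(scale-free). Linearity of response vs pressure is an ordinary
least-squares line with r².

## fEPSP pipeline

Timeline: baseline samples are those at or before the TBS marker (30 min);
LTP window (TBS, TBS+90] min; DP window (LFS, LFS+90] min, all at 1
sample/min. Normalization divides by the single pre-TBS baseline mean
(×100) and is applied once — there is no re-baselining before DP. The
endpoint is the literal final sample of a window; the window mean averages
the last 10 samples. SEM uses the n−1 sample standard deviation. Group
contrasts use Welch's unequal-variance two-sided t-test (small n, no
evidence of equal variances); p-values are reported pairwise without
multiplicity correction. Slopes are treated as magnitudes; a reader flag
(`flip_sign`) accommodates negative-going conventions.

## Synthetic generators

The generators emulate the *statistical structure* the analysis assumes,
not raw physiology:

- **Scan maps**: nearest-node resampling of a reference map to the scan
  step (2 mm default protocol) plus multiplicative (5% default) and
  additive Gaussian noise, clamped at zero.
- **Voltage sweeps**: v = sensitivity·|E(P)| + Gaussian noise. The pickup
  of the short-wire test sample is modelled as a single scalar sensitivity
  (V per V/m); whether the physical pickup is exactly E × wire length is
  unknown, so the scalar is configurable.
- **fEPSP cohorts**: per animal, percent-of-baseline trajectory = 100
  during baseline; plateau + overshoot·e^{−t/τ} after TBS; exponential
  decay from the LTP end level toward a DP level after LFS; i.i.d.
  Gaussian noise (default sd 5% of baseline) on every sample. The
  trajectory form is the simplest shape matching the qualitative time
  course of the modelled recordings with a well-defined endpoint for
  recovery tests. Default LTP plateaus are the published endpoint means of
  the three treatment arms (TMAS 343.9, TUS 154.8, control 74.4 % of
  baseline — the control arm genuinely ends below baseline and is
  reproduced as such). DP levels are not published; defaults (180/110/65)
  preserve the reported ordering and significance structure. τ defaults to
  8 min and is shared by the LTP rise and DP decay.

Determinism: a cohort seed fans out to per-animal substreams via
`SeedSequence(seed).spawn(n)`; identical seeds give bit-identical data.
Because noise is white, passing recovery tests demonstrates correct
quantification arithmetic, not robustness to autocorrelated drift or
electrode artefacts present in real recordings.

## Problem sizes and tolerances

The reference simulation domain is 30×40×30 mm at λ/4 (≈765k nodes,
~35 s single-core); unit tests use a smaller focal-region grid
(12×16×12 mm) computed once per session. Oracle agreement is asserted at
<1% relative error within 8 mm of the focus (nulls excluded); beam
geometry at ±10% (focal length) and ±15% (−6 dB width) of the nominal
23/2 mm; LTP round-trips at 3 SEM over ≥20 seeds with ≥95% pass rate; the
Welch null rejection rate at 0.05±0.02 over 1000 simulations.

## Known limitations

Lossless homogeneous medium (no skull attenuation — intracranial pressure
is an input); linear acoustics (no harmonics, so peak-negative = peak);
plane-wave coupling direction (slightly underestimates |E| off axis where
wavefronts diverge); no ohmic return paths or conductor boundaries for the
induced currents; behavioral outcomes of the modelled experiments are out
of scope.
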