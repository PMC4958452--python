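# Methods

`stenosim` couples a semi-analytic model of pulsatile blood flow in a
stenosed, oscillating elastic artery to a linear point-scatterer ultrasound
simulator, and closes the loop with the image-based wall-displacement
evaluation that the package itself is designed to test.  This note records
the model, its assumptions, the defaults, and the design decisions taken
where the problem was genuinely open.

## Vessel geometry and wall motion

The lumen is an axisymmetric tube of rest radius R0 = 4 mm with a cosine
stenosis of height δ over |x| ≤ x0 whose severity is quoted as the radius
reduction δ/R0 (25% stenosis → δ = 1 mm).  The stenotic segment additionally
oscillates sinusoidally,

    R(x,t) = R0 [1 − (δ/2R0)(1 + α sin ωt)(1 + cos πx/x0)],   |x| ≤ x0,

modelling wall motion imposed by surrounding tissue (heartbeat, breathing).
The amplitude coefficient **α defaults to 0.05**; it has no established
literature value, and 0.05 makes the oscillation amplitude at the throat
(δα ≤ 50 µm at 25% stenosis) comparable to the compliance-driven distension,
so neither motion component dominates the tracking problem.  The stenosis
half-length default is x0 = 40 mm and the wall thickness h = 0.3 mm.

On top of the prescribed motion the wall responds quasi-statically to the
local pulsatile pressure through the thin-shell law

    ξ = p R² (1 − σ²) / (E h),

with E = 978 kPa and σ = 0.5.  Wall inertia and fluid shear on the wall are
dropped (the full shell PDEs are not solved); the effective stiffness that
appears in the pressure ODE below is therefore B = E/(1 − σ²), the unique
choice consistent with the shell law.  The wall density (1100 kg/m³) is
carried in the configuration but never enters this quasi-static law.

## Hemodynamics

Blood is laminar, Newtonian (µ = 3.5 mPa·s, ρ = 1050 kg/m³), fully developed
and incompressible; the long-wave linearised Navier–Stokes equations are
expanded in a Fourier series at multiples of the fundamental
ω0 = 2π/tp = 3π rad/s (tp = 2/3 s), with N = 14 harmonics.

* **Steady part** — lubrication balance (R/4)p0'' + p0' dR/dx = 0, i.e.
  dp0/dx ∝ R⁻⁴ (constant steady flux); integrated in closed form.
* **Harmonics** — the classical annular Bessel profile
  u_n ∝ J0(βn j^{3/2} r)/J0(βn j^{3/2} R) − 1 with βn = √(ρ n ω0/µ)
  (Womersley number βn·R0 ≈ 6.73 at the fundamental), the radial velocity
  from continuity, and the elastic-wall coupling v_n(R) = j n ω0 ξ_n.
  Substitution yields a second-order variable-coefficient ODE for p_n(x)
  which is integrated by adaptive Runge–Kutta (`solve_ivp`, rtol 1e-10)
  from the inlet.  Two transcription defects in the printed source equations
  were resolved by re-derivation: the radial-velocity formula must satisfy
  mass conservation exactly (verified analytically in the tests), which
  fixes the steady radial component to
  v0 = p0''(2R²r − r³)/16µ + p0' R R' r/4µ and puts a minus sign on the
  first-derivative term of the pressure ODE.
* **Inlet conditions** — the primary user input is the centerline-velocity
  waveform at x = −2x0.  dp_n/dx follows from the rigid-tube Womersley
  relation that reproduces each velocity harmonic on the axis; p_n follows
  from the forward-travelling characteristic root of the straight-tube
  reduction of the ODE (tube wave impedance; Moens–Korteweg speed ≈ 6.8 m/s
  here), taken on the branch with negative imaginary part (phase travels
  downstream) under the e^{+jnω0t} convention with j^{3/2} = e^{j3π/4}.
* **Quasi-static wall phase** — the wall oscillation is slow compared with
  every retained flow harmonic, so the pressure problem is re-solved
  per output frame with the geometry frozen at that frame's wall phase
  (48 frames per cardiac cycle by default).

The measured carotid waveform the model emulates is not tabulated anywhere,
so `synth_cca_waveform` generates a parametric stand-in: a diastolic
baseline (≈0.22 of peak) plus a systolic Gaussian (centre 0.30 tp, width
0.06 tp) and a dicrotic bump (0.55 tp), scaled to a 0.8 m/s peak.  The
steepest systolic rise falls at t/tp ≈ 0.24, inside the physiological
systolic acceleration band 0.22–0.26.  Cycle-mean centerline velocity is
≈0.26 m/s.  What it does not emulate: beat-to-beat variability, waveform
skew from wave reflections, or subject-specific spectra — conclusions drawn
from the synthetic waveform concern the machinery, not any individual
patient.

## Scatterer phantom

Scatterers carry vessel coordinates (axial s, radius r, azimuth φ); the
vessel axis is tilted 45° to the beam and passes through the transmit focus.
Density is ten scatterers per resolution cell (axial pulse footprint ×
lateral FWHM × elevation FWHM at the focus).  Region strengths follow the
per-mode table (wall 50, blood 5, tissue 10/0/0 for B-/M-mode/CFI);
amplitudes are **zero-mean Gaussian with the tabulated strength as standard
deviation** — the convention of scatterer-based field simulators, and the
only reading under which "amplitude 0" regions are genuinely echo-free and
speckle is fully developed.

Blood advects with the interpolated flow field (forward Euler at the pulse
repetition interval, tabulated on a normalised-radius × axial × time grid)
and recycles axially with a fresh amplitude draw.  Two kinematic
completions keep the blood pool consistent with the moving wall, both
consequences of the quasi-static treatment (the harmonic solution's wall
velocity contains only the compliance part):

* the prescribed oscillation adds the dilation field v = (r/R) dR/dt;
* blood in the outermost 15% of the radius rides the lumen surface at
  constant normalised radius (exact no-penetration), and all blood is
  clipped just inside the instantaneous surface W = R + ξ.

Wall/tissue scatterers move only radially.  The incremental update law
(displacement decaying linearly to zero at the radial scan edge R_range,
default 30 mm) is implemented with a configurable decay origin: measured
from the vessel axis it reproduces the textbook form, but the evaluation
pipeline measures the decay **from the lumen surface**, because an
axis-referenced decay would scale the inner-wall motion by ≈0.87 and no
sub-percent tracking agreement could exist.  For M-mode acquisition the
wall/tissue population is **regenerated every emission** from the current
analytic wall state (positions and amplitudes are redrawn after each RF
line, as the full-coupling scheme prescribes): statistically identical to
advecting a frozen population, but successive image columns then carry
independent speckle, which is what makes ensemble averaging and despeckling
effective downstream.  The correlated alternative (frozen positions,
incremental updates) remains available through `advance_wall_tissue`.

## Ultrasound simulation

The acoustics layer is a bespoke linear pulse-echo simulator (element-level
spatial impulse responses are deliberately out of scope): each scan line
sums beam-weighted, delayed copies of the two-way pulse — a Hanning-windowed
2.5-cycle sinusoid at the centre frequency, unit peak.  The beam weight is a
separable Gaussian; the lateral width is diffraction-limited at the transmit
focus (two-way FWHM = f#·λ/√2, f# from the 64-element active aperture with
one-wavelength elements) and spreads hyperbolically with a Rayleigh-type
range; the elevation aperture (5 mm element height) is lens-focused at the
same depth and treated identically.  Delays use the depth along the line
(ideal dynamic receive focusing); attenuation and noise are not modelled.
Internal sampling is 100 MHz.  Mode presets: B-mode 3 MHz/f7 cm, M-mode
3.75 MHz/f4 cm (convex, approximated by the same line-based model), CFI
5 MHz/f4 cm.  The CFI pulse repetition frequency defaults to 16 kHz — the
value the source's own discussion uses — rather than the 1 kHz of its
parameter table, which would alias every systolic velocity; the Nyquist
velocity is then c·PRF/(4f0) ≈ 1.23 m/s.

Images: quadrature demodulation at f0 (zero-phase FIR low-pass, then
decimation), envelope → per-frame peak normalisation → 20·log10 with a
50 dB dynamic range.  Axial velocities come from the lag-one autocorrelation
phase of the slow-time IQ ensemble (8 emissions per line, one-pulse-length
axial averaging); positive phase increments map to positive v_z and the
estimate wraps at the Nyquist velocity.  No clutter filter is applied by
default (the source displays unfiltered colour flow); a polynomial
regression wall filter is provided as an off-by-default hook.

## Wall-displacement evaluation

The M-mode line interrogates the stenosis centre; at 45° the beam meets the
near lumen surface where d·sin45° = W(−d·cos45°, t), so the tracked
interface sits at vessel-axial position ≈ −3 mm.  The numerical reference
trace is the exact radial position of that moving intersection, solved by
fixed-point iteration on the analytic surface W(s,t) — the ground truth for
the very interface the tracker follows.

Processing chain (defaults chosen once, recorded here):

1. per-seed envelope-squared M-mode images, ensemble-averaged over the
   seeded repeats and over a ~45 ms sliding window (the wall moves far less
   than a depth pixel within it);
2. SRAD despeckling (300 iterations, Δt = 0.05, the coefficient of
   variation referenced to a lumen rectangle, re-estimated every iteration);
   the bare `srad()` function defaults to the milder 100/0.05;
3. thresholding at 50% of the column maximum.  The wall is the
   supra-threshold run containing the column maximum; the evaluation uses
   the **intensity-weighted centroid of that run** rather than its leading
   edge, because for a cylinder inclined to the beam the leading edge is
   smeared by out-of-plane wall curvature whose apparent radial motion is
   geometrically compressed, so the leading-edge feature systematically
   under-reports wall displacement while the band centroid tracks the
   specular in-plane response with near-unit transfer.  The classic
   leading-edge crossing remains the `extract_wall` default;
4. Savitzky–Golay smoothing of the tracked trace (~70 ms, order 2); the
   acquisition is padded by 9% of a cycle at both ends so no temporal filter
   sees its own endpoints inside the scored cycle.

Both traces are reduced to displacements about their own cycle mean before
comparison; the per-time relative error is |est − ref| divided by the
reference peak-to-peak displacement (×100).  Normalising by the
instantaneous position would make percent-scale errors physically
meaningless for micrometre motion on a millimetre radius.  The mean and
maximum over one cardiac cycle are reported, per (stenosis, wall-frequency)
case, averaged over ten seeded speckle realisations.

## Problem sizes

The evaluation runs each case at 875 M-mode lines per second over one padded
cardiac cycle (≈680 emissions), 48 flow frames per cycle, a 257-point axial
pressure grid, a 33 × 49 × frames velocity table, roughly 3·10⁴ scatterers,
and ten seeds — the package's standard single-workstation configuration.
Colour-flow runs use 10 lines × 8 emissions around the systolic
acceleration instant t/tp = 0.24.

## Known limitations

* The quasi-static coupling is one-way per frame: wall oscillation
  modulates the flow only through the frozen geometry; there is no
  oscillation-driven axial pumping.
* The Gaussian beam reproduces beam-scale blur but not element-level
  diffraction detail; convex-array curvature is approximated by straight
  vertical lines.
* Threshold wall tracking at 45° on a curved interface has an inherent
  feature-dependent displacement transfer (see above).  On finite-look
  speckle the threshold estimator's expectation also lags the true motion
  (the detection level and run boundaries respond nonlinearly to speckle),
  and this residual transfer deficit of the full chain, together with the
  remaining speckle noise at the standard ten-seed compounding, dominates
  the tracking errors the acceptance script reports.
* Non-Newtonian rheology, turbulence, 3-D curved/bifurcated geometry,
  attenuation and thermal noise are out of scope.
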