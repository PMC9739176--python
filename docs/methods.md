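# Methods

This note documents the models, numerical choices and limitations behind
`fohtrack`: what the tracker assumes, what the synthetic-field generator
does and does not emulate, and which design decisions were genuinely open.

## Coordinate conventions

All positions are relative to the centre of curvature of the convex probe.
Polar coordinates are range `r` (mm) and angle `theta` (degrees) from the
vertical axis, positive toward positive lateral `x`. Cartesian `y` is
axial and depth-positive (`x = r sin(theta)`, `y = r cos(theta)`), so depth,
range and image row index increase together; the screen-style axis
convention sometimes used for scan conversion (`y = r sin(theta − 90°)`)
differs only in the sign of `y`. The inverse map is `r = hypot(x, y)`,
`theta = sign(x)·acos(y/r)`. Scan lines are evenly spaced in angle over the
full field of view, endpoints inclusive; real imaging systems use
proprietary spacing, so this is a configurable surrogate.

The default probe has a 55° field of view, 300 mm imaging depth, 128 scan
lines and a 68 mm radius of curvature. The radius of the clinical probe is
not public; 68 mm is chosen so that the canonical accuracy grid (5 mm
lattice spanning depths 40–140 mm below the probe face on the right
half-plane, restricted to the fan) contains exactly 356 positions, the size
of the reference experiment. All values are configurable through
`ProbeGeometry` or the YAML probe config.

## Tracking pipeline

1. **Matched filter.** Each column is cross-correlated with a template of
   the received pulse, with group delay compensated so a pure-template
   column peaks at the template's start sample. The default template is the
   simulator's straight-needle (in-band) pulse; real deployments supply a
   measured template. Filtering is done per column in the frequency domain;
   the production path (`matched_filter_envelope`) fuses the correlation and
   the analytic signal into one FFT pass and is cross-checked in tests
   against the sequential operations.
2. **Envelope.** Magnitude of the analytic (Hilbert) signal — ripple-free
   for band-limited pulses.
3. **SNR gate.** Frame peak over the common noise RMS (measured from
   transmitter-off frames, processed the same way). The default gate is
   16 dB: the expected peak of a pure-noise frame of ~2.5×10⁵ samples is
   ~5σ ≈ 14 dB re the noise RMS, so a 16 dB gate rejects noise-only frames
   with probability well above 99.9% while passing ~30 dB tissue frames. A
   12 dB gate, sometimes suggested for this purpose, sits *below* the
   noise-peak expectation and would pass pure noise almost always.
4. **Angle.** Column energies are thresholded at −6 dB relative to the
   maximum (preventing noisy lines from biasing the estimate); the centre of
   mass of the surviving distribution is `theta_bar` and its energy-weighted
   standard deviation is `sigma_theta`. The spread uses the weighted RMS
   deviation with a √(N′/(N′−1)) small-sample factor, N′ being the number of
   non-zero-energy columns; a literal reading of the ambiguously typeset
   alternative (divide the weighted sum of squares by N′(N′−1)·Σe) is
   available as `spread_variant="printed"`. Centre of mass is used when the
   maximum column energy is ≥ 6 dB above the median column energy (a zero
   median counts as unbounded dynamic range); otherwise the maximum-pixel
   angle is used.
5. **Range.** Time of arrival on the maximum-energy surviving column,
   restricted to a gate of ±8 template lengths around the global peak so the
   cumulative energy is not biased by the noise floor. The onset rule
   (`t_0.1 − 0.125 δt` on the cumulative energy, linear interpolation
   between samples) is exact for flat-envelope pulses. Because the
   matched-filtered envelope is symmetric about the raw pulse position, the
   onset measured on a processed column is offset by a fixed,
   template-dependent amount; `toa_template_offset` calibrates this offset
   by passing a clean copy of the template through the identical chain and
   subtracting. Without this calibration the range would be biased by about
   half a pulse length (≈1 mm at 2 MHz).
6. **Scan conversion.** `K_{r,s} = diag(σ_r², (r tan σ_θ)²)` is the
   covariance in local Cartesian axes aligned with the scan line (radial,
   tangential); rotation by `φ = θ − 90°` maps it to image axes, putting all
   radial uncertainty on the axial axis when the tip is on-axis. The
   rotation is exact for displacements expressed in the local axes; when
   σ_θ is large (≳2°) and the tip is near the axis, resampling `(r, θ)`
   through the nonlinear map inflates σ_y by a curvature term of order
   `r σ_θ²`, which linear propagation deliberately excludes.

Invalid frames (gated out, zero-energy, or out-of-fan results) yield
`valid=False` and are excluded from error/repeatability metrics with their
count reported; content-related failures never raise.

## Synthetic field generator

The generator is a forward model of what the needle-tip hydrophone receives,
not a diffraction simulation. Per scan line the clean waveform is the pulse
scaled by

* a lateral Gaussian beam profile `exp(−Δθ²/2w_lat²)` with
  `w_lat = 0.8° + 0.008 °/mm · |depth − focal_depth|`,
* an elevational Gaussian profile `exp(−z²/2w_elev²)` with
  `w_elev = 6 mm + 0.05 · |depth − focal_depth|`,
* an optional attenuation factor `10^(−α d_cm f_MHz / 20)` (α = 0 for water
  scenes, 1 dB·cm⁻¹·MHz⁻¹ as a tissue-like setting),

inserted so that its cumulative-energy onset falls at
`trigger_to_transmit_delay + (r − ρ)/c`, with white Gaussian noise whose
RMS realises the requested peak-SNR. The piecewise-linear "hourglass" beam
widths, minimal at the focal depth, are modelling choices fixed once from
the qualitative focal-depth contrast of the reference out-of-plane
experiment; they are not claims about any hardware.

The transmit pulse is a Gaussian-windowed 2 MHz sinusoid (60% fractional
bandwidth at −6 dB, sampled at 10 MHz). When the needle is angled, a second
Gaussian-windowed component at 0.5 MHz is added with gain ramping linearly
from 0 at 0° to 0.67 at 40° (flat beyond), calibrated so the raw received
amplitude rises by 67% between 0° and 40° while the matched filter, which
rejects the low band, keeps the processed amplitude flat to within ±10%.
Both components are sampled on a grid containing t = 0 so their peaks align
exactly.

Dataset generators reproduce the reference experiment designs: the 5 mm
accuracy grid (356 positions, 18 frames each), the elevational sweep (−36 to
36 mm in 1 mm steps, 73 positions, two focal depths) and the needle-angle
sweep (thirteen angles, 0–60°, tip on axis 150 mm below the face). Frames
are generated lazily from per-(position, frame) seeds spawned from the base
seed, so datasets are deterministic and never need to be held in memory.

**What the generator does not emulate:** needle-shaft echoes, reverberation
and side-lobe artefacts, sound-speed heterogeneity and aberration, focal
apodisation, element directivity, or any probe-specific transmit sequence.
Passing tests therefore demonstrate that the *algorithms* are correct and
self-consistent under the stated statistical model, not that the pipeline
achieves the same numbers on clinical hardware; hardware systematics
(trigger-delay miscalibration, sound-speed error, probe alignment) are
exactly the terms absent here, which is why simulated accuracy figures are
compared against measured in-water figures as upper bounds.

## Evaluation harness

Tracking error at a location is the componentwise mean of tracked minus
true positions over repeated frames (Cartesian and polar), with the
Euclidean norm as headline magnitude — vector-first, then magnitude; the
magnitude-first alternative can be computed from the per-frame table.
Repeatability is the per-axis sample standard deviation (n−1). Spatial
summaries are means/standard deviations/percentiles (linear interpolation
between order statistics) of per-location magnitudes. Repeat-experiment
uncertainty is std/√N over repeats. The tangential repeatability reported
for grid runs is `r · std(θ)` in radians, making the radial/tangential
comparison dimensionally direct.

The optional Kalman smoother runs a standard linear filter on the (x, y)
pair with a constant-velocity (or constant-acceleration) state per axis,
white-noise acceleration (jerk) process noise, and each frame's propagated
2×2 covariance (floored at 1e−12 mm² for conditioning) as measurement
covariance; invalid frames are predict-only. The default process noise of
1 mm²·s⁻³ gives a roughly 3× RMS reduction on stationary tracks with
high-SNR-scale jitter; it is a configurable trade against lag.

## Known limitations and edge behaviour

* The centre of mass is biased toward the fan interior when the beam's
  −6 dB support is truncated by the fan edge (measured −0.67° with the tip
  exactly on the edge line at 200 mm range). Round-trip recovery guarantees
  therefore apply to poses whose beam support lies inside the fan; grid
  metrics include edge positions, where this bias contributes to the
  spatial error map just as it would physically.
* Sub-sample range accuracy relies on the received pulse matching the
  template shape; a mismatched template degrades the onset calibration
  gracefully (bias bounded by the envelope asymmetry) but is not corrected.
* The elevational model is symmetric in ±z, so simulated out-of-plane
  curves cannot reproduce asymmetries seen on real probes, and nothing in
  the pipeline infers the sign of the elevational offset.
* Isotropic pixels are assumed in image calibration; anisotropic displays
  are out of scope.

## Problem sizes used in the shipped checks

The grid experiment is run at desk scale — every 2nd of the 356 positions
and 6 frames per position at 60 dB SNR (≈1,100 frames, ~20 s on one CPU) —
which leaves the spatial means within a few percent of the full-protocol
values; the full 356×18 protocol is available through
`scripts/acceptance.py --position-step 1 --frames-per-position 18`.
Monte-Carlo covariance checks use 10⁵ samples; formula-fidelity checks use
100 random inputs at 1e−9 relative tolerance.
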