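# Methods

## Scope and intent

`sobpkit` reimplements the computational layer that sits on top of
Monte Carlo transport in a double-scattering proton commissioning
workflow: building spread-out Bragg peaks (SOBPs) from per-step
pristine-peak libraries, timing beam pulses on the rotating range
modulator wheel (RMW), adjusting modulation width with stop pulses, and
extracting/reporting the scalar beam metrics used to compare simulated
with measured data.  Particle transport itself, nozzle geometry,
detector response and absolute dosimetry are out of scope; a synthetic
beam model supplies curves with the statistical structure the analysis
needs.

## Synthetic pristine peaks

A pristine peak is modeled as a Bragg–Kleeman stopping-power shape
`D₀(d) ∝ (R − d)^(1/p − 1)` with p = 1.77 (protons in water), plus a
linear background ramp `b·(1 − d/R)` and a constant entrance pedestal
`e` on [0, R), convolved with a Gaussian of width σ (cm).  σ is a
depth-space proxy for the beam's energy spread (roughly
σ ≈ 2.5·(ΔE/E)·R): enlarging it lowers the smeared peak while leaving
the entrance untouched, so the *normalized* entrance dose PDD(0.5) and
the distal 80–20 falloff both increase — the qualitative behaviour a
commissioning physicist exploits when tuning a source model, and a
tested invariant here.

Numerics that matter:

- The convolution runs on an internal 0.01 cm grid.  The integrable
  singularity at d = R is handled by exact cell averaging of the
  antiderivative; the array is normalized by the *analytic* average over
  an aligned peak cell rather than the grid's maximum cell, which would
  jitter with the sub-cell position of R (that jitter is visible as
  non-monotone PDD(0.5) versus σ otherwise).
- The stopping-power shape is evaluated on a domain extended upstream
  of d = 0 (the curve continues smoothly into the nozzle material), so
  the convolution has no artificial truncation dip at the surface; the
  result is cropped to d ≥ 0.
- The distal 90% crossing is calibrated to the requested range by a
  bracketed Brent solve on an internal range shift (a plain fixed-point
  update oscillates at large σ).  Calibration error is below 0.005 cm,
  against a 0.02 cm contract.
- Defaults: σ = 0.3 cm for standalone peaks (σ = 0.2 cm in the SOBP
  synthesis pipeline), e = b = 0.0075, fluence 3×10⁶ protons per wheel
  step.  The pedestal values were chosen once so that a pristine peak's
  PDD(0.5) sits near 25% and a full-modulation SOBP's entrance plateau
  stays a few percent below the 95% level, as commissioning data shows;
  they are not refit anywhere.

Lateral profiles are `P(x) = [Φ((x+L/2)/σₚ) − Φ((x−L/2)/σₚ)]·(1+r(x))`
with Φ the standard normal CDF, giving an exact per-side 80–20 penumbra
of 1.6832·σₚ for wide fields.  The optional cosine ripple r(x) has one
full period across the middle-80% window, so its amplitude in percent
equals the profile's flatness — convenient for constructing metric
oracles.  Measurement noise is per-point multiplicative Gaussian with
an explicit seed, clipped at zero, with no autocorrelation: the
simplest model consistent with point-by-point scan data.

## Wheel, pulses, fluence

Wheel angles are degrees in [0, 360) increasing in the rotation
direction; pulse k's centre angle is `(phase + 6·rpm·k·period) mod 360`.
A point pulse lands wholly on the step containing its angle; a
finite-width pulse (uniform angular footprint) is split across steps in
proportion to angular overlap — the "partial shining" case.  Overlap
with a blocked step (the brass beam-stop wedge) is dropped.  Angles not
covered by any step raise an error rather than silently losing fluence.

Fluence equalization mirrors the machine's beam current modulation:
each hit step receives the same proton total regardless of its pulse
count.  When no pulse straddles a boundary the per-pulse weights are
closed-form; with straddling pulses the underdetermined system is
solved by iterative proportional scaling, which converges geometrically
to strictly *positive* weights.  (A non-negative least-squares solve
would satisfy the totals too, but returns a sparse vector — most pulses
switched off — which is unphysical for a BCM and destroys the
granularity of the stop-pulse procedure.)

The default wheel factory builds uniform angular sectors with uniform
pullback increments; the real wheels' proprietary step layouts are not
claimed.  For stop-pulse work the last sector should be a blocked
wedge, as on the real wheel: besides stopping the beam it separates the
thickest from the thinnest step, so no pulse footprint can couple the
extremes of the pullback range across the 0°/360° seam (such coupling
makes removing a "shallow" pulse renormalize the deepest peak and
produces a spurious width increase).

## SOBP synthesis

`fit_weights` resamples peaks and target onto the 0.1 cm lattice of the
fit window and solves the non-negative least-squares problem with
`scipy.optimize.nnls` — convex, deterministic, no initialization.  The
default window runs from 0.5 cm to the depth where the target first
falls below 1% of its maximum (excluding surface artifacts, covering
the whole compared region); the all-zero target returns zero weights.

The end-to-end `synthesize_sobp` pipeline makes three design choices
that an idealized flat target forces:

- **Pullback pitch 1.2 σ.**  Summed peaks scallop; with the
  Bragg–Kleeman shape the inter-peak ripple drops below ~1% once the
  pitch is ≲1.2 σ (85 peaks for the 25/20 cm case).  The pullback span
  stops 0.5 cm short of zero range, where the peak model degenerates.
- **Distal taper 3.3 σ.**  The SOBP's distal edge cannot fall faster
  than the deepest pristine peak; a target taper much sharper than that
  natural falloff forces an overshoot at the distal shoulder.  A cosine
  roll-off of length 3.3 σ matches the deliverable edge, positioned so
  the target's own D90 equals the requested range.
- **Proximal taper, 95% point pinned to range − modulation.**  With a
  plateau-only fit window the composed curve's proximal edge crosses
  95% below the plateau start, overshooting the width; with the
  sub-plateau region *in* the window the fit collapses (the target is
  zero there but any composition carries tens of percent of entrance
  dose, an unreachable constraint that tilts the whole plateau).  The
  resolution is a cosine proximal roll-on (default 1.6 cm) whose 95%
  point sits exactly at range − modulation, with the window starting at
  the plateau edge.  Modulation width then lands within ~0.1 cm of the
  request for all three reference cases.

`flat_target` keeps simple defaults on its own (0.3 cm distal taper,
sharp proximal edge, zero sub-plateau dose) when used directly.

## Stop pulses

Removing pulses shallowest-landing-peak-first (ties broken by
descending pulse index) tabulates SOBP width against stop-pulse count.
Per-peak weights are scaled by the ratio of remaining to full step
fluence, so the fitted SOBP weights and the BCM pulse weights compose
cleanly.  Tabulation stops when the width becomes undefined or *rises*:
once the plateau has shrunk to the scale of one pullback step the
prox-95 crossing becomes degenerate and sub-millimetre width wiggles
appear; truncating there keeps the curve monotone where it is
meaningful.  `adjust_modulation` brackets a requested width between
integer stops, interpolates the fractional stop pulse, scales that one
pulse's fluence, and recomputes the achieved width from the recomposed
curve.  Over a 2–20 cm sweep in 0.1 cm steps the achieved width is
within 0.1 cm of the request at every point of the reference fixture
(57 material steps + wedge, ~51 pulses/rotation precessing over 5
rotations for ~4.5 pulses per step).

## Metrics and reporting

All level crossings use linear interpolation between grid samples;
distal crossings take the deepest, proximal the shallowest (robust to
noise-induced multiple crossings; an optional window-3 median prefilter
exists, off by default).  A curve already at or above the level at its
first sample reports the proximal depth as that sample — the
full-modulation case.  SOBP curves normalize to max = 100; profiles
normalize to 100 at the field centre (midpoint of the 50% crossings),
so an off-centre ripple maximum may exceed 100.  Flatness and symmetry
are reported as absolute values (their defining differences are signed,
but QA tables list magnitudes), with "field size" for the middle-80%
window taken as the FWHM and symmetry integrals running over the
middle-80% halves.

Comparison rows follow the measured − simulated sign convention for
range and width differences; entrance-dose, penumbra and FWHM
differences are absolute.  Group summaries average absolute values.
Rounding to table precision (1 dp for percent, 2 dp for cm) happens
only in the rendered view; full precision is retained internally and
never fed back into computation.

The 24-configuration registry stores the three group envelopes (large:
range 5–25 cm / modulation 2–20 cm; deep: 20.1–32 / 2–10; small: 5–20 /
2–20) and uses the commissioning dataset's measured D90 values as
nominal ranges, with a 0.15 cm grace on registry self-validation since
a measured D90 may sit slightly past the nominal group maximum.
Requested range/modulation values are validated strictly.

## What the synthetic data does and does not show

The generator reproduces the *structural* properties the analysis
relies on — calibrated ranges, energy-spread monotonicity, flat fields
with analytic penumbras, seedable detector-like noise — but not the
physics a transport code provides: no nuclear buildup shape, no
scatter-dependent penumbra growth with depth, no field-size effects, no
detector volume averaging.  Passing tests therefore validate the
algorithms (fitting, pulse arithmetic, metrics, reporting) and the
published tables' arithmetic, not agreement between this beam model and
any real machine.  Known limitations: the entrance region of the
Bragg–Kleeman shape is flat rather than gently rising, so synthesized
full-range SOBPs carry a somewhat higher entrance plateau than measured
curves; wheel step layouts are generic; and the width metric becomes
ill-conditioned when the plateau shrinks below about two pullback
steps, which the stop-pulse tabulation handles by truncation.
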