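# Methods

## Physical model

`gelstream` models continuous-flow fractionation of sub-10-kbp dsDNA in an
agarose-filled chamber driven by two alternately applied electric fields of
very different magnitude, roughly 90° apart. Three ingredients set the
physics:

1. **Biased-reptation mobility.** In a sieving gel the electrophoretic
   mobility μ of a DNA chain depends on both the field strength E and the
   contour length L (0.34 nm per base pair): longer chains wrap gel fibers
   and drag more, while stronger fields stretch chains along the field and
   speed them up. The package represents μ(E, L) either as a parametric
   family

       μ(E, N) = μ₀ · [1/(3N) + β E² / (1 + γ E²)],   N = length_bp / kuhn_bp,

   (non-decreasing in E, non-increasing in length by construction, with
   N the chain length in Kuhn segments, kuhn_bp = 300 by default for the
   ~100 nm Kuhn length of dsDNA), or as a calibration table of
   (E, length, μ) triples interpolated bilinearly in (E, log length).

2. **Reorientation kinetics.** After a field-direction switch a chain needs
   t_or = L/(μE) to realign; the reorientation frequency is
   f_or = 1/(2 t_or) = μE/(2L). A fragment driven faster than f_or in a
   given field never completes reorientation and loses that field's
   displacement. At 50% duty this removes 2fL from the per-field speed:
   v_eff = max(μE − 2fL, 0).

3. **Migration angle.** The net trajectory angle from the collection (x)
   axis is the time-weighted vector sum of the two per-field displacement
   segments,

       Φ = atan2(v₁ sinθ₁ + v₂ sinθ₂, v₁ cosθ₁ + v₂ cosθ₂),

   which reduces exactly to the mobility-free ion angle
   Φ₀ = atan2(E₁ sinθ₁ + E₂ sinθ₂, E₁ cosθ₁ + E₂ cosθ₂) when f = 0 and
   μ₁ = μ₂. A published variant of this arctangent with a minus sign in
   the denominator is inconsistent with that reduction; it is kept behind
   `convention="as_printed"` for comparison only, and the vector-sum form
   is the default. When both effective velocities clamp to zero the
   dead-time model predicts no motion; the result is flagged
   `no_net_motion` and the angle falls back to the field-weighted average
   direction computed with the fragment's own per-field mobilities, since
   a never-reorienting coil responds to the time-averaged force.

Separation happens in two regimes. Below the weak-field f_or
(*field-dependent mobility*): Δμ = dμ/dE·(E₁−E₂) grows with length, so the
quasi-static vector sum differs by length. Between the weak- and
strong-field f_or (*switchback window*): the 2fL dead-time loss is
length-dependent, deflecting long fragments toward the strong-field
direction. `classify_regime` labels each (f, fragment) pair accordingly,
with the window boundary inclusive upward.

## Synthetic calibration table

The packaged table (`synthetic_calibration_table`) is **synthetic** — the
measured mobility curves it emulates were published only graphically. It
uses μ(E, L) = A(L)·(1 + b(L)·E²/(E_s² + E²)) with E_s = 60 V/cm on a
9-field × 5-length grid (5–134.6 V/cm, 0.5–10 kbp), built to reproduce the
qualitative structure of field-dependent mobility measurements in 1.2%
agarose:

- μ increases with E and decreases with length everywhere on the grid;
- the mobility gain Δμ between 59.5 and 22.4 V/cm strictly increases with
  length over 0.5–5 kbp (A decreasing, A·b increasing);
- b(5 kbp) = b(10 kbp), so those two lengths share exactly the same
  strong/weak mobility ratio and cannot be separated quasi-statically —
  they co-migrate at f → 0 (four streams) and split at 2 Hz, where the
  10 kbp fragment is weak-field-clamped (five streams);
- the 10 kbp scale is anchored so μ(59.5 V/cm) = 2.75 × 10⁻⁵ cm² V⁻¹ s⁻¹,
  the value implied by a 2.4 Hz reorientation frequency at that field.

Absolute values are plausible for 1.2% agarose (3–10 × 10⁻⁵ cm² V⁻¹ s⁻¹)
but are not fits to any measured dataset; only trends and the one anchor
are meaningful.

## Stochastic stream simulation

Particles enter at x = 0 with y drawn from a 110 μm top-hat injection band
(the documented injection-channel width; Gaussian widths can be emulated by
the caller) in a 1 × 1 cm chamber. Per half-cycle a particle first sits
through min(t_or, half-period) of reorientation dead time with zero net
displacement — the choice that reproduces the −2fL loss term exactly —
then translates at μᵢEᵢ along the active field direction. Isotropic
diffusion adds a Gaussian kick of variance 2DΔt per segment. A particle
terminates at its first (linearly interpolated) crossing of the collection
edge x = W or of the bottom edge y = H; `collected` records which.

**Injection phase.** Particles enter mid-cycle with probability
proportional to their instantaneous forward x-flux (flux-weighted phase),
the correct statistical model of steady injection across a fixed plane.
Time-uniform phase would leave an O(excursion/W) systematic offset
(~0.01°) between the mean exit angle and the analytic Φ, because exit
phases at a fixed plane are flux-weighted while entry phases would not be;
flux weighting removes it to < 0.001° at n = 5 × 10⁴. Set
`random_phase=False` to phase-lock all particles to the start of a
field-1 half-cycle (used for single-trajectory excursion measurements).

**Diffusion default.** `diffusion_coeff` defaults to 0 (band spreading in
this regime is dominated by injection width and the sawtooth). Monte-Carlo
consistency runs use D = 2 × 10⁻⁸ cm² s⁻¹, a realistic zero-field thermal
diffusivity for sub-10-kbp DNA in 1.2% agarose, giving the exit ensemble
its physical noise floor; without it the zig-zag trajectories are
quasi-deterministic and a standard-error comparison is degenerate.

**Performance.** While every particle is farther from any boundary than
its within-period path extent plus 7 diffusion standard deviations, whole
periods are fast-forwarded by dead reckoning (drift plus one aggregated
Gaussian kick); this is exact up to a first-crossing tail probability of
~10⁻¹² per particle-period and makes n = 2000 runs take well under a
second per protocol.

**Band broadening.** The closed-form per-period transverse excursion is

    L_fr = 0.5 · (μ₂E₂ / f) · (tanθ₁ cosθ₂ + sinθ₂),

reported in μm and as a fraction of the injection band. Note a convention
subtlety: the geometric y-deviation of the sawtooth from the strong-field
line is s₂·(sinθ₂ − tanθ₁ cosθ₂); the two coincide only when cosθ₂ enters
with flipped sign (θ₂ read as its acute supplement) or exactly at
θ₂ = 90°, where the simulator-measured excursion matches the closed form
to 0.1%. The closed form is implemented verbatim; the consistency test is
run at θ₂ = 90° so it validates the prefactor and the 1/f scaling without
committing to either angle convention.

## Measurement chain

Mirrors standard fluorescence quantitation of gel streams:

- **process_image** — per-image median background subtraction (robust when
  bright streams are sparse; rolling-ball available), Gaussian smoothing
  with σ = 1 px truncated to 5 × 5 support, then a linear contrast
  stretch saturating 1% of pixels at each end (2% total). The stretch is
  for display; quantitative profiles are taken with
  `contrast_stretch=False` since stretching distorts integrals.
- **extract_profile** — vertical line scan at a fixed column, averaged
  over 5 columns by default. On images of angled streaks, column
  averaging smears each ridge by slope × width × pixel pitch; use a
  narrow window or fine column pitch when streams are close.
- **fit_peaks** — least-squares multi-Gaussian fit with constant
  baseline, initialized from the most prominent local maxima of the
  lightly smoothed profile (prominence floor 0.1% of range, relaxed if
  too few maxima are found). Non-convergence raises a diagnostic error.
- **resolution** — Rs = |Δcenter| / (2σ₁ + 2σ₂).
- **overlap/purity** — two equal-area, equal-σ unit Gaussians at
  separation 4σRs cross at 2Rs from either center; the misassigned
  fraction is the standard normal survival function Q(2Rs).
  overlap = 100·Q(2Rs), purity = 100 − overlap. This model reproduces a
  published four-row purity table at its printed 1-decimal precision from
  the printed resolutions {1.3, 0.6, 1.0, 1.4}; tiny discrepancies in the
  2-decimal overlap column (e.g. 11.51 vs 11.50) are consistent with the
  printed Rs being rounded.
- **recovery** — trapezoidal integration of baseline-subtracted intensity
  over each fitted ±3σ window, outlets summed and divided by the inlet,
  ×100.

Report rounding follows the field's table conventions: Rs and purity to
1 decimal, overlap to 2.

## Parameters that matter

| parameter | units | default | note |
|---|---|---|---|
| E₁, E₂ | V cm⁻¹ | — | strong/weak field; E₁ ≥ E₂ > 0 enforced |
| θ₁, θ₂ | deg from x | — | ~90° apart in the experiments emulated |
| f | Hz | — | 0 denotes the quasi-static limit |
| duty | — | 0.5 | fraction of period in field 1; ≠0.5 generalizes the 2fL loss to fL/duty per field (an extension beyond the published model) |
| kuhn_bp | bp | 300 | Kuhn-segment size; only qualitative trends depend on it |
| chamber | cm | 1 × 1 | 10 × 10 mm separation chamber |
| injection band | μm | 110 | top-hat width at x = 0 |
| diffusion D | cm² s⁻¹ | 0 | 2 × 10⁻⁸ in MC consistency runs |
| derivative stencil | — | h = 1% of local E spacing | central, one-sided at edges |
| Δμ evaluation point | — | (E₁+E₂)/2 | second-order midpoint convention |

## What the synthetic data do and do not show

The generator reproduces: length- and field-dependent mobility trends, the
two separation regimes and their stream counts, sawtooth band broadening,
injection-width-dominated stream widths, and Poisson-noise fluorescence
images with known ground truth. It does **not** model: spatial
nonuniformity of the real field (published finite-element results show the
inter-field angle tightening to ~60° and the field ratio rising to ~3.1
near collection — a known systematic that makes measured angles exceed
uniform-field predictions), electroosmosis, Joule heating, gel
heterogeneity, dye chemistry, or absolute fluorescence calibration.
Passing tests therefore validate the model's internal consistency and its
agreement with published worked numbers, not quantitative prediction of
any particular device image.

## Numerical choices and degenerate inputs

- Angles are degrees at every interface, radians internally; one shared
  coordinate frame (x toward collection, y along the collection line,
  counterclockwise angles).
- Table interpolation is exact at grid nodes (nodes are returned
  untouched, not re-interpolated); queries outside the grid raise a range
  error naming the offending axis unless clamped-edge extrapolation is
  explicitly enabled.
- θ₁ = 90° makes the closed-form excursion singular → domain error.
- Both-clamped protocols with no diffusion refuse to simulate ("no
  transport") rather than spin forever; with diffusion a transit-time
  cap raises instead.
- Zero-σ peaks, inverted f_or orderings, non-positive fields/mobilities
  all raise domain errors rather than propagating NaNs.

## Problem sizes

Monte-Carlo consistency uses a 3 × 3 protocol grid (E₁ ∈ {44.8, 59.5,
89.8} V cm⁻¹ with E₂ = E₁·22.4/59.5, f ∈ {3, 5, 8} Hz) at n = 2000
particles, and the image round trip uses n = 5000 particles on a
1024 × 128 synthetic micrograph; both chosen as the smallest ensembles at
which the standard errors are an order of magnitude below the effects
being checked.
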