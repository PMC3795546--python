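# Methods

This note records the model, the numerical choices, and the reasoning
behind the defaults, at the level a maintainer or reviewer needs to judge
what the package's results do and do not show.

## Forward model

A vesicle is represented as n concentric regions of uniform excess
scattering density (contrast, units of 10¹⁰ cm⁻²). Region 1 is the water
pool; the wall regions model, inside out, a dense hydration layer (+), the
inner phosphocholine headgroups (+, high), the hydrocarbon core (−), the
outer headgroups (+, high) and, for glycolipid-bearing membranes, a
low-positive oligosaccharide layer protruding from the outer leaflet.

The spherical amplitude is the annular-region sum

    A(q) = Σᵢ Δρ̄ᵢ [V(rᵢ)Φ(qrᵢ) − V(rᵢ₋₁)Φ(qrᵢ₋₁)],   Φ(x) = 3j₁(x)/x.

The algebraically identical boundary-difference form (each boundary carries
the contrast step across it) is implemented independently in the test suite
and used as an oracle; the two conventions sum the same piecewise-constant
density. Ellipsoids of revolution (axial ratio νᵢ) keep their true volumes
(4/3)πνᵢrᵢ³ in the amplitude while the Φ argument uses the
orientation-dependent effective radius rᵢ√(1 + x²(νᵢ²−1)); the intensity is
the Gauss–Legendre average of |A|² over x ∈ [0, 1] (64 nodes). This
convention makes I(0) exactly the squared net excess mass, independent of
orientation, and reduces to the spherical case at ν = 1 to quadrature
precision.

### Polydispersity

The outer radius follows a Gaussian number distribution (mean R̄, sd σ)
truncated at R_min and renormalized on [R_min, ∞). D(R) multiplies I_s
directly — I_s already carries the V² weighting, so no extra volume
weighting is applied. As R varies, the wall keeps fixed thicknesses and
only the water pool scales ("pool" mode); this is the physically motivated
choice because the lower size cutoff is the wall itself (R_min < wall
thickness is rejected). A proportional-scaling mode exists for sensitivity
checks. The R integral uses Gauss–Legendre on [max(R_min, wall), R̄ + 6σ]
with 201 nodes by default; tests pin it against a 2000-node Riemann sum at
1e-4 relative. Note the integrand oscillates in R with period ~π/q, so
fits that go to q = 0.2 Å⁻¹ should not reduce the node count much below
~150 (a 51-node quadrature already shows ~5 % curve-level errors).

The interpretation of "mean radius 400 Å" as the mean *outer* radius (not
the pool radius) is an assumption; both are reachable because the pool
radius is R minus the wall.

## Distance distribution

p(r) = (r/2π²) ∫ q I(q) sin(qr) dq, trapezoid on the curve's own grid, with
two windowing choices:

- **High-q taper** (default on): half-cosine roll-off over the last decade
  of q. Without it, truncation ripples contaminate exactly the sub-bilayer
  region (r ≲ 60 Å) where the wall's alternating-contrast oscillation
  lives.
- **Low-q Guinier extension** (default on): the unmeasured [0, q_min)
  segment is filled with exp(a + bq²) fitted to the lowest points
  (q ≤ 1.6 q_min, 5–20 points). For vesicles with D_max ≈ 1500 Å measured
  from q_min = 0.003 Å⁻¹, the missing segment otherwise injects
  oscillations of period 2π/q_min that can displace the global maximum to
  the edge of the r grid. This extension is standard practice for direct
  transforms; it makes the transform nonlinear in I, so the linearity and
  round-trip properties are tested with it disabled.

An aliasing guard rejects grids with max(Δq)·r_max > π. The peak position
is refined by a 3-point parabola around the discrete maximum. The
"ripple extent" is the largest r below the global maximum at which the
sign-alternating oscillation (amplitude ≥ 0.2 % of max |p|, ≥ 2 sign
changes) is last visible; a solid body reports 0.

## Guinier analysis

Weighted linear regression of ln I on q² ((I/σ)² weights when σ is
present), iterated so the window satisfies q·Rg ≤ bound. The default bound
is **0.5**, deliberately tighter than the classic 1.3: for a homogeneous
sphere the truncation bias of a window reaching q·Rg = 1 is already +1 % of
Rg (313 vs 309.8 Å for R = 400 Å) no matter how the in-window points are
weighted, and vesicle curves bend away from the Guinier law even earlier.
At 0.5 the bias is ≤ 0.3 % for both compact and hollow particles while
polydisperse vesicle grids still retain dozens of points. The bound is
configurable. For strongly contrast-cancelling profiles (Rg much smaller
than the particle) no Guinier regime exists at all; the analysis makes no
claim there.

## Shell-model fitting

Residuals are log-intensity differences (the curves span ~4 decades and
both the low-q shoulder and mid-q wall features must be matched),
uncertainty-weighted when σ is available, minimized by bounded
trust-region-reflective least squares from a caller-supplied start. This is
a deterministic local refinement of a physically motivated model — no
global search, matching how shell models are used in practice. A free
global intensity scale (log₁₀-parametrized) is always available because
solution SAXS data are relative; note this leaves the contrast profile
determined only up to one global factor (scale absorbs its square), so
contrast-recovery statements are made either with the scale frozen or on
the core-normalized shape. The default fit range caps at q = 0.2 Å⁻¹;
above that the spherical-shell idealization, not the data, dominates the
residual. Goodness of fit is reported as R = Σ|I_obs − I_model|/Σ I_obs on
the fit range; values of a few hundredths indicate a curve tracked at the
noise level.

## Occlusion analysis and encapsulation efficiency

Protein at volume fraction φ in the pool gives core contrast
φ(ρ_p − ρ_w); a mass concentration c (% w/v, grams per 100 mL of pool)
occupies φ = c·v̄/100. Defaults: ρ_w = 9.38, ρ_p = 11.85 (midpoint of the
11.7–12.0 range for globular proteins), v̄ = 0.73 cm³/g (typical globular
protein); all configurable, and estimates can be reported with a
sensitivity band over ρ_p ∈ [11.7, 12.0] and v̄ ∈ [0.70, 0.75].
Concentration is defined per water-pool volume.

The contrast sweep substitutes each value into the pool, computes the
polydisperse curve on a dedicated very-low-q grid (1.5e-4–4e-3 Å⁻¹) for
Guinier and on a wide grid for p(r). The efficiency relation tabulates the
decrement (Rg_empty − Rg(c))/Rg_empty on a concentration grid that spans
the full range to pool saturation (100/v̄ % w/v) with quadratic spacing —
the decrement is steepest at low occupancy, so nodes concentrate there.
Tiny numerical non-monotonicities (< 1e-3) are flattened by a running
maximum; larger ones raise an error advising denser quadrature. Inversion
is monotone PCHIP interpolation of concentration against decrement, exact
on the tabulated nodes.

## Synthetic data

The canonical fixture freezes thicknesses 6/9/24/9/12 Å (hydration, inner
head, hydrocarbon, outer head, sugar; 60 Å wall) and contrasts
+0.6/+2.5/−2.0/+2.5/+0.5, with R̄ = 400 Å, σ = 30 %, R_min = 60 Å. The
contrasts were chosen once, by the shipped `scripts/calibrate_fixture.py`
scan, to reproduce the observables that define an empty
ganglioside/cholesterol/egg-PC vesicle model: p(r) oscillation extending to
≈ 55 Å, a shoulder near q = 0.01 Å⁻¹ with a broad bump in 0.04–0.2 Å⁻¹, an
empty-model Guinier Rg in 500–650 Å, and p(r) maxima near 700 Å (empty) and
500 Å (pool contrast 2.6). The resulting net wall excess (Σtᵢρᵢ = 6.6
Å·units) is what sets the Rg sensitivity to core filling, and with the
default unit constants the fixture maps a 587 → 505 Å Rg drop to ≈ 6 % w/v.

Noise is σ_I = floor·I + scale·√I applied as Gaussian perturbations from a
seeded generator (defaults: 1 % relative floor, no counting term — the
visual noise level of a well-exposed synchrotron curve). An optional flat
`background` emulates the high-q plateau of real solution data left by
imperfect buffer subtraction; qualitative statements such as *where* free
protein changes a curve the most only reproduce the experimental picture
against that plateau. The mixture generator adds an independent
Guinier-sphere term for un-entrapped protein (default Rg 16 Å, the
globular-monomer scale) with a stated forward-intensity fraction.

What the generator does **not** emulate: instrumental smearing, absolute
calibration, inter-particle interference at high concentration, protein
adsorption to the wall, or aspherical deformation. Tests passing on these
synthetics therefore validate the numerics and the internal consistency of
the occlusion logic, not the treatment of those experimental effects.

## Problem sizes and determinism

Default grids: 1500-point q grids for wide curves, 160-point low-q grids
for Guinier, 201 radius nodes, 2001-point r grids to 2000 Å; the full test
suite and the acceptance script run in a few minutes on one CPU. All
randomness flows through explicit integer seeds; repeated runs are
byte-identical.

## Known limitations

- The fixture's contrast magnitudes are calibration products, not fitted
  experimental values; only their sign pattern and the derived observables
  are constrained.
- Encapsulation estimates inherit the ρ_p/v̄ assumptions linearly; the
  sensitivity band quantifies this.
- The direct transform (no regularized indirect transform) is faithful to
  the analysis it implements but is sensitive to the windowing choices
  documented above.
- Above q ≈ 0.2 Å⁻¹ the spherical multi-shell idealization deviates from
  real bilayer curves; WAXS-range features are out of scope.
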