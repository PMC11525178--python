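# Methods

## The measurement principle

An elastic cylinder embedded in living tissue is a spring with a known
constant. If its wall material has Young's modulus `E` (kPa) and the
printed geometry is height `H`, outer diameter `D`, wall thickness `t`
(µm), the diametral structural stiffness — contact force per µm of
mediolateral narrowing — follows thin-ring bending scaling,

```
k = α · H · (t/D)³ · E        [nN/µm]
```

with a single dimensionless constant `α` absorbing the load geometry.
Width change over time, measured from microscopy, then converts to force as
`F(t) = k · (width₀ − width(t))`, to stored elastic energy as the area
under the force–displacement path, and to an impulse summarizing the rate
of force generation. Everything in the package exists to produce, check or
consume this chain.

Units are µm / kPa / nN / pJ / minutes throughout the API; these are
mutually consistent (1 kPa = 1 nN/µm², 1 nN·µm = 10⁻³ pJ) so no hidden
conversion factors appear in the mechanics. All conversions live in
`morphoforce.units`.

## Ring contact model

The cylinder is reduced to its annular cross-section in 2D plane strain and
the resulting force per unit height is multiplied by `H`. This is justified
by the sensed load being diametral and by `H` entering the stiffness law
linearly; the residual 2D-vs-3D discrepancy is absorbed into the fitted
`α`. The tissue folds are two rigid, frictionless surfaces approaching
symmetrically along the mediolateral (x) axis. Three contact modes exist:
`flat_plates` (default; contact arc grows with load), `point_load` (the
classical ring-bending configuration, used for validation), and
`conforming_arc` (rigid surfaces hugging the undeformed outer wall over a
configurable half-angle, emulating distributed tissue contact — note that
this mode is dramatically stiffer and is not the calibration default).

**Material.** The hydrogel is modelled as an isotropic, nearly
incompressible neo-Hookean solid. At the wall strains the solver actually
sees (a few percent, even at 25% diameter narrowing) the material response
is its linearization, with moduli `(E, ν)`; incompressible inputs
(ν = 0.5) are represented as ν = 0.4995 in plane strain, making the
volumetric stiffness ~10³ × the shear stiffness — numerically
indistinguishable from incompressible at the force resolution of interest.
The uniaxial incompressible closed form `σ = μ(λ − λ⁻²)` (with `μ = E/3`)
is available separately in `morphoforce.materials` and is the reference for
the stress–strain utilities.

**Elements.** The structured mesh (default 96 circumferential × 4 radial
bilinear quadrilaterals, node counts fixed by that layout) puts high-aspect
elements in bending, where plain bilinear quads shear-lock, and the near
incompressibility adds volumetric locking. The element therefore combines:

* Wilson/Taylor incompatible bending modes (two internal quadratic modes,
  statically condensed), with the centroid-Jacobian correction that keeps
  the patch test on tapered shapes;
* a volumetric/isochoric split of the elasticity tensor in which only the
  Lamé-λ (dilatational) energy is integrated on the element-mean in-plane
  dilatation. Averaging the full dilatational operator (classical B-bar)
  was rejected: at four elements through the wall it discards genuine
  bending energy (≈4.5% error on the ring oracle); the λ-only split leaves
  the compressible bending response untouched and still removes volumetric
  locking.

With this element the coarse default mesh reproduces the classical
diametral point-load stiffness of a thin ring (coefficient
`8/(12(π/4 − 2/π)) ≈ 4.481` at the wall mid-surface) to 0.2%, and
point-load stiffness changes by under 1% when the mesh is refined to
192 × 8 across the whole calibration range. Under flat-plate contact an
additional local compliance appears — the outer element row bending beneath
the localized surface pressure — which converges more slowly: flat-plate k
shifts by up to ~4% on the same refinement for the extreme sweep
geometries. The calibration is defined at the (96, 4) resolution; refining
the whole sweep would move the fitted constant by roughly that amount.

**Geometric nonlinearity** is corotational: each element carries its
precomputed small-strain stiffness plus the rotation extracted from the
deformation gradient at its centroid. This represents large rotations at
small material strains exactly to leading order — the regime of a ring
ovalizing between plates. The formulation was validated against an
independent inextensible-elastica boundary-value solution of the
point-loaded ring (generic ODE solver, no shared code): forces agree within
3% out to 20% diameter narrowing.

**Contact** is a frictionless penalty on the outer-surface nodes, stiffness
`penalty · E ·` (tributary arc length) per node with `penalty = 10³`, and a
C¹ quadratic force ramp over the first `5×10⁻⁴ t` of penetration — the ramp
removes the force-law kink that otherwise makes Newton cycle through
active sets. Penetration beyond `10⁻³ t` (including the ramp offset) raises
an error rather than silently softening the result.

**Solution.** Narrowing is displacement-controlled in increments of ≤1% of
`D`; each step is equilibrated by Newton iteration (tangent = rotated
element stiffness + active contact stiffness; the omitted geometric
stiffness only slows convergence) with backtracking line search on the
residual norm, to a residual below `10⁻⁸ · E·H·t`. Failed steps bisect up
to 16×. Forces on the two surfaces are tracked separately (they balance to
~10⁻¹⁰ relative) and external work matches stored strain energy to 0.1%.

## Calibration

`run_sweep` solves one ring per grid cell (default 3 values per parameter
spanning H 20–100 µm, D 140–220 µm, t 5–25 µm, E 5–80 kPa; 81 solves,
cacheable to disk for resumability) with flat plates, and extracts `k` as
the through-origin slope of the F–δ curve over δ ≤ 2% of `D` (the
"small-displacement" window; a fraction rather than an absolute value so
thin and thick sensors are treated alike). `fit_alpha` minimizes
`Σ (kᵢ − α xᵢ)²` with `xᵢ = Hᵢ(tᵢ/Dᵢ)³Eᵢ`, which has the closed form
`α = Σkx / Σx²`; a numeric optimizer mode exists and must agree to 10⁻¹⁰.
Unweighted least squares is the default (it weights the stiffest cells
most); a relative-error weighting mode is provided. On this grid the fit
gives α ≈ 7.5 with R² > 0.999 and a worst-case relative residual of ~24% —
the cubic law is a good global summary, not an exact solution, with the
thickest-wall cells (t/D up to 0.18, where thin-ring theory is strained)
carrying most of the residual.

The package ships `ALPHA_DEFAULT = 7.718` as the inference constant;
locally refitted values are always reported alongside, never silently
substituted.

## Inference definitions

* **Strain** (%): `100 · (width₀ − width) / width₀`; positive in
  compression, negative for widening sensors (e.g. under ROCK inhibition).
  The same `k` is used for widening traces — the linear regime is assumed
  symmetric about the printed width.
* **Linear range**: the constant-k conversion is flagged (not dropped)
  beyond |strain| > 20%; downstream summaries can exclude flagged points.
* **Energy** (pJ): trapezoidal integral of `F dδ` along the measured path.
* **Impulse** (nN·min): the defining phrase — force *generated* within each
  60-min window, multiplied by time — is read as
  `(F(t+60) − F(t)) · 60 min`, maximized over sliding windows. A constant
  force therefore carries zero impulse: the statistic compares rates of
  force generation, which is exactly how it separates treated from control
  cohorts. A classical `∫|F| dt` mode is available behind a flag.
* **ATP equivalent**: `energy / 10⁻¹⁹ J` (≈60 kJ·mol⁻¹ ÷ N_A); 1 pJ ≈ 10⁷
  molecules.
* **Cohorts**: profiles are linearly interpolated onto a common time grid,
  never extrapolated beyond a profile's own last timepoint; per-timepoint
  mean ± t-distribution 95% CI (CI omitted with a warning at n = 1).
  Two-group comparisons: equal-variance two-tailed t-test by default,
  Mann-Whitney U on request.

## Imaging

Stacks are maximum-projected on load. Frames register to the first frame by
subpixel phase correlation (translation; a rigid mode adds a small rotation
search over ±5°). Segmentation is global Otsu (or fixed) thresholding,
morphological closing, largest connected component, hole filling — the
filled footprint is the automated stand-in for an operator's manual
outline. Width is the bounding-rectangle x-extent × pixel size, image x
being the mediolateral axis. Missing detections become explicit NaN gaps,
never interpolation.

## Synthetic data

Trajectories use a saturating exponential `s(t) = s_max(1 − e^{−t/τ})`
(default plateau 8% of a 180 µm width, τ = 60 min, ~1 px of width noise)
— matching a force that rises to ~100 nN over one to two hours before
plateauing; a piecewise-linear mode exists for edge-case tests. Cohorts
draw per-embryo `s_max` and `τ` as nominal × mean-one lognormal multipliers
(default CV 15%, n = 10). Movies render an anti-aliased elliptical annulus
whose perpendicular axis bulges by `0.3 × strain` (the contralateral
elastic expansion of a squeezed ring), then apply optical blur, Poisson
shot noise, Gaussian read noise and scripted stage drift at 0.59 µm/px and
30-min steps. AFM curves come from the same pyramidal forward model the
fitter inverts. Generators are pure functions of (params, seed) and always
emit noise-free truth.

What the generators do *not* emulate: real tissue background and
autofluorescence gradients, sensor–tissue boundary ambiguity (an operator's
judgment near the contact), z-drift and projection artifacts, or any
biology of ROCK inhibition beyond the sign and rate of the width change.
Passing the end-to-end recovery tests therefore demonstrates the pipeline's
correctness on idealized-but-noisy data, not robustness to every real
imaging pathology.

## Frame solver

Bars and V-springs are solved as corotational Euler–Bernoulli frames
(exact nonlinear internal force; element tangents by central differences —
robust and cheap at these sizes). Perfectly straight columns receive a
10⁻³·L half-sine imperfection so buckling can break symmetry; the pinned
column's peak load reproduces the Euler load within 2%, and peak load
decreases strictly with initial mid-rise — the reason curved bars make
poor sensors and the cylinder is the calibrated shape.

## Numerical choices and degenerate inputs

Zero narrowing/shortening returns an exact zero curve. Meshes require
≥(96, 4) elements with the circumferential count divisible by 4 (symmetry
nodes). Geometry or modulus outside the calibrated ranges warns but
proceeds (the law becomes an extrapolation); `t ≥ D/2` is an error. Hertz
fits initialize the contact point at the first force exceeding 3× the
pre-contact noise SD and fit `log E` to keep the modulus positive.
Through-origin slopes are used wherever the physical reference state is the
origin (stiffness extraction, stress–strain linearity, uniaxial modulus
with a window containing zero).

## Known limitations

* **Large-strain linearity.** In this 2D reduction the flat-plate F–δ curve
  softens: the secant stiffness leaves a 10% band around the initial
  tangent at ~9–10% width strain, and sits ~19% low by 20% — confirmed
  independently by the elastica oracle, so it is converged large-deflection
  ring mechanics, not discretization. A full 3D cylinder with its actual
  tissue contact geometry can remain quasilinear further; treat
  constant-k forces between ~10% and 20% strain as approximations
  (the per-point validity flags use the 20% bound for compatibility with
  the established read-out convention, but the conservative user may
  exclude points beyond 10%).
* The sweep's thickest walls (t/D ≈ 0.18) are outside thin-ring theory;
  the cubic law misfits them by up to ~24% and the fitted α depends
  slightly on grid placement.
* Plane strain suppresses end effects of short cylinders; `H` linearity is
  exact in the model by construction, not verified in 3D.
* The imaging module measures projections only and assumes a single bright
  sensor; overlapping bright structures would need masking upstream.
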