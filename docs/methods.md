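# Methods

## Constitutive model

Cartilage is modeled as a biphasic mixture with intrinsically
incompressible solid and fluid.  Total stress is
`σ_t = σ_nf + σ_f − p I`.

* **Non-fibrillar matrix** — compressible Neo-Hookean solid with strain
  energy `W = μ/2 (I₁ − 3) − μ ln J + λ/2 (ln J)²`, parameterized by the
  modulus `E_nf` and a fixed Poisson ratio ν_nf = 0.42 (the conventional
  drained value for the proteoglycan gel; configurable).
* **Fibril network** — tension-only and strain-stiffening,
  `σ_f = (E_f0 + E_fε ε_f) ε_f` for ε_f > 0, else 0, where ε_f is the
  nominal strain along the fibril direction.  Fibrils are oriented parallel
  to the articular surface (the radial and hoop directions of the
  axisymmetric problem), homogeneous through the depth: a depth-dependent
  arcade is not identifiable from a single indentation record, and the
  indentation response is dominated by the surface-parallel superficial
  fibrils.  The fibril stress acts along the deformed fibril direction
  (Cauchy stress `σ_f m⊗m` with `m = F e_R/|F e_R|`).
* **Permeability** — void-ratio power law `k = k0 ((1+e)/(1+e0))^M`.  With
  incompressible constituents `(1+e)/(1+e0) = J`, so the solver uses
  `k = k0 Jᴹ`.  The initial void ratio defaults to e0 = 4 (fluid fraction
  0.8, typical for cartilage).  `k0` is exposed in 10⁻¹⁵ m⁴ N⁻¹ s⁻¹ and
  converted to mm⁴ N⁻¹ s⁻¹ internally (MPa/mm/s/N unit system throughout).

## Finite-element solver

Axisymmetric u–p formulation on structured meshes of rectangular
Taylor–Hood elements (9-node biquadratic displacement, 4-node bilinear
pressure; 3×3 Gauss quadrature), graded geometrically toward the indenter
rim where the contact-pressure gradient concentrates.  Kinematics are
finite-strain (total Lagrangian); the momentum residual integrates the
first Piola stress, and the mass balance integrates the backward-Euler
storage term `(J − J_old)/Δt` plus the pulled-back spatial Darcy term.
Boundary conditions: bottom fixed and sealed (bone interface), axis
symmetric, free draining on the outer radius and on the top surface outside
the indenter, sealed and displacement-driven under the indenter.

The Newton tangent is assembled from forward finite differences of the
element residual, evaluated for all 22 element dofs of all elements in one
batched vectorized pass; a strict-decrease backtracking line search, a
linear time-extrapolation predictor for the start iterate, and recursive
time-step bisection provide globalization.  Linear systems are solved by
sparse LU with symmetric diagonal equilibration.

**Contact.**  The indenter is represented by prescribing the axial
displacement of the surface nodes under the punch.  The default is
frictionless (`smooth`: radial displacement free), which matches the
assumption of the Hayes contact solution used for property extraction; a
`bonded` option constrains the radial displacement too.  At protocol depths
beyond ~20% strain the bonded variant develops near-singular surface modes
at the punch rim that quasi-static Newton cannot traverse.

**Numerical regularization.**  Two deliberate tolerances, both documented
because they bound the solver's fidelity rather than being free accuracy
knobs:

* the tension-only switch of the fibril law is blended quadratically over a
  2×10⁻³ strain half-width inside the solver (the raw kink causes
  active-set chatter and, worse, curvature that collapses the Newton
  radius); the stress perturbation is O(E_f0 · 10⁻³) MPa and identical in
  forward generation and inverse fitting;
* at deep indentation the discrete contact problem develops near-singular
  (surface-wrinkling-like) modes at the punch rim — a genuine feature of a
  homogeneous soft solid compressed >20% under a sharp flat punch, which
  real cartilage suppresses through depth-dependent stiffness that this
  model class omits.  These modes bound the attainable residual, so a
  stalled Newton iterate is accepted when its RMS residual is below 1% of
  the simulation's running force scale.  Cross-mesh comparison shows the
  effect on reaction forces is below ~0.5%.  Meshes refined beyond about
  twice the default resolution cannot traverse the full 22%-strain protocol
  at all; small-strain verification (consolidation, Hayes) therefore uses
  fine meshes where the problem is well posed, and protocol simulations use
  the default mesh, whose doubling error on the reference configuration is
  1.8%.

**Pre-stress seek.**  The experimental 12.5 kPa pre-stress ends in an
equilibrated contact state; the solver reproduces it directly as a
drained-equilibrium bisection on indentation depth (each trial is a static
solve), and transient records start from that state.

**Time grids.**  Ramps use uniform steps; 900 s holds use geometrically
growing steps; sinusoids use fixed steps per cycle.  Presets: `coarse`
(3/10/16 steps for ramp/hold/cycle — used for synthetic generation and
fitting, chosen so that a full-protocol forward solve takes seconds),
`default` (5/16/24), `fine` (8/24/32).  Inverse identification uses the
same preset for data generation and fitting in the recovery studies, so the
time-discretization error cancels exactly in the self-consistency tests.

## Hayes correction

The plane-ended punch on a bonded elastic layer carries
`P = 2 E a w κ/(1−ν²)`.  κ(a/h, ν) is computed by solving the mixed
boundary-value problem: the bonded-layer surface compliance in Hankel space
(derived from Love's stress function; it reproduces the classical kernel
with κ′ = 3−4ν) is combined with Sneddon's cosine representation of the
contact pressure, reducing the punch condition to an Abel equation plus an
exponentially decaying correction kernel, solved by collocation on an even
polynomial basis.  Results are cached per (a/h, ν); the solve itself is
milliseconds, so no interpolation table is needed.  Verified limits:
κ → 1 as a/h → 0 (classical flat-punch half-space load), thin-layer
confined-compression slope of the kernel, and — independently — the solved
pressure reproduces a uniform unit deflection under the punch when
substituted into the original deflection integral.

Extraction conventions: ν = 0.5 (incompressible short-time response) for
instantaneous and dynamic moduli, ν = 0.42 for equilibrium; both
configurable.  A single κ per record is used at all frequencies.  The
instantaneous modulus of a step is the Hayes-corrected peak force increment
over the 5% strain increment, with the pre-step strain as the regressor of
the linear fit; equilibrium points use the end-of-hold force, with a
plateau criterion (force rate over the final 60 s below 0.5% of the step
force change per minute) that flags — but does not discard —
unequilibrated steps.  Phase differences are read from the discrete Fourier
component at the drive frequency (least-squares projection on
{1, cos, sin}, integer cycles, first cycle dropped as a start-up
transient); negative raw differences are reported and flagged as artifacts
rather than silently wrapped.

## Inverse identification

Objective: mean squared difference between simulated and measured force
over the 2nd and 3rd stress-relaxation steps (ramps and holds), divided by
the squared measured force range of that window; forward-model failures
return a large finite penalty.  Steps 1 and 4 are deliberately excluded, a
built-in holdout; the transient part of the window is what identifies `k0`
and `M` (with equilibrium samples alone the objective is flat in `k0`, an
assertion in the test suite).  `k0` is optimized in log₁₀ space, the other
parameters linearly, by bounded trust-region least squares with finite
differences.  Multistart screens each start with one forward solve and
polishes the best candidates.  Default bounds span the values reported for
human knee and hip cartilage across degeneration states:
E_f0 ∈ [10⁻⁶, 50] MPa, E_fε ∈ [0, 500] MPa, E_nf ∈ [0.01, 5] MPa,
k0 ∈ [10⁻², 10³]·10⁻¹⁵ m⁴ N⁻¹ s⁻¹, M ∈ [0, 25].

## Synthetic data

The generator emulates the reference protocol: group-wise log-normal FRPE
parameter draws, forward simulation, resampling at 10 Hz (relaxation) and
50 samples/cycle (dynamic), multiplicative Gaussian force noise (default
1%) and optional displacement jitter.  Group defaults encode the
qualitative osteoarthritis contrast — severe OA with nearly vanished
initial fibril modulus, reduced non-fibrillar modulus and permeability
exponent, and elevated permeability; moderate OA barely distinguishable
from normal — centered on magnitudes typical of healthy human femoral
condyle cartilage.  They are conventions: the underlying study reports the
distributions only graphically, so no default here is presented as a
published number.  Cohorts default to 35 samples in 17/15/3
normal/moderate/severe groups over 24 knees (11 two-sample knees holding a
medial and a lateral specimen); within-knee similarity is produced by a
shared knee-level standard-normal effect mixed into the log-parameter draw
with weight √ρ (ρ = 0.6 by default).

What the generator does *not* emulate: depth-dependent composition,
device compliance, drift, contact-finding artifacts, histology.  Passing
recovery tests therefore demonstrate the identifiability and correctness of
the pipeline under the model's own assumptions, not robustness to every
real-world artifact.

## Cohort statistics

OARSI grades pool as 0–1 → normal, 2–3 → moderate, 4 → severe.  Group
contrasts are mean differences with cluster-bootstrap confidence intervals
that resample knees, not samples (two specimens of one knee are strongly
correlated).  With only ~12 knees per group the plain percentile interval
undercovers (~93% measured), so the default applies the expanded-percentile
small-sample correction (percentile levels widened by the t-versus-normal
factor at the cluster count); measured coverage is 94–96% over 500
replicates.  Groups smaller than 5 are summarized descriptively and never
tested — mirroring how a 3-sample severe group should be treated.

## Problem sizes used in the shipped studies

Consolidation verification: 16 elements through the depth, 121 time steps;
Hayes verification: 40×16-element meshes at three aspect ratios; recovery
studies: the coarse preset on the default mesh (24 elements), 20 noisy
replicates with 10 multistarts each; coverage study: 500 cohort replicates
with 1000 bootstrap resamples.  These sizes were chosen so the full test
suite runs in minutes on one core while every verification retains a
comfortable margin to its tolerance.

## Known limitations

* Homogeneous material through depth; no osmotic swelling, no fibril
  viscoelasticity — by design of this FRPE variant.
* Sharp-edge displacement contact (no contact search, no friction
  coefficient between 0 and ∞) and the wrinkling-related resolution limits
  described above.
* The Hayes correction assumes a linear elastic layer; applying it at 20%
  protocol strains follows field convention but inherits that
  approximation.
* Backward Euler is first-order; the consolidation benchmark shows the
  practical effect (sub-1% with the shipped grids).
* Synthetic cohorts share one geometry; specimen-specific thickness
  variation is supported by the API but not exercised by the defaults.
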