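# Methods

## The model swimmer

The swimmer is a rigid assembly of two parts: a spherical head of radius
`R` and a helical flagellum — a circular helix of amplitude `b`, pitch
`lam`, number of turns `N` (axial length `L = N*lam`), and circular
cross-section of radius `r` — attached on the head's axis. A rotary motor
prescribes the relative angular rate `omega = Omega_head - Omega_flagellum`
about the common axis. At bacterial scales inertia is negligible (Reynolds
number << 1), so the flow obeys the Stokes equations and forces depend
linearly on velocities: every rigid part has a 6x6 resistance matrix mapping
its linear/angular velocity to (minus) the viscous force/torque it feels.
Requiring zero net force and torque on the free swimmer closes the problem
and yields the swimming speed `U` and the head rotation rate `Omega` as
linear functions of `omega`.

The centerline is parameterized as
`(x, b E(x) cos(kx - phi), chi * b E(x) sin(kx - phi))` with `k = 2*pi/lam`,
chirality `chi = +-1`, and an optional attachment envelope
`E(x) = 1 - exp(-(kE x)^2)` that lets the filament grow from the axis to its
full amplitude over a length `~1/kE`. The sine/cosine pair is deliberate: a
cosine in both transverse components would describe a planar wave, not a
circular helix. Untapered helices attach at the head surface with their
first material point a distance `sqrt(R^2+b^2)` from the head center.

Everything is computed in a consistent nondimensional unit system; the
shipped examples and defaults use `b = mu = omega = 1`. All reported speeds
scale linearly with `omega` and geometry size, powers as `mu * omega^2 *
length^3`; none of the dimensionless comparisons (relative errors, upsilon,
energetic efficiencies) depend on this choice.

## Three routes to the resistance problem

**Local drag (RFT).** Resistive force theory assigns each filament element
independent tangential/normal drag coefficients per unit length,
`df = [C_T tt + C_N (I - tt)] u ds`. Two coefficient families are provided:

* `gray_hancock`: reference length `q = lam`, and by default the classical
  denominators `C_T = 2 pi mu/(ln(2q/r) - 1/2)`,
  `C_N = 4 pi mu/(ln(2q/r) + 1/2)`. A variant with the two half-integer
  terms swapped between the denominators circulates in parts of the
  literature; it is available via `sign_convention="swapped"`. The
  classical form is the default because only it reproduces the relative
  ordering of the two RFT speed predictions in the benchmark comparison
  (the swapped form inverts the Gray–Hancock/Lighthill ordering entirely).
* `lighthill`: `q = 0.09 lam` with `C_T = 2 pi mu/ln(2q/r)`,
  `C_N = 4 pi mu/(ln(2q/r) + 1/2)`.

The filament resistance matrix follows by integrating the local law along
the centerline for the six unit rigid motions, averaged over equally spaced
stroke phases (default 8). Stroke averaging matters even for whole-turn
helices: instantaneous matrices carry phase-dependent transverse couplings
(for example an axial force from a transverse rotation) that cancel in the
stroke mean, leaving the sparse block pattern of a rotating helix. The
quadrature is validated to 1e-9 against the closed forms
`A = Lam (C_T c^2 + C_N s^2)`, `B = -chi Lam b s c (C_N - C_T)`,
`C = Lam b^2 (C_N c^2 + C_T s^2)` with `c = lam/ell`, `s = 2 pi b/ell`,
`ell` the arc length per turn and `Lam = N ell`.

**Additive approximation.** Head and flagellum coefficients are computed in
isolation — the head from the Stokes closed forms `A0 = 6 pi mu R`,
`C0 = 8 pi mu R^3`, the flagellum either from RFT or from the coupled
solver run on the flagellum alone — and summed in the axial momentum
balance. Solving the 2x2 system gives

    U     = C0 B omega / ((C0+C)(A0+A) - B^2)
    Omega = (1 - (A0+A) C0 / ((C0+C)(A0+A) - B^2)) omega

and the motor torque from the head balance, `T = |C0 Omega|`. This neglects
all hydrodynamic interaction between the parts.

**Coupled (global) solve.** The full hydrodynamics is resolved with the
method of regularized Stokeslets: a dense collocation system `G g = u`
relating nodal point forces to nodal velocities through a blob-regularized
Green's function. The head carries a Fibonacci-spiral surface distribution;
the flagellum a centerline distribution with blob size equal to the
filament radius. Partwise resistance blocks are assembled by moving one
part with the other held fixed and integrating force/torque over the whole
assembly; their sum is the (symmetric, positive definite) assembly
resistance matrix, while the individual blocks need not be symmetric. The
axial 2x2 balance built from these blocks yields `U` and `Omega`; the motor
torque is integrated from the tractions of the solved swimming flow over
the flagellum nodes. A phase-resolved variant solves an augmented system
(collocation rows plus six explicit zero-force/zero-torque constraints) for
the instantaneous rigid velocities given an arbitrary shape velocity; its
phase average agrees with the stroke-averaged route to within 2% and is
used for instantaneous velocities and trajectory integration (exponential-
map rotation update, midpoint translation).

## Numerical choices and calibration

* **Head blob size.** `eps_head = 0.34 * sqrt(4 pi R^2 / n)`. The factor is
  frozen once by a documented deterministic routine
  (`calibrate_head_epsilon_factor`) that scans the factor and matches the
  isolated-sphere drag to `6 pi mu R`; at 300–1200 nodes both drag and
  torque then sit within 1% of the closed forms. It is not a per-run fit.
* **Filament discretization.** Centerline node spacing equal to the
  filament radius (`spacing_factor = 1`). A centerline-blob model needs
  spacing comparable to the blob: the axial coefficients change by <1% when
  the spacing is halved from `r`, but are ~5% off at `2r`. Reduced-
  resolution presets (`low`: 300 head nodes, spacing `2r`) are used for
  qualitative property tests; all quantitative benchmarks run at the
  default.
* **Mixed blobs.** Kernel entries between nodes of different blob size use
  `eps_ij^2 = (eps_i^2 + eps_j^2)/2`, keeping the system matrix symmetric
  and the resistance matrix reciprocal to <1e-3.
* **Linear algebra.** Dense LU with multiple right-hand sides; one
  factorization per geometry per stroke phase is shared by the partwise
  solves and the motor-torque traction solve. No iterative tolerances.
* **Stroke averaging.** Whole-turn helices have phase-independent axial
  coefficients, so sweeps over integer turn counts use a single phase;
  fractional turn counts default to 8 phases.
* **Pole convention.** Assembly matrices use the head center; isolated
  filaments their axial midpoint. Axial scalars are invariant to pole
  shifts along the axis, so the two conventions mix safely in the axial
  balance.

## The correcting factor and performance measures

The additive route overestimates both the drag sum and (in magnitude) the
coupling available for thrust, because each part moves in the other's wake
(hydrodynamic screening). A single geometry-only scalar repairs most of the
speed error:

    upsilon = (A0 + A)(B1 + B2) / ((A1 + A2) B),

with `A0, A, B` isolated coefficients and `(A1+A2), (B1+B2)` partwise sums
from the coupled solve. The corrected speed is `upsilon * U_additive`;
upsilon is invariant under rescaling of viscosity and motor rate (all
coefficients are linear in `mu`; `omega` never enters).

Six performance measures are tracked, each in global / additive / corrected
variants: two energetic efficiencies (useful power to move the head alone,
`A0 U^2 / (T omega)`, or the whole swimmer, `(A1+A2) U^2/(T omega)`), two
propulsion efficiencies (distance per flagellar revolution `U/(omega -
Omega)` and per motor revolution `U/omega`), the swimming efficiency
(distance per unit work `U/(T omega)`), and the work per traveled distance
(its inverse). Corrected variants scale the additive closed forms with the
power of `U` they contain: `upsilon^2` for the energetic efficiencies,
`upsilon` for the propulsion and swimming efficiencies, `1/upsilon` for the
work per distance. A non-translating swimmer (zero coupling) reports zero
efficiencies and an explicit infinite sentinel for the work per distance.

Speeds are signed: a right-handed helix driven at `omega > 0` (head
counter-rotating against the flagellum) swims toward -x in this convention,
and flipping the chirality flips the sign of `U` but not `|Omega|`.
Comparisons therefore use magnitudes or ratios.

## Benchmarks and oracles

* Isolated sphere: drag and torque against `6 pi mu R`, `8 pi mu R^3`
  (within 1% at default resolution).
* Two equal spheres translating together along their line of centers:
  per-sphere drag against (a) the exact bispherical-coordinate series,
  convergent for any separation `rho > 2R`, and (b) a resummed
  method-of-reflections series `6 pi mu R/(1 + 1.5 beta - beta^3)`,
  `beta = R/rho` (Stokeslet + source dipole with Faxen sampling, geometric
  sum over reflections). The reflections series carries ~4% truncation
  error near contact (`rho = 2.2R`) where the solver agrees with the exact
  series to 0.2%, so close-separation checks use the exact series and the
  reflections series is checked at moderate separations. Note the
  screening direction: per-sphere drag is *below* the isolated value and
  *rises* toward it as the separation grows.
* Helix block pattern: the stroke-averaged resistance matrix of an isolated
  helix reproduces the sparse axial/transverse pattern with off-pattern
  entries below 1e-6 of the matrix norm.
* RFT quadrature vs the closed forms above.
* The benchmark swimmer comparison (below).

## The benchmark swimmer comparison

For the reference configuration (two-turn helix, `r = b/16`, `lam = 8b`,
head `R = 2b`, `mu = omega = b = 1`) the package compares the simplified
speed predictions to the coupled solve. The uncorrected relative errors
(additive, Gray–Hancock RFT, Lighthill RFT) and the Gray–Hancock corrected
error reproduce the published reference comparison within ~0.7 percentage
points. The corrected additive and corrected Lighthill errors land a few
percentage points above their reference values. The discrepancy traces to
the ratio `(B1+B2)/(A1+A2)` entering upsilon: it is converged in this
solver (stable to 0.5% under doubling the head resolution, halving the
filament spacing, stroke averaging, and attachment tapering) but sits ~5%
below the value implied by the reference computation (which meshed the
filament surface rather than its centerline), and the
correction algebra amplifies that into the corrected-error residual. This
is a genuine model-fidelity difference between a centerline-blob filament
and a meshed filament surface, not a resolution artifact; the uncorrected
ratios, which this difference largely cancels out of, agree to a fraction
of a percentage point.

A related model-level feature: over the tight-helix length sweep
(`lam = 2.42b`) the additive speed error of this solver changes sign near
`N ~ 7` (the additive prediction crosses the coupled one), so in a small
neighborhood of the crossing the *uncorrected* error is accidentally near
zero and the corrected error cannot undercut it. Away from that
neighborhood the correction reduces the speed error several-fold at every
length, and `upsilon` stays within 6% of unity for tails longer than five
pitches.

## Length sweeps and optimization

Sweeps vary the number of turns at fixed pitch, amplitude, head size and
motor rate (default family `r = b/16`, `lam = 2.42b`, `R = 2b`, the
configuration of the reference length study; the sweep helix is untapered).
Each grid point records the partwise scalars, both swimming solutions,
upsilon and all measures; failed points are recorded and the sweep
continues. The qualitative structure at reduced resolution matches the
full-resolution behavior: the coupled and additive speeds both attain an
interior maximum over `N in [1, 20]` but at different lengths; the coupled
head-payload energetic efficiency has an interior maximum that the additive
variant (monotone) misses entirely; the first propulsion efficiency is
monotone in tail length; the additive drag and torque sums always
overestimate their coupled counterparts, with the torque sum far more
additive than the drag sum (rotation-induced disturbances decay one power
of distance faster than translation-induced ones).

Length optimization runs a coarse grid scan followed by golden-section
refinement; monotone metrics return the bracket boundary with an explicit
"no interior optimum" flag.

## What the synthetic geometry does and does not emulate

The generator produces ideal rigid geometries: perfect spheres, perfect
(optionally tapered) helices, a rigid motor at a fixed rate. It emulates
the scale separation and geometry of flagellated bacteria well enough to
study hydrodynamic interactions between body and propeller. It does not
model flagellar elasticity or bundling, a finite motor torque-speed curve,
Brownian motion, nearby walls, or end effects of a meshed filament surface.
Passing tests therefore validate the hydrodynamic interaction physics of
the rigid model, not predictions for any real organism.

## Known limitations

* Corrected-speed predictions inherit the centerline-filament model's ~5%
  bias in the partwise coupling-to-drag ratio (see above).
* No wall effects (free space only); no deformable flagella.
* The RFT route supports untapered helices only.
* The two-sphere reflections series degrades near contact; use the exact
  series there.
* Problem sizes: default-resolution sweeps to 14 turns of the tight helix
  build dense systems of ~6000 unknowns (about a minute per point on one
  core); the shipped studies choose grids accordingly.
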