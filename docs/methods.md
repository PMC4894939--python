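# Methods

`agekin` implements a kinetic description of stochastic age-structured
populations: the state of a population is the *age chart* — the vector of
times of birth (TOB) of every living individual — and the model is a pair
of per-individual hazards, a birth/fission hazard β and a death hazard μ,
functions of the individual's age `a` and possibly of the population size
`n`. This note records the models, the numerical choices, and what the
synthetic experiments do and do not demonstrate.

## State convention

All internal state is stored as TOB `b = t − a` rather than age. TOB is
constant along the characteristics of the age-transport operator, so an
individual is a single number that never changes, and every deterministic
solution reduces to algebra on propagators

    U(b; t0, t1) = exp( − ∫_{t0}^{t1} h(s − b) ds ),

the probability that an individual born at `b` experiences no event of
hazard `h` during `[t0, t1]`. `h = μ` gives survival against death;
`h = γ = β + μ` gives the no-event probability used by the simulators and
the fission theory. Propagators factorise over individuals and compose
over abutting intervals; both identities are property-tested.

## Stochastic simulators

Two statistically exact samplers are implemented.

**Per-individual inversion** (size-independent hazards). Each individual
carries an event clock drawn by inverting its total-event survival:
solve Λ(a0, a) = E with E ~ Exp(1), where Λ is the integrated total
hazard from the individual's current age `a0`. Built-in models invert in
closed form (constant rates, linear death hazard) or through the
waiting-time distribution's inverse survival function (hazards derived
from a waiting-time density `g`, where the event age at birth is simply a
draw from `g`). At an event, a competing-risks coin β/γ decides the event
type. Because no hazard depends on `n`, clocks remain valid across events
and the scheme is exact.

**Thinning** (bounded, possibly size-dependent hazards). Candidate events
are proposed from the homogeneous bound `n · bound(n)` and accepted with
probability γ_n(a)/bound. Every accepted event invalidates pending
proposals (the bound may change with `n`); proposals that would exceed the
declared bound raise an error rather than silently truncate. For
size-independent models the two samplers are verified to produce the same
event-time law (two-sample Kolmogorov–Smirnov on first-event times).

A fixed-timestep scheme (per-individual event probability γ·dt per step)
is available behind `method="fixed-step"` for bias experiments only; its
O(dt) bias is demonstrated, not corrected.

**Budding vs fission bookkeeping.** In budding dynamics a birth adds an
age-0 individual and the parent persists. In fission dynamics an event
either replaces the individual with two age-0 twins (probability h2) or
removes it (h0 = 1 − h2); a surviving twin becomes a singlet but keeps
its TOB. Twin pairs are simply two individuals sharing a TOB and a twin
pointer, so a pair automatically carries event hazard 2γ.

**Randomness.** Trajectory `r` of a run with master seed `s` uses the
stream `SeedSequence((s, r))`, split into an event stream and a motion
stream. Draw order is fixed: founder ages (when drawn per trajectory),
founder clocks in index order, then per-event draws in event order.
Event logs are therefore bitwise reproducible, and spatial runs with
diffusivity `D = 0` reproduce the non-spatial event sequence exactly.

**Spatial runs** add independent one-dimensional Brownian motion with
diffusivity `D` between events; increments are exact Gaussians applied at
event, proposal and snapshot times, and a newborn starts at its parent's
position. Motion cannot alter size statistics unless hazards depend on
position; this reduction is tested.

## Deterministic layers

**McKendrick–von Foerster / renewal.** For size-independent hazards the
mean age density satisfies the transport equation with boundary flux
B(t) = ∫ β ρ. The renewal (Volterra) equation for B is marched with the
product-trapezoidal rule on a uniform grid — second order, verified by
grid-refinement ratio — with optional Richardson extrapolation over a
halved step, which cancels the leading error term and is used by all
higher layers. The founder source term is integrated by Simpson's rule on
the founder density truncated at its 1e−10 survival quantile (recorded in
metadata). A Laplace-domain route inverts B̃ = Ñ/(1 − K̃) with the
32-node fixed-Talbot rule when the model carries closed-form transforms
(constant-rate models do); it is restricted to exponentially bounded
kernels and is cross-checked against the time-domain march.

**Master equation.** For age-independent (possibly size-dependent) rates
the population-size law is integrated as a linear ODE with DOP853 at
rtol 1e−11. (The generator is conservative; the matrix exponential in the
installed scipy produced visibly non-stochastic columns on small
generators, so the ODE route is used.) This solver is the independent
oracle for the thinning simulator.

**Factorial moments.** The k-th factorial moment density X^(k) of the age
structure obeys the same transport operator with death-only decay; its
boundary surface at age zero couples order k to order k−1. Order 1 is the
transport solution; order 2 is obtained by marching the boundary surface
φ(y; τ) = X^(2)(y, 0; τ) on a uniform lattice. The surface jumps across
y = τ (individuals born before vs after the start), so the boundary
integral is split at the moving breakpoint with one-sided values
maintained for the diagonal, its two corner limits, and the τ → 0⁺
boundary row; each smooth piece is integrated with trapezoidal weights
(second order), and the whole march is Richardson-extrapolated.
Evaluation interpolates the surface in diagonal-aligned coordinates so
interpolation never mixes the two sides of the jump; on lattices aligned
with the march step the evaluation is interpolation-free. Orders above 2
are rejected: each additional order consumes the full previous surface
along a moving boundary, and order 2 already yields age-window variances
via Var = ∫∫X^(2) + mean − mean². Window integrals use Gauss–Legendre
panels split at the age-equals-elapsed-time lines. On measure-zero
region boundaries all closed forms and solvers take the limit from the
later-listed region (so age = elapsed time evaluates the boundary-fed
branch); this convention is arbitrary but applied consistently.

Initial two-point correlations g2 are supported (the march then carries
an O(J³) founder-correlation term); a single founder has g2 ≡ 0.

**Fission mean field.** Singlet/doublet densities close on the
pair-creation flux B(t), marched from the same product-trapezoidal kernel
machinery with the total-event propagator; fields follow in closed form
(X = 2BU(1−U), Y = BU², T = 2BU for post-start TOBs). The equivalence
with the binary branching process is implemented as redundant solution
routes — Volterra march on hazards, renewal march on the waiting-time
density, Talbot inversion of T̃ = (1−g̃)/(s(1−2h₂g̃)), and the explicit
branch-cut-plus-residue formulas of the Gamma model — whose pairwise
agreement is asserted rather than assumed.

**Gamma fission model.** Cycle times are Gamma with unit mean and
variance 1/α. For non-integer α the mean population is evaluated from the
branch-cut integral plus the residues of the α-th-root poles; the
integral is taken in the radial variable on [0, R] with R chosen so the
exponential damping is below 1e−16, by adaptive Gauss–Kronrod quadrature.
Two sign conventions are possible for the branch-cut term depending on
the orientation of the cut; the implementation fixes them by requiring
agreement with an independent numerical inversion (the Talbot oracle at
moderate α), and the tests pin this down at α = 2.5. For integer α the
transform is rational and the full residue sum over all α poles is exact
and is used directly — this matters because cotangent-contour inversion
fails for large α: the poles spiral up the imaginary axis and escape the
contour (at α = 100 a 32–64 node Talbot rule is off by several percent,
while the residue sum matches the time-domain renewal march to 13
digits). The generic Laplace route should therefore not be trusted above
α ≈ 30; the residue and renewal routes remain valid. For even integer α
the printed branch-cut formula is ill-defined (a pole sits on the cut)
and a warning is raised before the residue evaluation is returned.

As α → ∞ divisions synchronise and the mean approaches the discrete
Galton–Watson doubling staircase. At integer times the smooth Gamma model
straddles the staircase jump (T → the midpoint), so the meaningful lower
envelope at the jump points is the pre-jump value 2^(⌈t⌉−1); the ordering
in α and both envelopes are tested with that convention.

## Reference experiments and the synthetic generator

The three preset configurations are the package's study conditions:

* **pure-death** — linear death hazard μ(a) = a, ten founders with ages
  from Gamma(shape 4, rate 4) (unit mean, sd 1/2), horizon t = 2;
* **carrying-capacity** — budding with per-individual birth rate
  β₀(1 − n/K), β₀ = 1, K = 5, one Gamma-aged founder, horizon t = 5;
* **gamma-fission** — fission-only, Gamma cycle times at α ∈ {1, 10, 100},
  single age-0 founder, horizon t = 3.

The "full" scale uses 400,000 trajectories per ensemble; the "desk" scale
(used by tests and the acceptance script) uses 50,000, which widens
Monte-Carlo bands by √8 but leaves every comparison comfortably resolved.
Where a founder age is described as exponential, the parameter is a
*rate* (density λe^{−λa}); the closed-form moment expressions fix this
convention, and prose descriptions of "mean λ" elsewhere should be read
accordingly.

The generator draws i.i.d. founders and evolves them under exactly the
hazards the deterministic layers solve. Passing tests therefore
demonstrate internal consistency of simulator and theory and correctness
of the numerics — they do not probe features real populations have and
the model lacks: inter-individual interactions other than through n,
correlated founder ages (supported in the moment layer but not generated
by the presets), measurement noise, or lineage/generation effects.

## Known limitations

* Mean-field and moment solvers require size-independent hazards; the
  size-dependent hierarchy is not solved (only simulated, with the master
  equation as the age-independent oracle).
* Moment order is capped at 2 (variances); higher-order correlation
  estimators are not provided.
* The spatial model is one-dimensional free diffusion without spatial
  interaction; no analytic spatial solution is evaluated.
* The Laplace renewal route needs closed-form transforms and is
  restricted to exponentially bounded kernels; heavy-tailed founder
  densities must use the time-domain march.
* Plain-trapezoid integrals of fields across the age-equals-elapsed-time
  discontinuity carry an O(h · jump) artifact; the window-moment routines
  avoid it by splitting panels, but naive post-hoc integration of dumped
  grids will see it.
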