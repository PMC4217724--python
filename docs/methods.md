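# Methods

## Degradation degree and its anchor

Hydrolytic degradation of oriented PLLA shows up first as a loss of
ductility: elongation at break falls by a factor of four over a month
while the elastic modulus moves by under ten percent. The degradation
degree D = 1 − L/L0 measures this ductility loss on [0, 1]. The pristine
reference L0 is not measurable (the material starts degrading
immediately), so it is derived from an anchor: the unstrained specimen
at the earliest time point (3 days) is assigned D = 0.1, giving
L0 = L(0%, 3 d)/0.9 = 1.2214. This derivation reproduces every degree in
the packaged tensile grid to better than 1e-6, which is strong evidence
it is the procedure the data were produced with. Degrees use the
engineering-strain elongation ratio; the true-strain reading does not
reproduce the grid.

Degrees computed from arithmetic are clamped to [0, 1]; elongations
above L0 are rejected rather than clamped (a specimen cannot be less
degraded than pristine — more likely a data error).

## The degradation surface

Family: D(ε, t) = 1 − exp(−c tⁿ (b + a εᵐ)), all five constants
positive, time in days, strain dimensionless (month-scale inputs are
converted at 30.44 d/month). Properties by construction: D(·, 0) = 0,
monotone non-decreasing in both arguments, saturation at 1. The strain
and time dependencies are separable inside the exponent; the tensile
grid is too small (12 cells) to support a less parsimonious coupling.

Fitting is weighted nonlinear least squares (`scipy.optimize.
least_squares`, trust region reflective) with box constraints
(1e-6, 10] on every constant, multi-started from one nominal point plus
seeded log-uniform draws; the best of all starts wins, so the fit is
deterministic for a fixed seed and invariant to observation order.
Weights default to uniform. On the packaged grid the fit reaches
RMSE ≈ 0.06, and a dense five-dimensional grid search finds nothing
better — the residual is data scatter (the 20% pre-stretch series jumps
between 3 and 10 days in a way no smooth monotone surface can follow),
not optimizer failure.

The surface family is registered by `family_id` and pluggable; the
constants reported alongside the original dataset are retained as
provenance metadata but deliberately not interpreted, because the
functional form they belong to is not recoverable from the available
text (published as an image). All downstream use re-fits the packaged
family.

## Reduced-order scaffold mechanics

### Model reduction

The scaffold — sinusoidal in-phase hoops linked by straight bridges on a
3.5 mm (OD) x 0.125 mm (wall) cylinder — is modeled on the unrolled
mid-wall surface (x = circumferential arc length, y = axial). This is a
deliberate reduction from 3-D continuum FE to a planar beam problem; it
preserves the structural mechanisms the study questions turn on (crown
bending during crimp/expansion, plastic set and recoil, circumferential
stiffness, strain localization) and gives up radial wall bending,
out-of-plane strut twist and 3-D contact. Absolute stresses are
therefore indicative only; all conclusions drawn from the model are
trend and localization statements.

The ring closure appears as *wrap* elements whose far node is shifted by
the current circumference C = C0 + ΔC, and ΔC is a solved degree of
freedom:

- prescribing ΔC = rigid cylindrical crimper/balloon surrogate
  (displacement-controlled, frictionless); the total radial force is
  2π times the conjugate reaction, from virtual work F·dR = G·dC with
  dC = 2π dR;
- ΔC free with zero conjugate force = free recoil;
- a scalar spring on ΔC = the compliant mock vessel.

### Elements, section, material

2-node corotational beams (Crisfield), 3 dof/node, two Gauss points per
element, Euler–Bernoulli local kinematics (local rotations only; local
transverse end displacements vanish in the corotational frame). The
rectangular section (strut width x wall thickness) is integrated by
fibers placed at Gauss–Legendre points per half-depth, which integrates
the elastic inertia and the fully plastic section modulus exactly; the
verification suite holds the solver to the cantilever (PL³/3EI) and
ring-membrane (w = pR²/EA) closed forms within 2% and the plastic limit
moment σy w h²/4 within 5%.

Fibers follow one-dimensional plasticity with multilinear **kinematic**
(Masing) hardening, implemented as a Besseling overlay of
elastic-perfectly-plastic sublayers whose weights reproduce the
tabulated hardening curve (the decomposition requires a concave curve,
which degradation-scaled PLLA curves satisfy). The kinematic choice is
deliberate: crimp-then-recoil is a massive load reversal, and an
isotropic model lets reverse flow raise the yield surface so far that
post-recoil stress magnitudes exceed the crimp peak — the opposite of
the observed behaviour. With the overlay, reversal stresses are bounded
by the forward envelope and the expected stress relaxation on recoil
emerges at the default geometry. The overlay return mapping is closed
form per sublayer (no local iteration).

The pristine hardening curve (yield ≈ 60 MPa rising to ≈ 176 MPa at
140% plastic strain, E = 1700 MPa) represents oriented semicrystalline
PLLA tubing; the degradation-indexed curve library scales its flow
stress by (1 − 0.85 D) — a point at the fracture threshold retains ~23%
flow stress, so *deactivation*, not material collapse, is the failure
mechanism — and sets failure strain to L0(1 − D). Moduli are held
constant across the library, encoding the observed near-independence of
stiffness from degradation.

### Solver

Implicit quasi-static Newton with a consistent tangent (including the
corotational geometric terms), at most 50 iterations per increment,
convergence at ‖R_free‖ ≤ 1e-6 · ref + 1e-9 N. The reference force
`ref` is the norm of the assembly of |element force| contributions
("gross" internal force): unlike the net internal force it does not
cancel in self-equilibrated states, so the relative measure stays
meaningful after unloading. A shallow line search tries steps
(1, ½, ¼, ⅛) and takes the first descent step or the best candidate;
deep backtracking is deliberately avoided because it stalls Newton
sequences whose residual transiently rises. Stages are walked in
increments with recursive halving on non-convergence (7 levels).

Recoil is displacement-controlled withdrawal of the surrogate: the
prescribed circumference marches toward its reference value and a step
that flips the contact-reaction sign is undone and halved, approaching
the contact-opening point from one side only. This matters: with
plastic hysteresis the reaction at a given circumference depends on the
path, so bisection that re-loads the scaffold converges to a
discontinuity instead of the opening point, and force-controlled
release diverges outright when the stored elastic energy is large.

The mock vessel is a linear radial spring engaged unilaterally
(compression only). Its natural radius grows linearly with lumen
pressure so that the unstented diameter change across the 80→160 mmHg
pulse equals the 5% compliance; its stiffness comes from equating the
projected-area pressure load on the vessel segment to the spring force
at that compliance. Its diastolic natural diameter defaults to 95% of
the deployed stent diameter, i.e. the scaffold is slightly oversized
and props the vessel open — the configuration in which pulsatile
loading transfers to the scaffold. Goodman points are
(σ_sys + σ_dia)/2 and |σ_sys − σ_dia|/2 of the signed extreme-fiber
stress per Gauss point over the two quasi-static solves.

### Degradation stepping

Degradation is staggered (one-way coupled per step): at each time
increment, every Gauss point's D is evaluated from the surface at its
*peak historical tensile fiber strain* (an engineering measure, matching
the pre-stretch variable the surface was calibrated on) and the new
elapsed time, clamped to be non-decreasing; material properties are
re-interpolated from the curve library (linear in D, clamped at the
library ends — no extrapolation, which the source data cannot support);
points with D ≥ 0.9 are deactivated (stress zeroed, stiffness cut to a
1e-6 numerical residual that keeps the tangent regular); equilibrium is
re-solved. Deactivation at 0.9 encodes "almost complete degradation" at
that degree and the observation that re-expansion fractures occur at
exactly the sites that degraded fastest.

Radial strength at a time point is measured on a deep copy of the
state: a rigid-cylinder crimp sweep recording total radial force versus
outer diameter; the peak is the radial strength. Outputs are reported
both as total force and per modeled axial length.

## Molecular-weight kinetics

retention(t) = exp(−k t) per environment, fitted in log space where the
model is linear through the origin (closed form
k = −Σ t ln r / Σ t²; a single observation gives k = −ln r / t
exactly). First-order decay is the minimal model consistent with
near-linear early-phase Mw loss and single-anchor calibration; the
in vivo rate (k ≈ 0.0802/month) exceeds the in vitro rate
(k ≈ 0.0631/month). Mw is deliberately not coupled to mechanics: over
the modeled window the molecular weight falls ~35% while radial support
is essentially retained, so a Mw-mechanics coupling would be
unconstrained by the available observations.

## Synthetic data

The generators produce the statistical shape of the three measurement
campaigns, not laboratory data:

- tensile grids: degrees from a known surface plus Gaussian noise
  (clamped to [0, 0.95]), elongations L0(1 − D*), moduli within ±5% of
  pristine, plastic curves scaled monotonically with D*;
- Mw retention: exponential decay with lognormal noise, anchored at the
  6-month retentions;
- diameter follow-up: constant nominal OD plus caliper noise and an
  optional drift (default zero — the scaffold's diameter does not
  change significantly over follow-up).

All generators are pure functions of (parameters, seed). What passing
tests on synthetic data demonstrate is therefore internal consistency
(round trips, estimator calibration, invariance properties), not
agreement with any particular laboratory measurement. Bench-loop
conditions (920/840 mmHg pump pressures, 70 cycles/min, PBS pH
7.4 ± 0.2, 5% compliance) are recorded in fixture headers as provenance
only.

The packaged tensile fixture is the exception: its moduli and
elongations are the published grid values. Its companion plastic-curve
file is synthetic (the published stress–strain curves exist only as
figures) and is labelled as such.

## Problem sizes and defaults

Default geometry: 6 crowns/hoop, 2 hoops, 3 bridges, strut width
0.15 mm, hoop height 1.0 mm, 8 elements per strut (≈ 100 elements,
≈ 320 dof). The crown count, strut width and hoop height are stated
assumptions — the source geometry is proprietary — and configurable.
Tests and the example study use 3–4 elements per strut and 20–30 crimp
increments, which reproduce all qualitative behaviours of the fine mesh
in a few seconds; the package's documented studies use these coarsened
settings as their standard problem size. Degradation time points
default to 10/20/30 days (the bench radial-strength comparison), with
month-scale points (1/3/6) for the Mw and diameter campaigns.

## Known limitations

- Planar reduction: no radial wall bending, strut twist, 3-D contact,
  balloon folding or vessel tissue constitutive behaviour; absolute
  stresses are indicative, trends and localizations are the outputs.
- The degradation surface is calibrated on pre-stretch ≤ 40% and ≤ 30
  days; crown strains exceed that range, so crown degradation rates are
  an extrapolation of the fitted family (the family saturates, keeping
  the extrapolation bounded).
- Mesh-scale localization: with softening material, strain concentrates
  at the crown scale set by the discretisation; comparisons across mesh
  resolutions are qualitative.
- No viscoelasticity, temperature dependence, crystallinity evolution,
  autocatalytic hydrolysis, or fatigue-life prediction beyond Goodman
  point placement.
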