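# Methods

`magsteer` simulates and optimizes the steering of superparamagnetic
nanoparticle concentrations in a planar fluid sample surrounded by four
electromagnets. This note documents the model, the numerical choices, the
parameters that matter, and what the synthetic scenarios do and do not
demonstrate.

## Physical model

**Coil fields.** Each electromagnet is an infinitely thin circular loop of
radius *a* with *N* windings. In loop-attached cylindrical coordinates
(ρ, z) the field components are the standard semi-analytic expressions in
the complete elliptic integrals *K*(*m*) and *E*(*m*) with the
modulus-squared convention *m* = 4*aρ* / ((*a*+*ρ*)² + *z*²), which is the
parameter convention of `scipy.special.ellipk`/`ellipe`. The spatial
Jacobian ∂**H**/∂**x** is evaluated analytically: the cylindrical partials
are closed forms obtained with d*K*/d*m* = −*K*/(2*m*) − *E*/(2*m*(*m*−1))
and d*E*/d*m* = (*E*−*K*)/(2*m*) (generated symbolically and verified
against central finite differences to < 1e−7 relative), followed by the
cylindrical-to-cartesian transform. For cylindrical radii below 1e−9 m the
elliptic form is a 0/0 limit, so the on-axis closed form
H_z = *N I a*²/(2(*a*²+*z*²)^{3/2}) and its divergence-free Jacobian limit
(∂H_ρ/∂ρ = −½ ∂H_z/∂z) are used instead; this branch matters because grid
lines of the centered 31 × 31 sample lie exactly on the coil axes. Points
within 1e−9 m of the filament itself raise an error. Fields of several
coils superpose linearly in the currents.

**Magnetization and force.** A particle of core volume *V* carries the
equilibrium moment **m** = *g*(*H*) **H** with
*g*(*H*) = *V M*(*H*)/*H*, where *M*(*H*) = *M*_s *L*(μ₀ *M*_s *V H* /
(k_B *T*)) is the Langevin magnetization curve and
*L*(*x*) = coth *x* − 1/*x*. The Taylor branch *x*/3 − *x*³/45 replaces the
exact form for |*x*| < 1e−4, where coth *x* − 1/*x* loses half its digits
to cancellation; *g*(0) is the analytic initial-susceptibility limit
μ₀ *M*_s² *V*²/(3 k_B *T*), making *g* continuous. The body force is the
point-dipole (magnetic-charge) law **F** = (**m**·∇)**B** =
μ₀ *g*(|**H**|) (∂**H**/∂**x**)ᵀ **H**, which for the curl-free coil field
equals (μ₀/2) *g* ∇(*H*²): the force points up the field-magnitude
gradient, i.e. toward the coils. For the 400 nm magnetite particle the
Langevin argument is ≈ 4.9 *H*·(m/A), so the moment is saturated
essentially everywhere in the working field range (≥ 10³ A/m); the force
then scales linearly, not quadratically, with the coil current.

**Drift and transport.** Inertia is negligible at this scale, so the
particle velocity is the instantaneous mobility response
**v** = **F**/(6π η R_p) + **v**_f (Stokes drag with hydrodynamic radius
R_p plus the carrier flow). The ensemble is described by its concentration
field, governed by the advection–diffusion equation
∂c/∂t = ∇·(D∇c) − ∇·(**v**c) with the no-flux wall condition
**n**·(D∇c − **v**c) = 0 (impermeable dish: total mass is constant).

## Discretization

The sample is a uniform grid of square voxels (default 31 × 31 over
8 cm × 8 cm; a 30 × 30 variant with Δx ≈ 2.7 mm is available through the
configuration), flattened as k = i + nx·j with voxel centers at cell
midpoints and the sample centered on the origin. The spatial operator is
assembled in finite-volume flux form: each interior face carries
F = −D(c_R − c_L)/Δx + v_face (c_L + c_R)/2, entering the two adjacent
balances with opposite signs, and boundary faces carry zero flux. This
reproduces the classical second-order central stencils in the interior for
uniform velocity while making the column sums of A(u) exactly zero, so
mass conservation holds to rounding regardless of step size. The magnetic
drift is evaluated directly at face midpoints (the flux quadrature points)
rather than averaged from voxel centers; the per-coil unit-current fields
at the faces are cached once per geometry, since the field is linear in u
even though the force is not.

The cell Péclet number is large for these parameters (D ~ 3.7e−13 m²/s
from Stokes–Einstein against drifts of a few µm/s), so the central scheme
can produce small negative concentrations near steep fronts. Values are
deliberately *not* clipped — clipping would break mass conservation — and
a first-order upwind advective flux is available via the `scheme: upwind`
configuration flag when monotonicity matters more than second-order
accuracy (the pure-advection test uses it).

Time integration is classical fixed-step RK4. Within each constant-current
segment A(u) is assembled once and the sub-step is
Δt = 0.4 · min(Δx²/(4D), Δx/max|v|), the explicit stability limits with a
safety margin; a norm growth beyond 1e6× aborts with a step-size
diagnostic. Because RK4 preserves linear invariants of a column-sum-zero
operator, the total mass at every snapshot matches the initial mass to
~1e−12 relative over the full 10000 s horizon.

## Model order reduction

Snapshots of the full state on a uniform time grid (default 101 over
[0, t_f]) form the snapshot matrix X, used raw (no mean-centering, no
weighting). The SVD X = UΣVᵀ gives the POD basis; the retained rank ℓ is
the smallest with energy fraction ε(ℓ) = Σ_{i≤ℓ}σ_i²/Σσ_i² ≥ ε* (default
ε* = 0.98), or a fixed ℓ from the configuration. Modes follow a
deterministic sign convention (largest-magnitude entry positive) so runs
are bit-for-bit reproducible. The reduced dynamics are the Galerkin
projection Ã(u) = U_ℓᵀ A(u) U_ℓ, the cost Q̃ = U_ℓᵀ Q U_ℓ, and optional
concentration bounds are evaluated on the lifted state at the shooting
nodes only (continuous-time path constraints are not transcribed).

## Optimal control

The control is a zero-order-hold current vector (default n_t = 4 segments
over t_f = 10000 s, so one level per 2500 s), bounded by |u| ≤ 13 A. The
cost is J = ∫ (xᵀQx + uᵀRu) dt + γ t_f with, in the packaged scenarios,
Q = −1 at the single target voxel and zero elsewhere, R = 0, γ = 0, and
t_f fixed: only the target concentration is optimized. The state quadrature
is trapezoidal on the snapshot grid; the uᵀRu term is integrated exactly
(it is piecewise constant, and the trapezoid rule would be ambiguous at
segment boundaries).

The transcription is direct multiple shooting: decision variables are the
n_t current vectors (scaled by u_max) and the reduced states at the
n_t − 1 interior nodes (scaled by the initial-state magnitude); each
segment is integrated by RK4 in the reduced space with the full-order
stability sub-step; node continuity is enforced as equality constraints.
The NLP is solved with SLSQP using forward finite differences of relative
step 1e−3; per-segment memoization makes each finite-difference
perturbation cost one segment integration instead of a full horizon.
`max_iter = 0` returns the guess unchanged, and if the NLP iterate is
worse than the guess (by defect-free sequential reduced cost) the guess is
retained, so the returned schedule never regresses.

The outer loop alternates: full-order simulation under the current
schedule → POD basis from those snapshots → reduced DMS warm-started from
the previous currents and the restriction of the previous full-order node
states under the *new* basis → full-order re-evaluation. The best
full-order solution seen is kept, so the reported cost history is
nonincreasing. The reduced and full costs of a schedule agree closely only
once the basis has seen its own optimized trajectory — after one outer
iteration the gap on the scaled scenario is ~80 %, after three it is
< 1 % — which is the reason the alternation exists.

**Initial guess.** Each coil is driven in proportion to the positive
cosine between its direction (from the initial centroid) and the desired
direction of motion (centroid → target; for a holding problem, opposite
the flow), with the best-aligned coil at u_max. Driving the guess at the
full bound rather than a fraction reflects that the optimum of a
monotone-in-field-strength cost sits on the box boundary; the fraction is
configurable (`guess_fraction`).

## Parameters and calibration

| parameter | default | origin |
|---|---|---|
| sample | 8 cm × 8 cm, 31 × 31 voxels | published setup |
| particle | d = 400 nm magnetite, M_s = 4.78e5 A/m | published setup |
| u_max, t_f, n_t | 13 A, 10000 s, 4 | published setup |
| ε* | 0.98 | published setup |
| T | 300 K | assumed (room temperature) |
| η | 3e−3 Pa·s | blood-like viscosity, number assumed |
| R_p | 200 nm (core radius) | assumed |
| D | k_B T/(6π η R_p) ≈ 3.7e−13 m²/s | Stokes–Einstein, override available |
| coil radius / standoff | 0.05 m / 0.10 m | assumed geometry |
| coil turns | 10000 | calibrated, see below |
| blob σ / center | 2.5 mm at (−3 cm, 0) | assumed, see below |
| target | (0 cm, 1 cm) | published figure caption |

The coil winding count is the one genuinely calibrated quantity: the
reference description never prints coil strength, but it does state that
particles travel roughly 3 cm per 10000 s horizon. For a 400 nm particle
in 3 mPa·s fluid that drift requires field gradients of order 2 T/m at
~10 cm range, i.e. ~1.3e5 ampere-turns; with u_max = 13 A that is 10⁴
turns per coil. With this choice the packaged steering run travels
~2.7 cm per horizon, with face drift speeds between ~0.5 µm/s (far side)
and ~10 µm/s (near a driven coil). The initial blob emulates particles
captured against a wall by a single magnet — a compact Gaussian a few
voxels across (σ = 2.5 mm ≈ one voxel) centered 1 cm off the left wall.

Under these frozen conditions the 0.98 energy criterion on the
guess-driven steering trajectory selects ℓ = 5 reduced states (the
reference run reports 6); the selected rank is sensitive to the unprinted
coil geometry and blob extent, growing roughly with the ratio of travel
distance to blob width.

## Scaled test scenario

The `ci` scenario (15 × 15 grid, n_t = 2, t_f = 4000 s, target 2.2 cm from
the blob) exercises the identical code path at ~30× lower cost and is the
scale used for the optimizer and holding tests; the full 31 × 31 pipeline
appears in the conservation, POD-rank and calibration checks. Problem
sizes were chosen so the whole suite completes in well under a minute of
CPU apart from the optimizer tests (a few seconds each).

## What the synthetic scenarios do not show

The generator emulates the idealized in-vitro setting: uniform fluid,
no walls other than the dish, no vasculature, membranes, shear-induced
diffusion, particle–particle interaction, agglomeration, gravity or
buoyancy, no coil electrical dynamics (voltage–current lag, mutual
inductance), and feedforward control without imaging feedback. Passing
tests therefore validate the numerics and the control machinery, not
in-vivo targeting performance. Quantities tied to the unprinted coil
geometry (absolute travel distances, attainable target concentrations,
the exact selected POD rank) are calibration-dependent and are checked at
order-of-magnitude or banded tolerances only.

## Known limitations

- The central scheme admits small negative concentrations at sharp fronts
  (documented above); the upwind option trades accuracy for monotonicity.
- Shooting nodes coincide with control segments (one node per level);
  finer shooting grids are not implemented.
- Free final time, terminal costs/constraints and 3-D grids are out of
  scope; γ only offsets the reported cost.
- The SLSQP inner solver sees the reduced problem only through finite
  differences; with very tight `max_nlp_iter` budgets it may stop at the
  iteration limit (status is reported, and the best-so-far schedule is
  still returned).
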