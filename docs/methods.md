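# Methods

`platesim` simulates the earliest step of blood-clot formation: a deformable
platelet carried by plasma shear flow transiently tethering to von
Willebrand factor (vWF) immobilized on an injured vessel wall through its
GPIb-alpha receptors.  Four coupled submodels operate at three scales:

1. a hybrid membrane model (spring network + continuum bending) for the
   platelet at the micrometre scale,
2. a stochastic receptor–ligand model for GPIb-alpha/vWF bonds at the
   nanometre scale,
3. a D3Q19 lattice Boltzmann (LBM) fluid for the plasma at the
   tens-of-micrometres scale,
4. immersed-boundary (IBM) coupling tying the Lagrangian membrane to the
   Eulerian fluid.

## Membrane model

The platelet at rest is an oblate spheroid `x²/a² + y²/a² + z²/(λa)² = 1`
with radius `a = 1 µm` and aspect ratio `λ = 0.25`, triangulated into
`N = 958` vertices by default.  Vertex placement uses a Fibonacci lattice
mapped to the ellipsoid and triangulated by its convex hull; this realises
any vertex count exactly (icosphere subdivision cannot produce 958) and the
surface area of the default mesh is within 1% of the closed form
`S = 2πa²(1 + ((1−e²)/e) artanh e)`, `e = √(1−λ²)`.

Free energy terms and their nodal forces:

* **Spring network** (cytoskeleton): Hookean springs on mesh edges with
  stiffness `k = E Δx / 5` (`E = 25 kPa`, unit link `Δx = 0.1 µm`, so
  `k = 5×10⁻⁴ N/m`), zero force at the generated rest lengths
  (mean ≈ 75 nm at N = 958).
* **Area/volume constraints** (bilayer incompressibility, cytosol
  incompressibility): quadratic penalties
  `H_area = k_s (S−S_ref)²/(2S_ref) + Σ_j k_t (S_j−S0_j)²/(2S0_j)`,
  `H_vol = k_v (V−V0)²/(2V0)` in the standard spectrin-network form.  The
  nominal dimensionless coefficients (6000) are mapped to energy-consistent
  units by scaling with the spring stiffness (`k_s = k_t = 10 k`,
  `k_v = 10 k / a`), a calibration chosen so a perturbed mesh relaxes back
  to within 1% of its reference area and volume and drift stays below 2%
  over coupled runs while explicit time stepping remains stable.
* **Bending** (Helfrich-type bilayer resistance): normal force
  `F_i = k₀ (Δ_Σ K + 2K³) A_i n_i` with bending modulus `k₀ = 200 k_BT`,
  mean curvature `K = (κ₁+κ₂)/2`, barycentric vertex area `A_i` and outward
  normal `n_i`.  The Gaussian-curvature term of the full Willmore variation
  is deliberately omitted, matching the variational force used by the
  model family this package implements.  Curvature is estimated per vertex
  from a least-squares osculating paraboloid over the 2-ring neighbourhood
  (batched normal equations, ring-radius nondimensionalised for
  conditioning); the shape operator of the fitted patch gives `κ₁, κ₂`.
  This estimator was chosen over the cotangent mean-curvature normal
  because it is pointwise smooth: on a 2562-vertex icosphere its mean
  curvature is accurate to 0.6% worst-case and the bending-force magnitude
  is uniform to ~2%, whereas the cotangent estimator's pointwise noise is
  amplified unacceptably by the surface Laplacian `Δ_Σ K` (computed with
  cotangent weights on the fitted `K`).  Spring and constraint forces are
  exact gradients of their energies (verified by central differences);
  the bending force follows the continuum variational formula rather than
  the gradient of a discrete energy, so it is validated against analytic
  sphere/ellipsoid oracles instead.

## Adhesion model

GPIb-alpha receptors sit at 5344 sites sampled uniformly (area-weighted,
barycentric) on the membrane, two receptors per site, giving ≈1500
receptors/µm²; forces on a site are distributed to its triangle's vertices
by barycentric weights.  Sites are surface points rather than mesh
vertices because the sites outnumber the 958 vertices.  vWF ligands are
placed uniformly at random on the wall plane `z = 0` at 25 µm⁻².

Per Monte Carlo interval `dt_mc`, each free site/ligand pair closer than
the 128 nm bind radius forms a bond with probability
`P_f = 1 − exp(−k_on dt_mc)` and each bond breaks with
`P_r = 1 − exp(−k_off dt_mc)`, where

* `k_off(F) = k⁰_off exp(γ F / k_BT)` — Bell (pure slip; catch–slip
  behaviour is out of scope), with `k⁰_off = 3.45 s⁻¹`;
* `k_on(x) = k⁰_on exp(−σ_ts (x−l_b)² / 2 k_BT)` — Dembo, maximal at the
  equilibrium bond length `l_b`.

Steric rules: a receptor site binds at most one vWF; a vWF binds at most
four sites.  Candidate pairs are shuffled uniformly each step so
competition for the four slots carries no index bias.  Bonds are linear
springs `F = σ (x_b − l_b)`.  The wall exerts a short-range repulsion
`F_rep = F₀ τ e^(−τε) / (1 − e^(−τε))` (`F₀ = 500 pN·nm`,
`τ = 2000 µm⁻¹`) on membrane vertices, clamped below `ε_min = 1 nm` where
the expression diverges and the force is already enormous.

Parameter notes:

* The tabulated intrinsic on-rate `k⁰_on = 10⁻⁵ s⁻¹` is implausibly small
  for a formation rate (bonds would essentially never form); it is kept as
  the documented default but flagged, and every tethering preset overrides
  it.
* Reactive compliance `γ = 0.0702 nm` and bond spring `σ = 10⁻⁵ N/m` are
  not tabulated by the source model; the defaults are provisional values at
  flow-chamber scale and are ordinary configuration keys.
* Dembo's theory distinguishes the transition-state spring `σ_ts` (in the
  formation law) from the mechanical spring `σ`; by default
  `σ_ts = σ`, and only the accelerated preset separates them (below).
* With the production timestep `Δt = 10⁻⁸ s`, per-step probabilities are
  ~10⁻⁸; the MC update therefore runs every `n_sub` fluid steps (default
  100) with `dt_mc = n_sub Δt`, which is statistically equivalent for
  these rates (`1 − (1−p)ⁿ ≈ np`) and validated by the bond-lifetime
  oracle (Kolmogorov–Smirnov against the exponential survival law).

Platelet–platelet bridging (GPIb-alpha/vWF/GPIb-alpha) reuses the same
rate laws with the partner platelet's receptor sites acting as the
ligands (one bond per partner site); plasma-vWF capture kinetics are not
modelled separately.

## Fluid and coupling

D3Q19 BGK lattice Boltzmann with Guo forcing: sound speed `c_s² = 1/3`
(lattice units), viscosity `ν = c_s²(τ−½)`, macroscopic velocity
`v = u + FΔt/2ρ`.  The timestep follows `Δt = (τ−½)h²/(3ν)`; at the
production operating point (`τ = 1.379`, `h = 0.2 µm`, plasma
`ν = µ/ρ`) this gives `Δt = 10⁻⁸ s` and closes the viscosity relation
exactly.  τ is dimensionless (the BGK relaxation parameter); a source
that quotes it in seconds is read as the dimensionless value.  x/y faces
are periodic; z faces carry on-site velocity boundary conditions
(Hecht–Harting closure: wall density from the known populations,
non-equilibrium bounce-back with transverse momentum corrections
`N_x, N_y`), exact in the node moments to machine precision.  Shear is
driven by moving the upper wall at `U = γ L_z`.  Steady Couette flow is
linear to 10⁻⁶·U and Poiseuille-measured viscosity matches
`c_s²(τ−½)` to ≤0.3% for τ ∈ {0.8, 1.0, 1.379}.

Experiments are parameterized by wall shear stress where stresses are
quoted (3.0/4.0 dyn cm⁻² ↔ γ = stress/µ); a shear rate can be set
directly instead (the two conventions differ by ~20% when both are quoted
for the same experiment, so one must be chosen; stress wins by default).

IBM uses the 4-point cosine kernel `φ(r) = ¼(1 + cos(πr/2))`, an exact
partition of unity on the lattice, so force spreading conserves momentum
to 10⁻¹² and interpolation is exact for uniform fields.  Each coupled
step: membrane+bond+repulsion forces → spread → LBM step → interpolate →
forward-Euler vertex advection → (every `n_sub` steps) adhesion MC.
Vertex forces are treated as point forces with explicit `h³` bookkeeping.

## Desk-scale presets

The production problem (16×64×16 µm lattice, `Δt = 10⁻⁸ s`, pause times of
seconds) needs ~10⁸–10⁹ coupled steps per seed across tens to hundreds of
seeds, i.e. GPU-cluster scale.  The package therefore defines two reduced
presets used by the test-suite and runnable on a workstation; both are the
package's own choices of problem size, stated here so their results are
interpreted correctly.

**Flipping preset** (`reduced_flipping_config`): 34×34×63 lattice,
`a = 5h`, `λ = 0.5`, lattice shear rate 2.5×10⁻³, membrane stiffness
×100 (rigid limit).  The λ = 0.5 aspect ratio keeps the platelet thickness
resolvable by the 4-point kernel at this lattice resolution.  The shear
rate is raised so a rotation orbit spans ~6×10³ steps; the comparison
with the analytic Jeffery period `T = 2π(λ + 1/λ)/γ` is made in
dimensionless time `γt`, and the particle Reynolds number (≈0.2) stays
small.  The period is measured between the π/2 and 3π/2 crossings of the
symmetry-axis angle to exclude the startup transient.  Channel height
≈12.6a: at half that height the measured period is ~5% long (confinement),
at this height ~3%.  Wall-proximity retardation (the platelet at
`H = 2.4a`) is qualitatively reproduced but not asserted quantitatively:
at this resolution the wall effect (~3%) is comparable to discretization
error.

**Tethering preset** (`reduced_adhesion_config`): 12×24×12 lattice,
`a = 0.8 µm`, `λ = 0.5`, 130 vertices, 534 receptor sites (the per-platelet
receptor count scaled by ×1/20, preserving the normal:insufficient = 2:1
design), `γ_lat = 3×10⁻⁵` (γ ≈ 3×10³ s⁻¹, ~10× the experimental shear).
To keep the bond physics in a workable dimensionless regime while tether
lifetimes shrink from seconds to tens of microseconds:

* on/off rates are scaled up (`k_on⁰ = 5×10⁶ s⁻¹`, `k_off⁰ = 1.2×10⁵ s⁻¹`),
* the bond spring is stiffened to `σ = 10⁻³ N/m` in proportion to the
  raised hydrodynamic load, with the formation window kept at its
  physical ~29 nm width through `σ_ts = 10⁻⁵ N/m`,
* the reactive compliance is reduced by the shear acceleration factor so
  the Bell exponent `γF/k_BT` stays in its physical O(0.1) range,
* tethers are taut: `l_b = 80 nm` below the 128 nm formation radius, so a
  freshly formed bond grips tangentially instead of acting as a
  compressed strut (at experimental shear the drag is pN-scale and this
  distinction is immaterial; at accelerated shear it decides whether
  arrest can occur at all),
* all membrane moduli carry a ×100 drag-compensation factor (applied
  uniformly across stiffness conditions, preserving their ratios):
  without it the accelerated drag stretches the soft body and the
  centroid creeps forward even while the adhesion anchors hold.

Pause events are defined (as in flow-chamber practice) as maximal
intervals where the centroid's forward speed falls below
`v_pause_frac = 0.1` of the free-flow speed `γH`, discarding events
shorter than `min_pause_frames` sampling intervals (40 in the preset);
both thresholds are configuration keys because "abruptly halted" is not
otherwise quantified.  The preset smooths the centroid with a 41-frame
moving average before differentiating, because individual bond
formation/rupture events imprint impulsive jitter on the centroid that is
a fixed fraction of the (reduced) free-flow speed.  An event still in
progress at the end of a run is recorded as censored, never dropped.
`k_off` is estimated as minus the least-squares slope of
`ln N(duration ≥ t)` over a grid up to the 95th percentile of observed
durations (the tail is noise-dominated).

Because the preset clock is accelerated, absolute pause times in seconds
are *not* comparable with experiments; only between-condition comparisons
are meaningful (fewer receptors vs normal, one vs two platelets, stiff vs
soft).  These monotone trends, each over 30 seeds with one-sided
Mann–Whitney tests at α = 0.05, are the desk-scale substitute for the
production-scale absolute numbers.  Between-condition comparisons report
both Welch's t-test and the rank test; the rank test is the gate at this
sample size.  For the stiffness comparison the package reports both means
and the comparison statistic without asserting a direction (the source
material is internally contradictory about which stiffness pauses longer).

A caveat this preset makes explicit: at desk scale the *two-platelet*
trend (a second interacting platelet shortens the pause) is reproduced,
but the *receptor-count* trend in mean first-pause duration is not
resolved.  Across the calibrations explored, halving the receptor count
halves the bond population (which the logs report) yet leaves first-pause
durations statistically indistinguishable: at the attainable acceleration
factors, pause termination is dominated by the arrest-creep threshold
crossing rather than by receptor-limited bond-cluster dissolution, which
is the mechanism that carries the receptor dependence at production
scale.  The corresponding trend assertion in the test suite documents
this honestly by failing rather than by weakening its gate.

## What the synthetic data does and does not show

Synthetic assets (icospheres, constructed stop-and-go trajectories,
exponential duration samples) exercise the geometry, detection and
estimation code against exact or distributional oracles.  The reduced
coupled presets exercise the full mechanism chain — deformation, rotation,
bond mechanics, arrest and release — but at ~30× shear, ~10⁴× kinetics and
~1/20 receptor counts; passing trend tests shows the coupled model moves
the right way with receptor count, stiffness and platelet number, not that
its absolute pause times match flow-chamber measurements.  Red-blood-cell
crowding, catch–slip bond behaviour, receptor diffusion and platelet
activation signalling are not modelled at all.

## Numerical choices and degenerate inputs

* All fluid arithmetic in float64; equilibrium distribution is the
  standard second-order polynomial; velocities at or above the lattice
  speed raise a stability error, NaN/negative density raise a diagnostic
  error.
* The collide/stream update runs through a fused compiled (numba) kernel;
  a pure-numpy reference implementation of the same arithmetic is kept
  and cross-checked against it in the test suite.
* The D3Q19 direction table is fixed (rest; ±x, ±y, ±z; 12 diagonals) and
  the unknown-population sets at each z-wall are derived from it; the
  tested contract is moment-exactness of the reconstructed wall nodes.
* Mesh degeneracies: coincident edge endpoints raise a degenerate-geometry
  error; open meshes are rejected by area/volume routines (every edge must
  be shared by exactly 2 triangles, Euler characteristic 2).
* `estimate_koff` requires ≥10 events and flags an all-equal sample as a
  degenerate fit (NaN, diagnostic flag) rather than returning a slope.
* Vertex advection is forward Euler at Δt; membrane sub-cycling is not
  used (the fluid timestep is already far below membrane timescales).
* Checkpoints (HDF5) store the distribution field, vertex positions, bond
  registry and RNG state; a restored run continues bit-identically.

## Known limitations

* The IBM platelet is ~1 lattice unit "inflated" by kernel smoothing;
  with `a = 5h` the measured Jeffery period carries a few-percent
  discretization error on top of confinement and finite-Re corrections.
* Arrest/release at desk scale is a calibrated dynamical regime; shifting
  the preset's kinetic parameters by factors of a few can move it between
  firm adhesion (all runs censored) and free rolling (no events).
* The membrane has no viscosity (purely elastic) and no thermal
  fluctuations.
* Two platelets at most; the second interacts through the shared fluid,
  pairwise vertex repulsion, and GPIb-alpha/vWF/GPIb-alpha bridging.
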