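# Methods

## Forward model

Volume conduction at TES/EEG frequencies (< 100 Hz) is quasi-static: the
potential ψ satisfies ∇·(σ∇ψ) = 0 in the head Ω with an insulating boundary
away from the electrodes. Electrodes follow the complete electrode model
(CEM): each contact patch E_l has a contact impedance per unit area z_l
(Ω·m²), a single electrode potential V_l, and carries a prescribed total
current I_l, with ψ + z_l σ∂ψ/∂n = V_l on E_l. All quantities are real
(capacitive effects neglected); SI units throughout (m, S/m, A, V).

First-order Galerkin discretization on tetrahedra gives a symmetric
(N+L)×(N+L) system K v = f:

* volume stiffness ∫σ∇φ_i·∇φ_j (constant gradients per tet);
* CEM surface terms per electrode: (1/z_l)∫φ_iφ_j facet mass blocks
  (closed form A/12·(1+δ_ij) on linear triangles), couplings −(1/z_l)∫φ_i
  between boundary nodes and the electrode unknown, and the diagonal
  (1/z_l)|E_l|;
* loads: f_l = I_l on electrode unknowns for TES; for an EEG dipole **d**
  at **r**, the partial-integration load f_n = d·∇φ_n(r) on the four
  vertices of the containing tet (lowest-index tet on ties, for
  determinism).

K is singular with the constant vector as nullspace; since every admissible
load sums to zero (current conservation, enforced with a 1e-10 relative
tolerance), the system is consistent. Uniqueness comes from the grounding
contract of zero-mean electrode potentials — the average-reference EEG
convention, montage-independent, applied as a post-solve shift.

### Solvers

The default path is a cached sparse LU of the one-node-grounded reduction
plus iterative refinement until the true relative residual of the full
system is below the tolerance (default 1e-11; typical direct residuals are
~1e-14). The factorization is computed once per assembled system, so the
L−1 solves of a transfer matrix and all subsequent pattern evaluations cost
only triangular solves. Systems here are ~1.5×10⁴ unknowns — far below the
point where a direct factorization becomes unattractive.

A conjugate-gradient path (`method="cg"`) is kept as an independent check.
Because CG requires a symmetric positive-definite preconditioner and scipy
ships no incomplete Cholesky, the preconditioner is an incomplete LDLᵀ
reconstructed from an incomplete LU with natural ordering and no pivoting
(K ≈ UᵀD⁻¹U, M⁻¹ = U⁻¹DU⁻ᵀ). The iterates stay orthogonal to the nullspace
automatically (K maps into the complement of the constant vector). Direct
and iterative paths agree to better than 1e-9 in the tests. Iteration caps
default to 5000; diagnostics (residual, iteration count, method) are
recorded on every solution.

Per-element fields are E = −∇ψ (constant per element) and J = σE. The
current actually drawn through an electrode is recovered with the
variationally consistent CEM flux (1/z_l)∫(V_l − ψ)dS, which reproduces
I_l to solver tolerance; the raw element-gradient flux ∫J·n̂ dS is also
available but is first-order and noticeably less accurate on practical
meshes — it is exposed for inspection, not verification.

## Head model

The synthetic head is a ball of concentric shells, by default
brain/CSF/skull/scalp with outer radii 80/83/88/94 mm — conventional
4-layer values, configurable — and isotropic conductivities 0.33 (gray
matter value used for the whole brain shell), 1.79, 0.008 and 0.35 S/m;
white matter (0.2) and eyes (1.5) exist as extra labels.

Meshing is deterministic with no external mesher: points are placed on
concentric Fibonacci-lattice spheres — every shell interface, plus
intermediate radii so the radial spacing never exceeds the target edge
length — and tetrahedralized with Delaunay (the domain is a ball, so the
Delaunay complex fills it exactly). Element tissue labels come from the
shell containing the centroid. Near-degenerate slivers from cospherical
point sets are dropped at a 1e-9·edge³ volume threshold; orientation is
repaired to positive volumes. At the default 7 mm edge the 4-layer head has
~83k elements and ~15k nodes, with ~0.3% of elements below the 0.05
stretch-factor quality threshold (stretch factor = inscribed-sphere radius
over longest edge, normalized by 2√6 so a regular tetrahedron scores 1;
the normalization constant is this package's choice).

Electrodes sit on a Fibonacci lattice at the outer radius; contact patches
are the boundary facets whose centroid lies within the contact radius
(default 4 mm, the 8 mm-diameter pad), assigned to the nearest electrode so
patches are disjoint. The default contact impedance 2.01 Ω·m² is the
per-unit-area equivalent of a 40 kΩ lumped resistance on that pad
(z = R·πd²/4).

What the synthetic head does *not* emulate: cortical folding, skull
foramina and thickness variation, anisotropy, internal air, and realistic
electrode geometry. Passing tests therefore validate the solver, the
algorithms and their relative orderings — not absolute dose predictions
for any real anatomy.

## Injection patterns and the transfer matrix

The elementary basis is the one-source set: pattern i has +I_max on
electrode i and −I_max/(L−1) elsewhere (ℓ1 norm exactly 2·I_max); the
first L−1 patterns form a complete basis of zero-sum injections, and any
zero-sum pattern decomposes uniquely on it by solving the (L−1)-dim map to
the first L−1 electrode currents. Solving each basis pattern yields the
3T×(L−1) transfer matrix of element E-field responses, flattened
element-major, component-minor (x, y, z per element) — the single
convention used everywhere.

## Targeting methods

A target is built from a seed point: the n (default 12) brain elements
nearest the seed that touch the brain outer interface, with direction d =
normalized average of the outward interface-facet normals and center r =
ROI centroid.

* **LS**: c = (TᵀT)⁻¹Tᵀe, e = b⊗d (desired field replicated on ROI
  elements). The normal-equations route is exact here because the problem
  is strongly overdetermined (3T ≫ L−1) and well-conditioned at these
  montage sizes.
* **LCMV**: c = G⁻¹T̃ᵀ(T̃G⁻¹T̃ᵀ)⁻¹d with G = TᵀT and T̃ the three rows at
  the target element; T̃c = d holds exactly before rescaling.
* Both are then ℓ1-rescaled to p ← 2·I_max·p/‖p‖₁, so the positive
  currents sum to exactly I_max. Both operate on the whole-head transfer
  matrix (not a brain-restricted one): minimizing the field only over gray
  matter invites spurious source–sink pairs elsewhere in the head.
* **One-source**: the dipole topography's argmax is the source (I_max),
  all other electrodes equal sinks. Deliberately exempt from the
  per-electrode cap; it is the uncapped reciprocity reference.
* **Opposite**: the 10 top-ranked electrodes are sources (+I_max/10 each),
  the 30 bottom-ranked are sinks (−I_max/30 each); the per-electrode
  maximum is exactly I_max/10 (≤ 200 μA at a 2 mA budget).
* **Ring**: sources as in *opposite*; sinks are the 10 electrodes nearest
  the source-set centroid, excluding sources. "Nearest" is 3-D Euclidean
  distance from electrode centers to the centroid — a "ring of closest
  electrodes" admits several readings (distance to the centroid, to the
  nearest source, graph adjacency); the centroid rule is adopted as the
  simplest rotation-invariant one that reproduces the ring topology.
* **ROADSS**: sources as above; r_m = mean source position, d_rm =
  |r_m − r|, r_s = r − d_rm·d; sinks are the 10 electrodes nearest r_s
  that are not sources. Radial targets put r_s inside the source cluster
  (ring-like sinks), tangential targets push it to the far side
  (opposite-like). The sink count is fixed at n_sources (configurable).

Ranking ties are broken by lowest electrode index. On montages smaller
than 40 electrodes the 10/30/10 counts scale down proportionally. The
brute-force pole-pair oracle enumerates all L(L−1)/2 pairs, reconstructing
each pair's field at the target by linearity, and maximizes the
directional potential gradient d·∇ψ = −d·E — the quantity the reciprocity
identity ties to the topography voltage difference, which is why its
electrode A coincides with the one-source topography argmax.

### Polarity convention

With the EEG dipole load f_n = +d·∇φ_n and injected currents positive into
the head, the discrete identity Φ(a)−Φ(b) = d·∇ψ_ab(r)/I_ab is exact up to
solver error (K is symmetric). Placing the *source* on the topography
maximum therefore maximizes d·∇ψ, i.e. the delivered current density at
the target points along −d for an outward normal d — anodal stimulation
drives current into the cortex. Method comparisons consequently use the
magnitude |J·d| of the directional intensity; the metrics API reports the
signed value, and reversing sources and sinks reverses the sign.

## Performance metrics

All density masses are |J|_i·V_i (the volume factor makes the measures
mesh-resolution independent; "weighted average" is otherwise
underspecified), and sphere membership is decided by element centroid.

* intensity / directional intensity / directionality: volume-weighted mean
  J over the ROI; |J̄|, J̄·d, and their ratio;
* TE_global: distance from the target center to the CoG of brain elements
  with |J| ≥ 75% of the maximum;
* TE_local: the same, restricted to elements within 3 cm of the target
  (threshold re-applied inside the neighborhood); bounded by 3 cm by
  construction;
* global focality: smallest target-centered radius containing half the
  total brain density mass (computed by sorting centroid distances);
* F_LOC: mass within 1 cm of the local CoG over mass within 3 cm of the
  target. If the local CoG sits more than 2 cm from the target the inner
  sphere escapes the outer one and the ratio can exceed 1; the value is
  reported as-is with a warning.

## Analytic oracles

The multilayer dipole potential uses per-degree radial profiles
A_k rⁿ + B_k r^−(n+1) (plus the primary dipole term in the innermost
layer), with coefficients from a small linear system per degree enforcing
potential/current continuity at interfaces and an insulating outer
boundary; radii are normalized to the outer radius for conditioning. The
series tail is geometric in (dipole radius / outer radius); 80 terms
default. The n=1 term reproduces the classical center-dipole closed form
3|d|cosθ/(4πσR²).

Point-electrode pairs on a homogeneous sphere have the surface series
Σ(2n+1)/n·P_n, which converges only conditionally on the surface; it is
summed exactly via Σ P_n(u) = (2−2u)^−1/2 − 1 and
Σ P_n(u)/n = ln[2/(1−u+√(2−2u))]. Interior points use the geometrically
convergent (r/R)ⁿ series. Multilayer point injection is not supported.

FEM-oracle comparisons use the standard relative difference measure
RDM = ‖v̂₁ − v̂₂‖ of zero-meaned, normalized patterns and the magnitude
ratio MAG, with 5% / 10% thresholds. At the default resolution the 4-layer
dipole topography agrees with the series at RDM ≈ 4%, the single-shell
pair injection at RDM ≈ 3% (excluding 10° caps around the injection
singularities).

## Problem sizes and numerical choices

Default study conditions: 4-layer head at 7 mm target edge (~83k elements,
inside the 60–100k band used for the validation runs), 64 electrodes
(128 for the montage-density comparison), I_max = 1 mA, cap I_max/10,
solver tolerance 1e-11, 75% CoG threshold, 1 cm / 3 cm focality radii.
The single-shell oracle comparison uses a 6 mm edge. These sizes keep a
full validation pass to a few minutes on one CPU while leaving the
qualitative method orderings stable; they are the package's default study
conditions, not tuning knobs.

Degenerate inputs are rejected loudly: non-increasing shell radii, shells
thinner than a quarter edge (named by shell index), electrodes that
capture no boundary facet, non-conservative loads, dipoles outside the
brain compartment, singular optimizer systems.

## Known limitations

* Spherical geometry only; no subject-specific anatomy, anisotropy or
  internal air. Absolute current densities are indicative, not dosimetric.
* First-order elements: raw boundary fluxes of J converge slowly (the CEM
  flux functional is the reliable one); field accuracy inside thin shells
  is limited by one element layer across the CSF at the default edge.
* The LS/LCMV implementations are the unconstrained closed forms used as
  references; per-electrode-capped convex variants are out of scope.
* The iterative-solver path is a verification tool; performance work
  (better preconditioners, matrix-free assembly) has not been pursued
  beyond what the default direct path makes unnecessary.
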