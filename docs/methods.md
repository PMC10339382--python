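# Methods

## Problem and scope

`toothmor` builds a real-time surrogate for the parametric stress analysis
of a transplanted tooth. The quantity of interest is the nodal von Mises
stress (VMS) field of a tooth-in-bone model under an occlusal force split
into a lateral component Fy and an axial (bite) component Fz, each ranging
over 50–200 N. High-fidelity solves are expensive, so the workflow is split
offline/online: a small set of finite-element snapshots on a uniform
(Fy, Fz) grid is compressed into a separated (sum-of-rank-one) tensor
representation once, after which any new force combination inside the grid
is answered by interpolating the parametric mode functions — in
milliseconds, with no further finite-element solve.

## Model geometry

The spatial domain is a procedurally generated 2-D plane-strain
cross-section rather than a patient-specific 3-D mesh: a dentin shell
around a root canal, a 200 µm periodontal ligament (PDL) ring, alveolar
bone out to a fixed outer boundary, and a rectangular crown block whose
upper edge carries the load. The root profile is a "stadium" curve
(parallel walls plus a semicircular apex); every tissue layer is an offset
strip of that curve, which makes the triangulation structured,
deterministic, and guarantees that the ligament topologically separates
dentin from bone. The canal keeps all layers annular (no singular core
meshing) and mirrors the anatomy of a real root.

Defaults: root half-width 1.2 mm, canal at 30 % of it, wall length 1.5×
the half-width, bone outer boundary at 2.4 mm, crown height 0.8 mm, element
size 0.1 mm (two elements through the ligament thickness). The default
cross-section has ≈3 300 linear triangles (≈7 400 nodes after quadratic
promotion), chosen to resolve the thin ligament while keeping the full
4×4-grid study at desk scale (minutes on one CPU core).

## Constitutive models

Dentin (E = 18 600 MPa, ν = 0.31) and bone (E = 13 700 MPa, ν = 0.30) are
homogeneous Saint Venant–Kirchhoff solids — identical to linear elasticity
at their working strains of ~10⁻³. The ligament uses the first-order
compressible Ogden law

U = (2μ/α²)(λ̄₁^α + λ̄₂^α + λ̄₃^α − 3) + (1/D)(J − 1)²,

with λ̄ᵢ = J^(−1/3)λᵢ. With this prefactor the ground-state shear modulus
is exactly μ and the bulk modulus is 2/D; a 2μα prefactor variant seen in
some renderings of the law is dimensionally inconsistent with that reading
and is not used. Cauchy stress follows in closed form from the spectral
decomposition of the left stretch,
σᵢ = (2μ/(αJ))(λ̄ᵢ^α − mean λ̄^α) + (2/D)(J − 1),
and is verified in the tests against central-difference differentiation of
the energy.

Ligament defaults are μ = 0.5 MPa, α = 10, and D set for an effective
ground-state Poisson ratio of 0.45 (D ≈ 0.414 MPa⁻¹). Experimental PDL fits
span orders of magnitude; these values describe a compliant, strongly
strain-stiffening, nearly incompressible tissue and were chosen on a
load-carrying argument: the mean ligament traction at 200 N on this section
is ≈0.9 MPa, and with these constants the tissue carries it at a few tens
of percent strain. A much softer ligament (μ of order 10⁻² MPa with the
same near-incompressibility ratio) cannot carry that traction at all — its
volumetric stress saturates at 2/D ≈ 0.1 MPa and the quasi-static problem
has no moderate-strain solution, so Newton cannot converge. All constants
are configurable placeholders, not measured values.

## Load application

Forces are applied as a uniformly distributed dead traction over the
crown's upper edge (point loads would create mesh-dependent
singularities), with resultant (Fy, −Fz): Fy acts along +x, Fz is the
downward bite force. A 2-D unit-depth slice carrying the full occlusal
force would see unphysically high tractions, so the solver divides the
force by an out-of-plane `slice_depth` (default 30 mm) representing the
extent over which a real 3-D root spreads the load; all reported force
balances are per unit depth. Reactions at the fixed outer bone boundary
balance the applied resultant to 10⁻⁸ relative.

## Finite-element solver

Total-Lagrangian plane strain on 6-node quadratic triangles (straight
sided, affine mapping, 3-point Gauss rule). Quadratic displacement
interpolation mitigates volumetric locking in the nearly incompressible
ligament without a mixed formulation. Newton–Raphson with relative residual
tolerance 10⁻⁸, at most 25 iterations per step, 4 load increments, and
automatic step halving (budget 6) on divergence. The tangent is assembled
analytically for the Saint Venant–Kirchhoff groups and by per-element
forward differences (step 10⁻⁷) for the Ogden group; convergence is always
judged on the exact residual, so the tangent choice affects speed only.
With the stiffness contrast between dentin and ligament (~4·10⁴) the
achievable relative residual floors near 10⁻⁸ in double precision, which is
why the tolerance is not set tighter. Nodal Cauchy tensors are recovered by
quadrature-weighted averaging of Gauss-point values; the von Mises field
includes the plane-strain out-of-plane normal stress.

## Snapshots and the separated decomposition

The snapshot tensor S(x, i, j) stacks nodal VMS fields over the uniform
force grid (static solves only; no time coordinate). The reduced model is
built greedily: each enrichment step finds the best rank-one correction
a⊗g⊗h to the current residual by an alternating fixed point that cyclically
replaces each factor with its least-squares optimum given the other two
(initialized from the leading singular vectors of the residual's parametric
unfoldings; relative-change tolerance 10⁻⁸, at most 200 sweeps). Each
accepted correction is a least-squares projection, so the relative
Frobenius residual history is non-increasing; enrichment stops at 10⁻⁴
relative residual or 50 modes. Parametric factors are stored unit-norm with
a positive-first-entry sign convention so serialized models compare across
runs.

Online evaluation interpolates each mode's parametric vectors at the query
forces — piecewise linear by default (conservative and monotone between
samples), natural cubic splines optionally; the scheme is recorded in the
model container. Queries outside the training box are refused rather than
extrapolated. The online stage performs no element assembly or solve, which
the tests assert through a solver call counter.

## Error assessment

Accuracy is certified at the centers of the parameter-grid subdomains
(for the canonical 4×4 grid: the 9 points {75, 125, 175}²), the locations
farthest from the training snapshots. For each center a fresh high-fidelity
reference is computed and the relative L2 error δ = ‖U − U_ref‖₂/‖U_ref‖₂
over the nodal VMS vector is reported as a percentage. δ is taken over the
whole mesh by default; a region mask (root dentin only, ligament only) is
available and recorded in the report header.

## Analytic surrogate (synthetic data)

A separable surrogate Σₖ aₖ(x)gₖ(Fy)hₖ(Fz) with smooth positive profiles
stands in for FE snapshots in tests of the decomposition itself. Its
parametric factor sets are orthonormalized across modes; for such tensors
greedy rank-one deflation recovers the construction exactly in `rank`
modes, which turns the generator into an exact oracle. Higher modes are
rescaled so the positive leading mode dominates every entry (preserving
rank and orthogonality) to keep the tensor stress-like (nonnegative). An
optional seeded multiplicative Gaussian perturbation destroys exact
separability in a controlled way. What the surrogate does not emulate:
mesh-dependent stress concentrations, solver noise, and the physical
coupling between the two force parameters — so surrogate-based tests
certify the decomposition and interpolation machinery, not the mechanics.

## Numerical choices and edge cases

- Zero load returns the zero solution without iteration; a zero snapshot
  tensor yields a 0-mode model; a zero-norm reference makes δ an explicit
  error, never a silent 0 or ∞.
- An identically zero residual stops enrichment via a dedicated signal.
- Near-equal principal stretches in the ligament are handled continuously
  (the principal-direction angle degenerates exactly where the stress
  becomes isotropic).
- Containers (HDF5) embed a payload checksum and the producing config's
  digest; truncated or tampered files fail on load.
- Trend classification calls a response quadratic only if the degree-2 fit
  reduces the relative RMSE by ≥2× and the curvature term spans ≥5 % of the
  response range, so noise-level curvature is not promoted.

## Known limitations

- The 2-D idealized section reproduces the layered mechanics (stiff core,
  soft thin ring, stiff matrix) but not patient anatomy; absolute stress
  values are not clinically meaningful.
- No contact, fatigue, dynamics, or 3-D effects; perfect bonding between
  tissues.
- The greedy decomposition is exact only for orthogonally decomposable
  tensors; on general data it converges geometrically and may use more
  modes than the minimal CP rank.
- Linear parametric interpolation limits online accuracy to O(Δ²) in the
  grid spacing; refining the uniform grid (rebuilding offline) is the
  supported accuracy lever.
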