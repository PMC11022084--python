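# Methods

This note documents the models, discretizations and design choices behind
`equivol`, and what the synthetic test bed does and does not establish.

## Laminar coordinates and the registration model

A laminar coordinate system between an inner surface `S0` and an outer
surface `S1` is an embedding `ψ : [0,1] × S0 → R³` with `ψ(0,·) = id` and
`ψ(1, S0) = S1`; the slices `S(t)` are layers, the curves `t ↦ ψ(t,x)`
streamlines, and thickness is streamline length.  We construct `ψ` by
surface LDDMM reduced to the vertices of `S0`: the velocity field lives in
a Gaussian reproducing-kernel space, so the optimal field is the finite
expansion `v(t,·) = Σ_l K(·, q(t,l)) α(t,l)` over the moving vertices and
extends analytically to all of R³ (a flow of diffeomorphisms, not just a
surface deformation).  Matching is scored by a squared varifold distance on
face centers, areas and unit normals — parametrization-invariant, so the
two surfaces may have unrelated meshings.

### Discretization

* Time: `T` uniform steps (default `T = 10`), forward Euler for the state
  equation.  The energy `h Σ_t αᵀ K(q_t) α` and the Euler flow are
  discretized *consistently*, and the gradient is the exact adjoint of this
  discrete forward model (verified against finite differences to 1e-6
  relative).  A consequence worth knowing:
  the momenta are calibrated to the Euler scheme, so re-integrating the
  streamlines with RK4 lands on a slightly different endpoint (≈1.5% for
  the standard sphere phantom).  Closed-form endpoint comparisons therefore
  use the Euler grid; grid-refinement (RK4) is used where only internal
  consistency matters (the equivolume bound).
* Kernels: single Gaussian by default; flow width `0.4 ×` and varifold
  width `0.5 ×` the mean inter-surface distance when not set explicitly.
  A normalized sum of Gaussians is available for multiscale problems — a
  rigid-shift-dominated registration needs a flow kernel comparable to the
  object size, not to the gap (see `test_sphere_translation_reaches_target`).
* Discrepancy weight: default `10`.  The varifold term is not scale-free
  (it grows like area²), so the default is calibrated to the desk-scale
  phantoms (unit-radius objects); for other scales set it per run.
* Kernel sums are dense `O(N²)`; a warning is raised above 5000 points.

### Normality constraint

The constraint "streamlines perpendicular to the evolving layers" is
`v(t, q) = λ n(t, q)` with `λ ≥ 0`, imposed per vertex and per time step as
the scalar residual

```
c = |v| − nᵀ v = 0
```

which vanishes iff `v` is a non-negative multiple of `n` (with `|v|`
smoothed as `sqrt(|v|² + ε²)`, `ε = 1e-9`, for differentiability at rest).
A quadratic variant `c = |v|² − nᵀ v` is selectable
(`constraint_form="quadratic"`) for comparison; it is dimensionally
inhomogeneous (it can only vanish at speeds 0 or 1 for normal motion) and
is not the default.  The evolving normal `n(t,·)` is recomputed from the
deformed triangulation at each step, and its dependence on the vertex
positions is part of the adjoint gradient.

Augmented Lagrangian schedule: multipliers `λ_AL ← λ_AL + μ c` after each
inner L-BFGS solve (memory 10, gradient tolerance 1e-6); `μ` starts at 1
and is multiplied by 10 whenever `max|c|` fails to shrink by a factor 4.
Convergence is declared on the *relative* residual
`max |c| / max(|v|, ε)` (default tolerance 1e-3).  Failure to converge sets
a warning flag on the result rather than raising — the flow is still
usable.

## Surface Jacobian, equivolumetric depth, time change

The surface Jacobian `σ(t,x)` (infinitesimal area ratio of `ψ(t,·)`) is
estimated two independent ways:

1. **One-ring ratio** `σ = a(t,x)/a(0,x)` on the evolving triangulation —
   exact under similarity transforms, `O(h²)` otherwise.
2. **Cofactor transport**: `σ = det(∂xφ) |∂xφ⁻ᵀ ν₀|`, computed by
   integrating `ζ̇ = div(v) ζ − (∂x v)ᵀ ζ` with RK4 along streamlines using
   the exact kernel Jacobian of `v`; `σ = |ζ|`.  (A simplified variant
   without the `ζ` factor on the divergence term is kept behind
   `debug_ode=True` for debugging comparisons only; it does not reproduce
   the one-ring estimate.)

Their agreement (≤2% on all synthetic registrations when evaluated on the
same integration grid) is a strong end-to-end check, since they share no
code path.

The equivolumetric depth `γ(t,x) = ∫₀ᵗ (∂tψ·n) σ du` is accumulated with a
trapezoidal rule in which `∂tψ du` is realized exactly as the polyline
segment displacement and the smooth factor `n σ` is endpoint-averaged.
This "segment" quadrature is exact on piecewise-linear streamlines and,
unlike a nodal-velocity trapezoid, needs no velocity estimate at the ends
of resampled streamlines (where finite differences are one-sided); on the
closed-form radial flow with 21 time nodes it lowers the equivolume
self-consistency deviation from 2.2e-3 to 5e-4.  A nodal-velocity variant
remains available (`quadrature="nodal"`).

The time change is `τ = γ / c0` with `c0 = γ(1,·)` (the per-streamline
equivolumetric thickness; the global constant of the strict equivolume
condition is absorbed into `c0`, i.e. normalized to 1).  `τ` runs from 0
to 1 exactly and is nondecreasing whenever the flow does not backtrack;
`c0 ≤ 0` raises with the offending vertex named.  Layer extraction inverts
`τ(t) = ε` per streamline by piecewise-linear interpolation; a stalled
segment (zero `γ` increment) deterministically maps to its left endpoint.
Reparametrization resamples every streamline at fixed `τ`-levels — the
streamlines as point sets are untouched, and any normality they had to the
old layers is generally lost to the new ones (a known trade-off:
simultaneously normal *and* equivolumetric coordinates would require
solving a harder control problem in which the tangential field is forced
to zero and `c0` becomes the unknown; that inverse problem is out of
scope here).

Layer normals along a flow are winding-consistent and globally oriented so
`n·w ≥ 0` at `t = 0`; quantities of the form `ζH` are invariant under a
global flip, so the validation identity is orientation-safe.

## Discrete differential geometry

* Vertex normals: area-weighted average of incident face normals
  (counterclockwise winding = outward).
* Mean curvature: cotangent Laplacian of the coordinates (mean-curvature
  normal) with barycentric vertex areas, projected on the vertex normal;
  sign fixed so an outward-oriented sphere of radius `r` has `H = −1/r`.
  Mean error on icospheres converges under refinement; the 12
  valence-five vertices keep an `O(1)` pointwise wobble typical of the
  estimator — aggregate statistics (mean, RMS) are the meaningful outputs.
* Tangential divergence: per-vertex orthonormal tangent basis from the
  normal, least-squares linear fit of the (tangentially projected) field
  over the one-ring, divergence = tangential trace of the fitted
  differential.  Exact for linear fields on flat meshes.
* Boundary vertices of open surfaces are flagged
  (`boundary_vertex_mask`) and excluded from the validation identity;
  their curvature/divergence values come from the partial one-ring.
* Degenerate faces (area < 1e-12 × bbox-diagonal²) are rejected at
  load/validation.

The identity `σ⁻¹ ∂tσ = div_S ρ − 2 ζ H` (with `w = ρ + ζ n` the layer
velocity split into tangential and normal parts, `∂tσ` by centered time
differences) ties all of these together; on unit-speed sphere inflation
(subdivision 4, 21 time nodes) the relative RMS residual is ≈2.2%,
dropping to ≈1.3% one refinement level up.

## Synthetic phantoms: what they emulate, what they do not

* `concentric_spheres` — closed surfaces, pure radial flow; every quantity
  has a closed form.  The workhorse for quantitative acceptance.
* `ring_pair` — inner torus of constant tube radius, outer torus with an
  angle-dependent radius (default `0.3 + 0.1 cos φ`): spatially varying
  thickness with a per-angle closed form.  A flat annular-band variant
  (`slab=True`) exists for visual comparison.
* `wavy_shell` — open folded sheet `z = A sin(2πf x)` offset along its
  analytic normals: gyral crowns (negative inward curvature) and sulcal
  fundi (positive) in one patch, with the self-intersection limit
  `A(2πf)² h < 1` enforced.  Used for the qualitative Bok signature: the
  `ε = 0.25` equivolumetric layer sits at a fractional depth > 0.25 over
  crowns (area expands outward, so the first quarter of the volume needs
  more length) and < 0.25 over fundi — deep layers thick in the gyrus,
  thin in the sulcus.
* `flat_slab` — the degenerate limit where everything is exact and
  equivolumetric ≡ equidistant.

Generators are deterministic; vertex jitter only appears when a seed is
given.  These phantoms exercise the geometry but not real-data
pathologies: segmentation noise, topology defects, strongly anisotropic
meshing, or contact between opposing banks of a sulcus.  Passing the suite
shows the estimators and the optimization are correct and consistent at
desk scale (≲ a few thousand vertices), not that the pipeline is robust to
imaging artifacts.

## Problem sizes and defaults used in the shipped checks

The standard quantitative phantom is the subdivision-3 icosphere pair
(642 vertices, 1280 faces) with `T = 10`, `w_D = 10`, L-BFGS capped at 300
inner iterations — chosen as the smallest configuration on which the
closed-form oracles are met with comfortable margins (thickness within
1.3%, mid-layer radius within 0.7%, normality residual ≈ 7e-5).  The
identity check runs at subdivision 4 with 21 time nodes, with one
refinement level (subdivision 5, 41 nodes) to confirm convergence.

## Known limitations

* `O(N²)` kernel and varifold sums; no fast summation backend.
* The constrained solver assumes the unconstrained optimum is a good basin:
  severely folded pairs may need a multiscale kernel schedule, which is
  supported (sum-of-Gaussians) but not automated.
* Equivolumetric reparametrization requires a non-backtracking flow
  (`c0 > 0` per streamline); strongly tangential unconstrained flows can
  violate monotonicity of `τ` at isolated vertices, which is reported, not
  repaired.
* PLY output stores float32 coordinates (the format's convention); OFF and
  VTK round-trip at full double precision.
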