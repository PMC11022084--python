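# equivol

Normal and equivolumetric laminar coordinate systems between two
triangulated surfaces.

## The problem

Many anatomical regions in 3D imaging data — most prominently the folded
cerebral cortex — are volumes sandwiched between an inner surface (the
grey–white boundary) and an outer surface (the pial boundary).  Analyzing
such a region calls for coordinates aligned with those surfaces: a family
of intermediate **layers** `S(t)` interpolating from `S0` (inner, `t=0`) to
`S1` (outer, `t=1`), and **streamlines** `t ↦ ψ(t, x)` — the discrete
analogue of cortical columns — crossing the layers.  Thickness is the
streamline length `θ(x) = ∫₀¹ |∂t ψ| dt`.

Two geometric priors matter:

* **Normality** — streamlines should cross the layers perpendicularly, so
  they behave like columns rather than shearing sideways.
* **Bok's equivolume hypothesis** — in a folded cortex, layers preserve
  *volume*, not distance: layers thin where the fold compresses area and
  thicken where it expands.  Equidistant layers misplace laminae in gyri
  and sulci; equivolumetric layers do not.

`equivol` builds such coordinate systems purely on surfaces (no volumetric
level-set grid), which also makes it applicable to regions bounded by
*open* surface patches.

## The method

1. **Diffeomorphic surface registration (reduced LDDMM).**  The inner
   surface's vertices `q(t, k)` are flowed by a velocity field in a
   reproducing-kernel Hilbert space `V` with kernel
   `K(x, y) = exp(−|x−y|²/2λ²) I₃`, minimizing

   ```
   ∫₀¹ Σ_{k,l} α(t,k)ᵀ K(q(t,k), q(t,l)) α(t,l) dt  +  w_D · D(S(1), S1)
   ```

   over the momenta `α(t, k)`, where `D` is a squared **varifold**
   discrepancy (orientation-aware kernel distance between unparametrized
   surfaces; spatial Gaussian × `(nᵀn′)²`).  The optimal field is the
   kernel expansion `v(t, ·) = Σ_l K(·, q(t,l)) α(t,l)`, known in closed
   form everywhere, with exact space derivatives.  Gradients are exact
   adjoints of the discrete forward model; inner solves use L-BFGS.

2. **Streamline-normality constraint.**  The residual
   `c = |v| − nᵀv` vanishes exactly when the velocity is a non-negative
   multiple of the evolving layer normal.  It is enforced per vertex and
   time step by an augmented Lagrangian (multiplier update `λ ← λ + μ c`,
   penalty growth when the residual stalls).

3. **Equivolumetric reparametrization.**  With the surface Jacobian
   `σ(t, x)` (one-ring area ratio, cross-checked by the cofactor transport
   `ζ̇ = div(v) ζ − (∂x v)ᵀ ζ`, `σ = |ζ|`), the equivolumetric depth

   ```
   γ(t, x) = ∫₀ᵗ (∂t ψ · n) σ du ,      c0(x) = γ(1, x),
   τ(t, x) = γ(t, x) / c0(x)
   ```

   is the relative volumetric depth along each streamline.  Resampling the
   layers at fixed `τ`-levels (streamlines unchanged) yields layers that
   satisfy the localized equivolume property: between any two levels every
   infinitesimal tube contains the same fraction of its volume.

Validation utilities include the area-evolution identity
`σ⁻¹ ∂t σ = div_S ρ − 2 ζ H` (a strong cross-check of the curvature,
divergence and Jacobian estimators), symmetrized nearest-vertex distance
reports with CDFs, and an equivolume deviation measure.

## Worked example

Concentric spheres `r0=1 → r1=2` have a fully analytic laminar system:
radial streamlines of length 1, `σ = r²`, and equal-volume shells at
radius `(1 + ε·7)^{1/3}` — the mid layer sits at `4.5^{1/3} ≈ 1.651`,
clearly off the equidistant `1.5`.

```python
import numpy as np
from equivol import (RegistrationConfig, register_normal, build_laminar_system,
                     surface_jacobian, equivol_depth, time_change,
                     extract_equivol_layer, thickness)
from equivol.synthetic import concentric_spheres

inner, outer = concentric_spheres(r0=1.0, r1=2.0, resolution=2)
result = register_normal(inner, outer, RegistrationConfig(discrepancy_weight=10.0))
print(f"normality residual: {result.residual_trace[-1]:.2e}")

system = build_laminar_system(result)
theta = thickness(system)
print(f"thickness: {theta.mean():.4f} +/- {theta.std():.4f}  (exact: 1.0)")

sigma = surface_jacobian(system)
gamma = equivol_depth(system, sigma)
c0, tau = time_change(gamma)
print(f"equivolumetric thickness c0: {c0.mean():.4f}  (exact: 7/3 = 2.3333)")

mid = extract_equivol_layer(system, tau, 0.5)
radii = np.linalg.norm(mid.vertices, axis=1)
print(f"eps=0.5 layer radius: {radii.mean():.4f}  "
      f"(equal-volume shell: 4.5^(1/3) = 1.6510, equidistant: 1.5)")
```

Output:

```
normality residual: 3.10e-04
thickness: 0.9874 +/- 0.0013  (exact: 1.0)
equivolumetric thickness c0: 2.2847  (exact: 7/3 = 2.3333)
eps=0.5 layer radius: 1.6405  (equal-volume shell: 4.5^(1/3) = 1.6510, equidistant: 1.5)
```

The registered mid layer lands on the equal-volume radius to ~0.6% — the
signature of the Bok reparametrization at work — and the residual shows the
streamlines are normal to the layers to 3 parts in 10⁴.

The same pipeline is available from the shell:

```bash
equivol synth --kind concentric_spheres --r0 1 --r1 2 --resolution 3 --out phantom/
equivol register phantom/inner.off phantom/outer.off --normal --out run/reg.npz
equivol layers run/reg.npz --levels 0.25,0.5,0.75 --out run/
equivol validate --archive run/reg.npz --out run/
```

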