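# Methods

## Model

All volumes live on a regular node-centred 3-D grid: voxel index `i` maps
to the physical point `origin + i·spacing` (mm). A deformation is stored
as its displacement `u` in physical units, `f(x) = x + u(x)`, mapping
reference-space points to subject-space points; images are resampled by
reading the moving image at `x + u(x)`. Storing displacements in mm and
differentiating per-axis by the voxel spacing is essential on anisotropic
grids (the default phantom spacing, 2.07 × 2.07 × 8.00 mm, mirrors a
whole-body MR protocol): a voxel-unit Jacobian would be wrong by the
spacing ratio.

The Jacobian determinant `J[f] = det(∂f_i/∂x_j)` is the local volume
ratio: 1 no change, >1 expansion, (0,1) contraction, ≤0 a fold (physically
infeasible). Derivatives use central differences at interior voxels and
one-sided differences on the boundary, which keeps every Jacobian map on
the grid of its source field. Interior accuracy is O(spacing²), verified
against closed-form radial and uniaxial fields.

Given cohort deformations `f_1 … f_n` to an initial reference, the
corrected reference is defined by a deformation `d` whose Jacobian is the
voxel-wise geometric mean of the clamped cohort Jacobians,
`J̄ = exp((1/n) Σ ln max{ε, J_i})`. The printed source formula for this
average contains `min{ε, J_i}`, which would destroy all values above ε;
the accompanying text describes a *lower* threshold, so the clamp is
implemented as `max`. Composing each subject's deformation with `d⁻¹`
makes the voxel-wise product of the composed Jacobians 1 — zero average
pointwise volume change — up to synthesis and inversion tolerances.

## Prescribed-Jacobian synthesis

Generating a displacement with a given Jacobian is ill-posed without
boundary conditions. Here `u = 0` on the grid boundary, which imposes a
global integrability constraint: the grid-wide arithmetic mean of the
target must be 1. Feasibility is restored before synthesis by uniformly
rescaling the target *outside* the body mask (the background), leaving the
anatomically meaningful prescription untouched; without a mask the whole
map is rescaled. A target that cannot be brought to mean 1 this way is
rejected.

The synthesis minimizes `F(u) = Σ_x (J[id+u](x) − target(x))²` by
preconditioned gradient descent:

- the exact gradient is assembled from the cofactor identity
  `∂det(A)/∂A = cof(A)` with `A = I + Du`, pulled back through the exact
  adjoint of the finite-difference operator;
- the gradient is preconditioned with the inverse of the 7-point Dirichlet
  Laplacian, solved directly with a type-I discrete sine transform. This
  is a Newton-like metric — the Gauss–Newton Hessian of `F` is dominated
  by a grad–div operator — and because the preconditioner is symmetric
  positive definite the step is always a descent direction;
- a backtracking step (halved until the objective does not increase,
  regrown on success) makes the objective monotonically non-increasing by
  construction.

Convergence is declared when the maximum absolute Jacobian mismatch on
*enforced* voxels is ≤ `tol` (default 0.01). Enforced voxels are interior
voxels (the one-voxel boundary shell is pinned by the boundary condition,
so matching there is not meaningful) intersected with the body mask when
one is supplied. Defaults: `ε = 0.01`, `tol = 0.01`, `max_iter = 500`,
initial step 1. The scheme is deterministic given the target and
configuration. Smooth targets converge in a handful of iterations; noisy
registration-derived means with a mask-boundary jump take tens.

An earlier variant that updated `u` by the gradient of a potential solving
`Δφ = log(target/J)` stalls around mismatch ~0.1: composing two central
first-difference operators is not the discrete Laplacian (odd–even
decoupling), so that update eventually ceases to be a descent direction of
the discrete objective. The cofactor-adjoint gradient does not have this
defect.

## Inversion and composition

`d⁻¹` is computed by the damped fixed-point iteration
`v ← v + α(−u(x + v(x)) − v)`, `v₀ = −u`, stopping when the undamped
update falls below `tol` (default 0.1 mm) or `max_iter` is reached
(warning; best iterate returned). The relaxation factor α is halved
whenever the update grows — plain iteration (α = 1) can stall where the
field is locally stiff, e.g. at the jump the background rescale creates at
the mask boundary. The iteration solves the *right*-inverse equation
`f ∘ f⁻¹ = id`; tests and consistency checks compose in that direction.
Vector fields are sampled trilinearly with nearest-border clamping
(avoiding spurious folds at the support edge); intensities use a constant
fill, labels nearest-neighbour interpolation only.

## Registration

The pairwise energy is
`E = Σ_channels w_I Σ_p |I_R(p) − I(p+u(p))|² + λ Σ_{(p,q)∈N} ‖u(p)−u(q)‖²`
with `N` the 6-connected unordered voxel pairs. The minimizer is a
coarse-to-fine (default 3 levels, ×2) gradient descent with backtracking
line search; each level is monotone, and a final full-resolution guard
returns the initialization if it ever had lower energy, so registration
never degrades a warm start. The energy's original optimizer (graph-cut
move-making) is interchangeable here: the reference construction consumes
only the resulting fields, and any monotone minimizer of the same energy
satisfies the contract. λ defaults to 1 with the weights `w_I` carrying
the balance, which presumes image channels on a scanner-like intensity
scale (the phantoms use 0–100 units); on unit-scaled data either raise
`w_I` or lower λ.

On the phantom cohort the energy minimum sits ~0.4 voxels from the
generating field (mean, inside the body): smooth interior regions carry
little intensity gradient, and there the regularizer, not the data,
decides the interpolation. This is a property of the energy, not of the
optimizer — driving the energy lower does not reduce the error.

## Pipeline and iteration

The initial reference is the cohort subject closest to both the median
fat mass and median height (sum of absolute robust z-scores,
median/MAD, zero MAD treated as 1; ties broken by subject id). Before
registration it is resampled under a half-voxel translation on all axes,
introducing the interpolation smoothing a synthetic (warped) reference
inevitably has, so intensity-based comparisons between the two are fair;
the half-voxel shift is applied once, not re-applied at later iterations.

Iterated refinement repeats: register all subjects to the current
reference (warm-started from the previous composed fields, which roughly
halves registration work), fit the correction, accumulate the inverse
corrections by composition, and resample the next reference *directly
from the initial reference* through the accumulated inverse — exactly one
interpolation pass per reference regardless of iteration count, avoiding
progressive blurring. Per-subject registrations are independent and may
run in any order or distributed.

## Metrics

`V(J) = J − 1` for `J ≥ 1` and `1 − 1/J` for `J ∈ (0,1)` weights
compression and expansion symmetrically (`|V(J)| = |V(1/J)|`); AAVC is
the ROI mean of `|V|`. The robust variant excludes voxels whose `|V|`
differs from the ROI median by more than 2.5 MAD (zero MAD excludes
nothing; if everything would be excluded the plain value is returned with
a warning). Diagnostics computed on registration outputs clamp `J` below
at ε first, since estimated fields can fold locally; the plain metric on
unclamped folds raises an error by default. Mutual information uses a
256 × 256 joint histogram over the ROI with per-image intensity ranges
and natural logs (the log base is a convention; it only scales the
value). Label fusion assigns the label winning a *strict* majority
(> n/2) of the warped segmentations, background otherwise — under a
plurality rule an organ that never reaches majority would be filled by
whichever label happens to lead, rather than honestly disappearing.

## Synthetic data

The phantoms are deliberately schematic: an ellipsoidal body (~27% of the
grid), a subcutaneous fat shell, a water-dominated interior with smooth
gradients and seeded smoothed noise, and ellipsoidal organs of distinct
intensity placed fully inside the body. Cohort subjects are the template
resampled through inverses of seeded, boundary-tapered, Gaussian-smoothed
random diffeomorphisms whose minimum Jacobian is guaranteed by bisection
on the amplitude (default floor 0.2, peak magnitude 6 mm ≈ 3 in-plane
voxels, correlation length 20 mm). Everything derives from explicit
seeds and is bit-reproducible.

What the phantoms do not model: MR intensity inhomogeneity, pose
variation, limbs leaving the field of view, sliding organ interfaces, or
genuinely different anatomy between subjects (all subjects are
diffeomorphic copies of one template). Passing tests therefore
demonstrate the volume-change bookkeeping — Jacobian computation,
synthesis, inversion, composition, and the zero-average-volume property —
under controlled conditions, not registration robustness on clinical
data.

## Problem sizes and tolerances

The shipped experiments use 48³ grids with 2.07 × 2.07 × 8.00 mm voxels
and cohorts of five subjects (three for the smaller refinement checks),
sizes at which the full pipeline — three refinement iterations with
fifteen registrations — completes in minutes on one CPU. The
zero-average-volume check accepts |geometric mean − 1| ≤ 0.05 on enforced
body voxels (combined synthesis tol 0.01 + inversion tol + interpolation);
measured values are an order of magnitude inside that. Finite-difference
convergence checks compare matched physical problems at two resolutions
and require an error ratio ≥ 3 (4 is the exact O(h²) limit).

## Known limitations

- The synthesis enforces the Jacobian, not any elastic-energy optimality:
  of the many fields realizing a target Jacobian it returns the one the
  preconditioned descent reaches from zero.
- Background rescaling concentrates the feasibility correction outside
  the body; with very small background volumes the required rescale can
  be large or infeasible (then rejected).
- Fixed-point inversion assumes approximate invertibility; fields with
  min J near 0 invert slowly or only approximately (a warning reports the
  residual).
- The registration is small-deformation (displacement model, diffusion
  penalty); it is not diffeomorphic by construction, which is precisely
  why the ε clamp exists downstream.
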