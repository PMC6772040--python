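# volref

Average-volume reference spaces for multi-subject deformable registration.

Atlas-based analysis of whole-body MR images (and volumetric imaging in
general) maps every subject of a cohort into a common reference space and
then performs voxel-wise statistics there. When local tissue volume — the
Jacobian determinant of each subject's deformation — is itself an analysis
variable, the choice of reference biases the result: a reference taken from
one subject carries that subject's anatomy, so the cohort-average volume
change at each voxel is not zero. `volref` builds a *synthetic* reference
with zero average voxel-wise volume change while keeping the sharpness and
registration quality of a real template.

## Method

Let `f_j : Ω_R → Ω_j`, `f_j = id + u_j`, be the deformations registering a
reference `I_R` to each of `n` subjects, and `J[f]` the Jacobian
determinant of `f`. A corrected reference `I_R'` is defined through a
deformation `d` with

```
J[d](x) = exp( (1/n) Σ_i ln( max{ε, J[f_i](x)} ) )
```

— the voxel-wise geometric mean of the cohort Jacobians, computed in the
log domain with a lower clamp `ε > 0` removing singularities from local
registration folds. The deformation registering subject `j` to the new
reference is the composition `f_j ∘ d⁻¹`, and by construction the
voxel-wise product `Π_i J[f_i ∘ d⁻¹] = 1`: the new space is neutral with
respect to average local volume change.

The package provides

- **field algebra** (`volref.fields`): spacing-aware Jacobian determinants,
  composition, fixed-point inversion, warping, half-voxel resampling;
- **prescribed-Jacobian synthesis** (`volref.synthesis`): given a target
  Jacobian map, an iterative search produces a zero-boundary displacement
  whose Jacobian matches it, with a monotonically non-increasing
  squared-mismatch objective;
- **registration** (`volref.registration`): pairwise multi-channel SSD +
  diffusion-regularized deformable registration (any monotone minimizer of
  this energy may be substituted);
- **the reference builder** (`volref.reference`): a statsmodels-style
  `AverageVolumeReference` model whose `fit()` returns a `ReferenceResult`
  with the correction field, its inverse, the composed per-subject fields,
  diagnostics and a `summary()` table, plus iterated refinement;
- **evaluation metrics** (`volref.metrics`): the symmetric volume-change
  transform `V` (`V = J − 1` for expansion, `1 − 1/J` for contraction),
  average absolute volume change (AAVC, plain and MAD-robust), average
  inverse consistency error (AICE), MSE, 256-bin-histogram mutual
  information, Dice overlap and strict-majority label fusion;
- **phantoms** (`volref.phantoms`): seeded synthetic fat/water/mask body
  phantoms, organ labels, and diffeomorphisms with guaranteed Jacobian
  floors, so the whole pipeline runs with no external data.

## Worked example

```python
import numpy as np
import volref as vr

spec = vr.PhantomSpec(shape=(48, 48, 48), seed=0)       # 2.07x2.07x8 mm voxels
image, labels = vr.make_phantom(spec)
body = vr.MaskVolume(image.channel("mask") > 0.5, image.grid)

fields = [vr.make_diffeomorphism((48, 48, 48), seed=s, magnitude_mm=6.0,
                                 min_jacobian=0.2) for s in range(5)]

model = vr.AverageVolumeReference(image, fields,
                                  vr.SynthesisConfig(mask=body))
result = model.fit()
print(result.summary())
```

prints

```
Average-volume reference space
==============================================
subjects:                5
synthesis converged:     True
synthesis iterations:    4
max Jacobian mismatch:   0.00427
mean |log geomean J| after correction: 0.00102

 subject  aavc_before  aavc_after
       0       0.0608      0.0515
       1       0.0503      0.0420
       2       0.0470      0.0400
       3       0.0524      0.0451
       4       0.0371      0.0413
```

The synthesis matched the prescribed mean Jacobian to 0.0043 everywhere it
is enforced; the voxel-wise geometric mean of the composed Jacobians is 1
to within 0.001 in log magnitude (the zero-average-volume property); and
the per-subject average absolute volume change drops once the common
component of the cohort's volume changes is absorbed into the reference.

A command-line interface mirrors the library
(`volref phantom | register | avg-jacobian | synth-field | build-reference
| evaluate | pipeline`); `volref pipeline --config cfg.json` runs the whole
chain — initial-reference selection by median fat mass and height,
half-voxel resampling, per-subject registration, correction, optional
iterated refinement — and writes NIfTI artifacts plus a `summary.json`
with the AAVC trace.

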