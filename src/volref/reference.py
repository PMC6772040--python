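"""Average-volume reference-space construction.

Given a cohort registered to an initial reference I_R by deformations
f_1 ... f_n, a new reference I_R' is obtained by warping I_R with a
correction d whose Jacobian is the voxel-wise geometric mean of the
J[f_i]; the deformation registering subject j to I_R' is then f_j o d^-1.
The voxel-wise product of the composed Jacobians is thereby driven to 1:
the new reference has zero average pointwise volume change with respect to
the cohort.

The construction is exposed statsmodels-style: ``AverageVolumeReference``
is the model, its ``fit()`` returns a ``ReferenceResult`` carrying the
correction field, its inverse, the composed per-subject fields, the
diagnostics, and a ``summary()`` table.  ``build_reference`` and
``iterate_reference`` are thin functional wrappers over the same objects.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .fields import compose, halfvoxel_resample, invert, jacobian_determinant, warp
from .grids import DisplacementField, ImageVolume, MaskVolume
from .metrics import aavc
from .registration import RegistrationConfig, register
from .synthesis import (
    ConvergenceReport,
    SynthesisConfig,
    displacement_from_jacobian,
    mean_jacobian,
)

__all__ = [
    "select_initial_reference",
    "AverageVolumeReference",
    "ReferenceResult",
    "build_reference",
    "iterate_reference",
]


def select_initial_reference(cohort: pd.DataFrame, exclusions: Sequence[str] = ()) -> str:
    """Pick the subject closest to both the cohort median fat mass and height.

    ``cohort`` needs columns ``subject_id``, ``fat_mass_kg``, ``height_cm``.
    Distance is the sum of absolute robust z-scores (median/MAD per
    covariate, a zero MAD treated as 1); ties are broken by subject_id
    order.  Subjects with evident problems (artefacts, anomalies, truncated
    field of view) are passed via ``exclusions``.
    """
    df = cohort.dropna(subset=["fat_mass_kg", "height_cm"])
    df = df[~df["subject_id"].isin(set(exclusions))]
    if df.empty:
        raise ValueError("no eligible subject to select a reference from")

    def robust_z(col):
        v = df[col].to_numpy(dtype=float)
        med = np.median(v)
        mad = np.median(np.abs(v - med))
        if mad == 0:
            mad = 1.0
        return np.abs(v - med) / mad

    score = robust_z("fat_mass_kg") + robust_z("height_cm")
    out = df.assign(_score=score).sort_values(["_score", "subject_id"])
    return str(out["subject_id"].iloc[0])


@dataclass
class ReferenceResult:
    """Fitted average-volume reference space.

    Attributes
    ----------
    reference : the corrected reference image I_R'
    d, d_inv  : the correction field and its numerical inverse
    composed_fields : per-subject displacements f_j o d^-1 to the new reference
    report : dict with synthesis convergence, per-subject AAVC before/after,
             and the geometric-mean Jacobian diagnostics
    """

    reference: ImageVolume
    d: DisplacementField
    d_inv: DisplacementField
    composed_fields: list
    report: dict = dc_field(default_factory=dict)
    model: "AverageVolumeReference | None" = None

    @property
    def converged(self) -> bool:
        return bool(self.report.get("synthesis", {}).get("converged", False))

    def per_subject_frame(self) -> pd.DataFrame:
        n = len(self.composed_fields)
        return pd.DataFrame(
            {
                "subject": np.arange(n),
                "aavc_before": self.report.get("aavc_before", [np.nan] * n),
                "aavc_after": self.report.get("aavc_after", [np.nan] * n),
            }
        )

    def summary(self) -> str:
        lines = ["Average-volume reference space", "=" * 46]
        syn = self.report.get("synthesis", {})
        lines.append(f"subjects:                {len(self.composed_fields)}")
        lines.append(f"synthesis converged:     {syn.get('converged')}")
        lines.append(f"synthesis iterations:    {syn.get('iterations')}")
        lines.append(f"max Jacobian mismatch:   {syn.get('max_mismatch', float('nan')):.5f}")
        gm = self.report.get("geomean_composed_abs_log")
        if gm is not None:
            lines.append(f"mean |log geomean J| after correction: {gm:.5f}")
        lines.append("")
        lines.append(self.per_subject_frame().to_string(index=False,
                                                        float_format=lambda v: f"{v:.4f}"))
        return "\n".join(lines)


class AverageVolumeReference:
    """Model: correction of an initial reference to zero average volume change.

    Parameters
    ----------
    initial : ImageVolume
        The initial reference image I_R (already half-voxel resampled if
        comparability of similarity metrics is desired).
    fields : sequence of DisplacementField
        Deformations f_j mapping the reference grid to each subject.
    synth_config : SynthesisConfig, optional
        Synthesis settings; its ``mask`` restricts where Jacobian matching
        is enforced (typically the body).
    roi : MaskVolume, optional
        ROI for the AAVC diagnostics; defaults to the synthesis mask, or
        the whole grid.
    """

    def __init__(
        self,
        initial: ImageVolume,
        fields: Sequence[DisplacementField],
        synth_config: Optional[SynthesisConfig] = None,
        roi: Optional[MaskVolume] = None,
    ):
        fields = list(fields)
        if not fields:
            raise ValueError("need at least one subject field")
        for f in fields:
            if not f.grid.matches(initial.grid):
                raise ValueError("all fields must live on the initial reference grid")
        self.initial = initial
        self.fields = fields
        self.synth_config = synth_config or SynthesisConfig()
        self.roi = roi or self.synth_config.mask or MaskVolume(
            np.ones(initial.grid.shape, dtype=bool), initial.grid
        )

    def fit(self, invert_tol: float = 0.05, invert_max_iter: int = 200) -> ReferenceResult:
        cfg = self.synth_config
        jacobians = [jacobian_determinant(f) for f in self.fields]
        jbar = mean_jacobian(jacobians, cfg.epsilon)
        d, syn_report = displacement_from_jacobian(jbar, cfg)
        d_inv = invert(d, tol=invert_tol, max_iter=invert_max_iter)
        reference = warp(self.initial, d_inv, interp="linear")
        composed = [compose(f, d_inv) for f in self.fields]

        aavc_before = [aavc(f, self.roi, clamp=cfg.epsilon) for f in self.fields]
        aavc_after = [aavc(c, self.roi, clamp=cfg.epsilon) for c in composed]
        logs = np.mean(
            [np.log(np.maximum(cfg.epsilon, jacobian_determinant(c).data)) for c in composed],
            axis=0,
        )
        report = {
            "synthesis": syn_report.to_dict(),
            "aavc_before": aavc_before,
            "aavc_after": aavc_after,
            "geomean_composed_abs_log": float(np.abs(logs[self.roi.data]).mean()),
        }
        return ReferenceResult(
            reference=reference,
            d=d,
            d_inv=d_inv,
            composed_fields=composed,
            report=report,
            model=self,
        )


def build_reference(
    initial: ImageVolume,
    fields: Sequence[DisplacementField],
    config: Optional[SynthesisConfig] = None,
    roi: Optional[MaskVolume] = None,
) -> ReferenceResult:
    """Functional wrapper: fit an :class:`AverageVolumeReference` model."""
    return AverageVolumeReference(initial, fields, config, roi).fit()


def iterate_reference(
    initial: ImageVolume,
    cohort_images: Sequence[ImageVolume],
    reg_config: Optional[RegistrationConfig] = None,
    synth_config: Optional[SynthesisConfig] = None,
    n_iters: int = 1,
    roi: Optional[MaskVolume] = None,
    apply_halfvoxel: bool = True,
) -> list[ReferenceResult]:
    """Iteratively refine the reference by repeated registration + correction.

    Each iteration registers every subject to the current reference
    (warm-started from the previous composed fields), fits the correction,
    and resamples the next reference DIRECTLY from the initial reference
    through the accumulated inverse correction — never from the previous
    reference — so each reference undergoes exactly one interpolation pass
    regardless of the iteration count.  Returns one ReferenceResult per
    iteration; each result's report carries the AAVC trace entries.
    """
    if n_iters < 1:
        raise ValueError("n_iters must be >= 1")
    reg_config = reg_config or RegistrationConfig()
    synth_config = synth_config or SynthesisConfig()

    base = halfvoxel_resample(initial) if apply_halfvoxel else initial
    current_ref = base
    warm: list[Optional[DisplacementField]] = [None] * len(cohort_images)
    acc_inv: Optional[DisplacementField] = None
    results: list[ReferenceResult] = []

    for _ in range(n_iters):
        fields = [
            register(current_ref, img, reg_config, init=w0)
            for img, w0 in zip(cohort_images, warm)
        ]
        model = AverageVolumeReference(base if acc_inv is None else current_ref,
                                       fields, synth_config, roi)
        res = model.fit()
        # accumulate the inverse correction and resample from the initial
        acc_inv = res.d_inv if acc_inv is None else compose(acc_inv, res.d_inv)
        reference = warp(base, acc_inv, interp="linear")
        res.reference = reference
        res.report["accumulated_inverse"] = True
        results.append(res)
        current_ref = reference
        warm = list(res.composed_fields)
    return results
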