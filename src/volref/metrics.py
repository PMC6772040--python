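"""Evaluation metrics for reference-space registration quality.

Volume-change measures (V transform, AAVC), inverse-consistency error,
intensity-based similarity (MSE, mutual information) and segmentation
overlap (Dice with majority-vote label fusion).
"""

from __future__ import annotations

import warnings

import numpy as np

from .fields import compose, jacobian_determinant
from .grids import (
    DisplacementField,
    ImageVolume,
    JacobianMap,
    LabelVolume,
    MaskVolume,
)

__all__ = [
    "v_transform",
    "aavc",
    "robust_aavc",
    "aice",
    "mse",
    "mutual_information",
    "dice",
    "majority_vote",
]


def v_transform(jac: JacobianMap | np.ndarray) -> np.ndarray:
    """Symmetric volume-change measure V.

    V = J - 1 for J >= 1 (expansion) and V = 1 - 1/J for J in (0, 1)
    (contraction), giving the same importance to compression and expansion:
    |V(J)| = |V(1/J)|.  The Jacobian itself is not linear in volume change,
    so squared differences of J would weight expansion more than the
    equivalent contraction.
    """
    j = jac.data if isinstance(jac, JacobianMap) else np.asarray(jac, dtype=float)
    if np.any(j <= 0):
        raise ValueError("V transform requires strictly positive Jacobians")
    return np.where(j >= 1.0, j - 1.0, 1.0 - 1.0 / j)


def _abs_v_in_roi(
    field: DisplacementField, roi: MaskVolume, clamp: float | None
) -> np.ndarray:
    if not field.grid.matches(roi.grid):
        raise ValueError("roi grid does not match field grid")
    if roi.n_voxels == 0:
        raise ValueError("roi is empty")
    jac = jacobian_determinant(field).data[roi.data]
    if clamp is not None:
        jac = np.maximum(jac, clamp)
    return np.abs(v_transform(jac))


def aavc(field: DisplacementField, roi: MaskVolume, clamp: float | None = None) -> float:
    """Average absolute volume change of a subject's transform over a ROI.

    AAVC(h) = (1/|Omega|) * sum_{x in Omega} |V[J[h]](x)|.  ``clamp``
    optionally imposes a lower Jacobian threshold before the V transform,
    removing singularities from local registration folds (same role as the
    epsilon clamp of the mean Jacobian); by default folds raise an error.
    """
    return float(_abs_v_in_roi(field, roi, clamp).mean())


def robust_aavc(
    field: DisplacementField, roi: MaskVolume, k: float = 2.5,
    clamp: float | None = None,
) -> float:
    """AAVC excluding outlier voxels.

    Voxels whose |V| differs from the ROI median by more than ``k`` times
    the median absolute deviation are excluded.  A zero MAD (degenerate
    distribution) excludes nothing; if every voxel would be excluded the
    plain AAVC is returned with a warning.
    """
    if roi.n_voxels < 2:
        raise ValueError("robust AAVC requires a ROI of at least 2 voxels")
    v = _abs_v_in_roi(field, roi, clamp)
    med = np.median(v)
    mad = np.median(np.abs(v - med))
    if mad == 0:
        return float(v.mean())
    keep = np.abs(v - med) <= k * mad
    if not keep.any():
        warnings.warn(
            "all ROI voxels flagged as outliers; returning plain AAVC",
            RuntimeWarning,
            stacklevel=2,
        )
        return float(v.mean())
    return float(v[keep].mean())


def aice(
    h: DisplacementField, h_inv_reg: DisplacementField, roi: MaskVolume
) -> float:
    """Average inverse consistency error, mm.

    Mean over the ROI of ||(h_I o h)(x) - x|| where h_I is the transform
    from the registration with fixed and moving images swapped.
    """
    if not h.grid.matches(h_inv_reg.grid):
        raise ValueError("both transforms must live on the reference grid")
    if roi.n_voxels == 0:
        raise ValueError("roi is empty")
    round_trip = compose(h_inv_reg, h)
    return float(round_trip.magnitude()[roi.data].mean())


def mse(ref: ImageVolume, warped: ImageVolume, roi: MaskVolume) -> float:
    """Mean squared intensity error over the ROI, averaged across channels."""
    if not ref.grid.matches(warped.grid) or ref.channels != warped.channels:
        raise ValueError("reference and warped image must share grid and channels")
    if not ref.grid.matches(roi.grid):
        raise ValueError("roi grid mismatch")
    if roi.n_voxels == 0:
        raise ValueError("roi is empty")
    diff = ref.data[:, roi.data] - warped.data[:, roi.data]
    return float(np.mean(diff * diff))


def mutual_information(
    ref: ImageVolume,
    warped: ImageVolume,
    roi: MaskVolume,
    bins: int = 256,
    channel: str | None = None,
) -> float:
    """Mutual information from a joint histogram over the ROI, in nats.

    The joint density is approximated with a ``bins`` x ``bins`` histogram of
    the two images within the ROI; marginals are histogram sums; each image
    is binned over its own intensity range within the ROI.  Empty bins
    contribute zero.  A constant image occupies a single bin and yields 0.
    """
    if roi.n_voxels == 0:
        raise ValueError("roi is empty")
    if channel is None:
        channel = ref.channels[0]
    x = ref.channel(channel)[roi.data].ravel()
    y = warped.channel(channel)[roi.data].ravel()
    joint, _, _ = np.histogram2d(x, y, bins=bins)
    n = joint.sum()
    p = joint / n
    px = p.sum(axis=1, keepdims=True)
    py = p.sum(axis=0, keepdims=True)
    nz = p > 0
    ratio = np.ones_like(p)
    np.divide(p, px * py, out=ratio, where=nz)
    return float(np.sum(p[nz] * np.log(ratio[nz])))


def dice(a: LabelVolume, b: LabelVolume, label: int) -> float:
    """Sorensen-Dice overlap 2|A n B| / (|A| + |B|) for one label.

    Defined as 1 when the label is absent from both volumes.
    """
    if not a.grid.matches(b.grid):
        raise ValueError("label volumes must share a grid")
    ma = a.data == label
    mb = b.data == label
    denom = int(ma.sum()) + int(mb.sum())
    if denom == 0:
        return 1.0
    return 2.0 * int((ma & mb).sum()) / denom


def majority_vote(warped_labels) -> LabelVolume:
    """Fuse warped segmentations by strict-majority voting.

    A voxel is assigned the label receiving more than n/2 of the votes;
    without a strict majority it is assigned background (0).  With this
    rule an organ that no label reaches by majority simply disappears from
    the fused segmentation rather than being assigned by plurality.
    """
    vols = list(warped_labels)
    if not vols:
        raise ValueError("majority_vote requires at least one volume")
    grid = vols[0].grid
    for v in vols[1:]:
        if not v.grid.matches(grid):
            raise ValueError("all label volumes must share a grid")
    n = len(vols)
    stack = np.stack([v.data for v in vols])
    labels = np.unique(stack)
    best_count = np.zeros(grid.shape, dtype=np.int64)
    best_label = np.zeros(grid.shape, dtype=stack.dtype)
    for lab in labels:
        count = (stack == lab).sum(axis=0)
        better = count > best_count
        best_count = np.where(better, count, best_count)
        best_label = np.where(better, lab, best_label)
    fused = np.where(best_count * 2 > n, best_label, 0)
    return LabelVolume(fused, grid)
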