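"""Displacement-field algebra: Jacobians, composition, inversion, warping.

The deformation associated with a displacement u is f(x) = x + u(x), mapping
reference-space physical points to subject-space points.  Its Jacobian
determinant det(df_i/dx_j) measures the local volume change: 1 means no
change, >1 expansion, (0,1) contraction, <=0 a physically infeasible fold.

Derivatives are taken in physical units (per mm), so Jacobians are correct
on anisotropic grids.  Central differences are used at interior voxels and
one-sided differences on the boundary, which keeps every derived map on the
same grid as its source field.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import map_coordinates

from .grids import (
    DisplacementField,
    GridInfo,
    ImageVolume,
    JacobianMap,
    LabelVolume,
    MaskVolume,
)

__all__ = [
    "jacobian_determinant",
    "compose",
    "invert",
    "InversionReport",
    "warp",
    "halfvoxel_resample",
    "interior_mask",
]


def _det3(a):
    """Determinant of a field of 3x3 matrices given as a[i][j] arrays."""
    return (
        a[0][0] * (a[1][1] * a[2][2] - a[1][2] * a[2][1])
        - a[0][1] * (a[1][0] * a[2][2] - a[1][2] * a[2][0])
        + a[0][2] * (a[1][0] * a[2][1] - a[1][1] * a[2][0])
    )


def jacobian_determinant(field: DisplacementField) -> JacobianMap:
    """Per-voxel Jacobian determinant of the deformation f = id + u.

    Raises
    ------
    ValueError
        If any grid axis has fewer than 2 voxels (no derivative defined).
    """
    if any(s < 2 for s in field.shape):
        raise ValueError("jacobian requires at least 2 voxels per axis")
    sp = field.spacing
    # a[i][j] = d f_i / d x_j = delta_ij + d u_i / d x_j
    a = [[None] * 3 for _ in range(3)]
    for i in range(3):
        grads = np.gradient(field.data[..., i], sp[0], sp[1], sp[2])
        for j in range(3):
            a[i][j] = grads[j] + (1.0 if i == j else 0.0)
    return JacobianMap(_det3(a), field.grid)


def _sample_vectors(field: DisplacementField, points: np.ndarray) -> np.ndarray:
    """Trilinearly sample a vector field at physical points (..., 3).

    Points outside the field's support take the nearest-border vector value,
    which avoids spurious folds at the grid boundary.
    """
    idx = field.grid.index_from_physical(points)
    coords = np.moveaxis(idx, -1, 0)
    out = np.empty(points.shape)
    for c in range(3):
        out[..., c] = map_coordinates(
            field.data[..., c], coords, order=1, mode="nearest"
        )
    return out


def compose(outer: DisplacementField, inner: DisplacementField) -> DisplacementField:
    """Displacement of the composed deformation f_outer o f_inner.

    Returned on ``inner``'s grid:  u(x) = u_inner(x) + u_outer(x + u_inner(x)),
    with the outer field sampled by trilinear interpolation (nearest-border
    clamp outside its support).
    """
    pts = inner.grid.meshgrid() + inner.data
    return DisplacementField(inner.data + _sample_vectors(outer, pts), inner.grid)


@dataclass
class InversionReport:
    converged: bool
    iterations: int
    residual_mm: float  # max displacement update at the last iteration


def invert(
    field: DisplacementField,
    tol: float = 0.1,
    max_iter: int = 50,
    full_output: bool = False,
):
    """Numerical inverse displacement by fixed-point iteration.

    Iterates ``v_{k+1}(x) = -u(x + v_k(x))`` from ``v_0 = -u`` until the max
    update falls below ``tol`` (mm) or ``max_iter`` is reached.  Requires the
    deformation to be approximately invertible (min Jacobian > 0); on
    non-convergence a warning is issued and the best iterate returned.
    """
    import warnings

    grid_pts = field.grid.meshgrid()
    v = -field.data
    residual = np.inf
    alpha = 1.0  # damping; reduced adaptively where the map is not contractive
    it = 0
    for it in range(1, max_iter + 1):
        update = -_sample_vectors(field, grid_pts + v) - v
        new_residual = float(np.max(np.abs(update)))
        if new_residual > residual:
            alpha = max(0.5 * alpha, 0.05)
        residual = new_residual
        v = v + alpha * update
        if residual < tol:
            break
    converged = residual < tol
    if not converged:
        warnings.warn(
            f"displacement inversion did not converge in {max_iter} iterations "
            f"(last update {residual:.3g} mm)",
            RuntimeWarning,
            stacklevel=2,
        )
    inv = DisplacementField(v, field.grid)
    if full_output:
        return inv, InversionReport(converged, it, residual)
    return inv


def _warp_scalar(data, field, order, fill):
    pts = field.grid.meshgrid() + field.data
    idx = field.grid.index_from_physical(pts)
    coords = np.moveaxis(idx, -1, 0)
    return map_coordinates(data, coords, order=order, mode="constant", cval=fill)


def warp(image, field: DisplacementField, interp: str = "linear", fill: float = 0.0):
    """Resample an image through a deformation: output(x) = input(x + u(x)).

    Samples are taken in the moving image space from coordinates in the
    reference space.  ``interp`` must be ``"nearest"`` for label volumes
    (linear interpolation would invent labels).  Out-of-support samples take
    ``fill`` (default 0).
    """
    if interp not in ("linear", "nearest"):
        raise ValueError(f"unknown interpolation {interp!r}")
    if isinstance(image, LabelVolume):
        if interp != "nearest":
            raise ValueError("label volumes must be warped with nearest interpolation")
        out = _warp_scalar(image.data.astype(float), field, order=0, fill=fill)
        return LabelVolume(np.round(out).astype(image.data.dtype), field.grid)
    if isinstance(image, MaskVolume):
        out = _warp_scalar(image.data.astype(float), field, order=0, fill=0.0)
        return MaskVolume(out > 0.5, field.grid)
    if isinstance(image, ImageVolume):
        order = 1 if interp == "linear" else 0
        out = np.stack(
            [_warp_scalar(ch, field, order=order, fill=fill) for ch in image.data]
        )
        return ImageVolume(out, field.grid, image.channels)
    raise TypeError(f"cannot warp object of type {type(image).__name__}")


def halfvoxel_resample(image: ImageVolume) -> ImageVolume:
    """Linear resampling under a half-voxel translation along all axes.

    Introduces the smoothing effect of resampling without altering the
    anatomy, so that image-similarity metrics are comparable between a
    reference taken directly from the cohort and a synthetic, resampled one.
    """
    shift = 0.5 * image.spacing
    field = DisplacementField.constant(image.grid, shift)
    return warp(image, field, interp="linear")


def interior_mask(grid: GridInfo, margin: int = 1) -> np.ndarray:
    """Boolean mask excluding a ``margin``-voxel shell at the grid boundary."""
    m = np.zeros(grid.shape, dtype=bool)
    sl = tuple(slice(margin, s - margin) for s in grid.shape)
    m[sl] = True
    return m
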