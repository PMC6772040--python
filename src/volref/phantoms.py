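"""Synthetic whole-body-like phantoms and seeded diffeomorphisms.

The phantoms are deliberately schematic — an ellipsoidal body with a
subcutaneous fat shell, a water-dominated interior with smooth intensity
gradients, and ellipsoidal labelled organs — because the surface under test
is the field algebra and volume-change bookkeeping of the reference-space
construction, not anatomical realism.  The default grid uses anisotropic
voxels (2.07 x 2.07 x 8.00 mm) so spacing-aware Jacobians are exercised.

All randomness funnels through ``numpy.random.default_rng`` seeded from the
spec, so every output is bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .fields import invert, jacobian_determinant, warp
from .grids import (
    DisplacementField,
    GridInfo,
    ImageVolume,
    JacobianMap,
    LabelVolume,
    MaskVolume,
)

__all__ = [
    "PhantomSpec",
    "make_phantom",
    "make_diffeomorphism",
    "make_analytic_field",
    "make_cohort",
    "make_cohort_table",
]

DEFAULT_SPACING = (2.07, 2.07, 8.0)


@dataclass
class PhantomSpec:
    """Parameters of the synthetic body phantom."""

    shape: tuple[int, int, int] = (48, 48, 48)
    spacing: tuple[float, float, float] = DEFAULT_SPACING
    n_organs: int = 3
    fat_fraction_range: tuple[float, float] = (0.2, 0.9)
    seed: int = 0

    def __post_init__(self):
        self.shape = tuple(int(s) for s in self.shape)
        if any(s < 16 for s in self.shape):
            raise ValueError("phantom shape must be >= 16 voxels per axis")
        lo, hi = self.fat_fraction_range
        if not (0 <= lo <= hi <= 1):
            raise ValueError("fat_fraction_range must be an interval within [0, 1]")

    @property
    def grid(self) -> GridInfo:
        return GridInfo(shape=self.shape, spacing=tuple(float(s) for s in self.spacing))


def _normalized_coords(grid: GridInfo) -> np.ndarray:
    """Coordinates scaled to [-1, 1] per axis over the grid's physical extent."""
    axes = [np.linspace(-1.0, 1.0, n) for n in grid.shape]
    return np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1)


def make_phantom(spec: PhantomSpec) -> tuple[ImageVolume, LabelVolume]:
    """Build a fat/water/mask phantom and its organ label volume.

    The body is an ellipsoid filling ~80% of the grid per axis; the fat
    channel peaks in a subcutaneous shell, the water channel dominates the
    interior with a smooth anterior-posterior gradient, seeded smoothed
    noise is added inside the body, and ``n_organs`` ellipsoidal organs of
    distinct intensity are placed fully inside the body.

    Raises
    ------
    ValueError
        If the requested number of organs cannot be placed inside the body.
    """
    grid = spec.grid
    rng = np.random.default_rng(spec.seed)
    q = _normalized_coords(grid)

    semi = 0.80
    rho = np.sqrt(np.sum((q / semi) ** 2, axis=-1))
    body = rho <= 1.0

    lo, hi = spec.fat_fraction_range
    fat_peak = lo + (hi - lo) * rng.uniform(0.6, 1.0)
    # subcutaneous shell: smooth radial profile peaking near the surface
    shell = np.exp(-((rho - 0.88) ** 2) / (2 * 0.06**2))
    fat = fat_peak * shell
    water = (1.0 - 0.75 * shell) * (0.6 + 0.25 * q[..., 1] + 0.15 * q[..., 0] ** 2)

    labels = np.zeros(grid.shape, dtype=np.int32)
    placed = 0
    attempts = 0
    organ_semi = 0.16
    while placed < spec.n_organs:
        attempts += 1
        if attempts > 200:
            raise ValueError(
                f"could not place {spec.n_organs} organs inside the body "
                f"(placed {placed})"
            )
        center = rng.uniform(-0.45, 0.45, size=3)
        axes = organ_semi * rng.uniform(0.6, 1.0, size=3)
        organ = np.sum(((q - center) / axes) ** 2, axis=-1) <= 1.0
        if not organ.any():
            continue
        # fully inside the body and not touching an existing organ
        if np.any(organ & ~body) or np.any(organ & (labels > 0)):
            continue
        placed += 1
        labels[organ] = placed
        water[organ] += 0.3 + 0.1 * placed

    noise = gaussian_filter(rng.normal(0.0, 1.0, grid.shape), sigma=1.5)
    noise = 0.02 * noise / max(np.abs(noise).max(), 1e-12)
    fat = np.clip(fat + noise, 0.0, None)
    water = np.clip(water + noise, 0.05, None)

    # absolute-content channels on a scanner-like 0-100 unit scale, so the
    # fixed-weight diffusion regularizer is balanced as for real data
    fat *= 100.0 * body
    water *= 100.0 * body
    data = np.stack([fat, water, body.astype(float)])
    image = ImageVolume(data, grid, channels=("fat", "water", "mask"))
    return image, LabelVolume(labels, grid)


def _boundary_taper(grid: GridInfo, width: int = 3) -> np.ndarray:
    """Smooth per-axis window that is 0 on the boundary and 1 in the core."""
    wins = []
    for n in grid.shape:
        ramp = np.ones(n)
        w = min(width, (n - 1) // 2)
        t = np.linspace(0.0, 1.0, w + 1)
        edge = np.sin(0.5 * np.pi * t) ** 2
        ramp[: w + 1] = edge
        ramp[n - w - 1 :] = edge[::-1]
        wins.append(ramp)
    return (
        wins[0][:, None, None] * wins[1][None, :, None] * wins[2][None, None, :]
    )


def make_diffeomorphism(
    shape,
    spacing=DEFAULT_SPACING,
    smoothness_mm: float = 20.0,
    magnitude_mm: float = 6.0,
    min_jacobian: float = 0.2,
    seed: int = 0,
) -> DisplacementField:
    """Seeded random smooth displacement with a guaranteed Jacobian floor.

    Gaussian white noise per component is smoothed to a correlation length
    of ``smoothness_mm``, tapered to zero on the grid boundary, scaled to a
    peak magnitude of ``magnitude_mm`` and then, if needed, shrunk by
    bisection until the recomputed min Jacobian is >= ``min_jacobian``.
    Returns the zero field with a warning if no positive magnitude works.
    """
    if not (0 < min_jacobian < 1):
        raise ValueError("min_jacobian must lie in (0, 1)")
    grid = GridInfo(shape=tuple(int(s) for s in shape), spacing=tuple(float(s) for s in spacing))
    rng = np.random.default_rng(seed)
    sigma_vox = np.asarray(smoothness_mm) / grid.spacing_arr
    raw = np.stack(
        [
            gaussian_filter(rng.normal(0.0, 1.0, grid.shape), sigma=sigma_vox)
            for _ in range(3)
        ],
        axis=-1,
    )
    raw *= _boundary_taper(grid)[..., None]
    peak = np.linalg.norm(raw, axis=-1).max()
    if peak == 0 or magnitude_mm == 0:
        return DisplacementField.zeros(grid)
    raw *= magnitude_mm / peak

    def min_j(scale):
        fld = DisplacementField(scale * raw, grid)
        return float(jacobian_determinant(fld).data.min())

    if min_j(1.0) >= min_jacobian:
        return DisplacementField(raw, grid)
    lo, hi = 0.0, 1.0
    for _ in range(40):
        mid = 0.5 * (lo + hi)
        if min_j(mid) >= min_jacobian:
            lo = mid
        else:
            hi = mid
    if lo == 0.0:
        import warnings

        warnings.warn(
            "could not satisfy min_jacobian at any positive magnitude; "
            "returning zero field",
            RuntimeWarning,
            stacklevel=2,
        )
        return DisplacementField.zeros(grid)
    return DisplacementField(lo * raw, grid)


def _smoothstep(x):
    """Quintic smoothstep on [0, 1] (C2, zero slope at the ends)."""
    x = np.clip(x, 0.0, 1.0)
    return x**3 * (10.0 - 15.0 * x + 6.0 * x**2)


def _smoothstep_integral(x):
    """Antiderivative of the quintic smoothstep, zero at 0."""
    x = np.clip(x, 0.0, 1.0)
    return x**4 * (2.5 - 3.0 * x + x**2)


def make_analytic_field(
    kind: str, shape=(32, 32, 32), spacing=DEFAULT_SPACING, **params
) -> tuple[DisplacementField, JacobianMap]:
    """Analytic displacement fields with closed-form Jacobians.

    kind="axis_scale": uniaxial stretch by ``factor`` (param, default 1.2)
    along ``axis`` (default 0), blended smoothly to identity within a
    ``pad`` fraction of the axis extent; the interior (core) Jacobian
    equals ``factor`` exactly.

    kind="radial_bump": radially symmetric Gaussian bump
    u(x) = amplitude * exp(-r^2 / (2 sigma_mm^2)) * (x - c); the closed-form
    Jacobian is (1 + a g)^2 * (1 + a g (1 - r^2/sigma^2)) with
    g = exp(-r^2/(2 sigma^2)).  Amplitudes outside the invertibility bounds
    (-1 < a < e^{3/2}/2) are rejected.
    """
    grid = GridInfo(shape=tuple(int(s) for s in shape), spacing=tuple(float(s) for s in spacing))
    pts = grid.meshgrid()
    if kind == "axis_scale":
        s = float(params.get("factor", 1.2))
        axis = int(params.get("axis", 0))
        pad = float(params.get("pad", 0.2))
        if s <= 0:
            raise ValueError("factor must be > 0 (non-positive Jacobian)")
        if not (0 < pad <= 0.25):
            raise ValueError("pad must lie in (0, 0.25]")
        t = pts[..., axis] - grid.origin[axis]
        extent = grid.extent[axis]
        xi = t / extent
        p = pad
        # weight w(xi): 0 at the ends, 1 in the core, quintic ramps over
        # [p, 2p] and [1-2p, 1-p]; smoothstep clipping handles the pieces
        w = np.minimum(
            _smoothstep((xi - p) / p), _smoothstep((1.0 - p - xi) / p)
        )
        # exact integral of w along xi, assembled piecewise
        int_w = p * _smoothstep_integral((xi - p) / p)
        mid = xi > 2 * p
        int_w = np.where(mid, p * _smoothstep_integral(1.0) + (np.minimum(xi, 1 - 2 * p) - 2 * p), int_w)
        tail = xi > 1 - 2 * p
        int_w = np.where(
            tail,
            p * _smoothstep_integral(1.0)
            + (1 - 4 * p)
            + p * (_smoothstep_integral(1.0) - _smoothstep_integral((1.0 - p - xi) / p)),
            int_w,
        )
        u = np.zeros(tuple(grid.shape) + (3,))
        u[..., axis] = (s - 1.0) * extent * int_w
        jac = 1.0 + (s - 1.0) * w
        return DisplacementField(u, grid), JacobianMap(jac, grid)
    if kind == "radial_bump":
        a = float(params.get("amplitude", 0.1))
        sigma = float(params.get("sigma_mm", 0.15 * float(np.min(grid.extent))))
        center = params.get("center_mm")
        if center is None:
            center = grid.origin_arr + 0.5 * grid.extent
        center = np.asarray(center, dtype=float)
        if not (-1.0 < a < np.exp(1.5) / 2.0):
            raise ValueError("amplitude outside the invertibility bounds")
        rel = pts - center
        r2 = np.sum(rel * rel, axis=-1)
        g = np.exp(-r2 / (2.0 * sigma**2))
        u = a * g[..., None] * rel
        jac = (1.0 + a * g) ** 2 * (1.0 + a * g * (1.0 - r2 / sigma**2))
        return DisplacementField(u, grid), JacobianMap(jac, grid)
    raise ValueError(f"unknown analytic field kind {kind!r}")


def make_cohort(
    spec: PhantomSpec,
    n_subjects: int = 5,
    deform_params: dict | None = None,
    seed: int = 0,
) -> tuple[ImageVolume, LabelVolume, list[tuple[ImageVolume, LabelVolume, DisplacementField]]]:
    """Template phantom plus ``n_subjects`` deformed copies with ground truth.

    Each subject j is the template resampled through the inverse of a seeded
    diffeomorphism f_j, so that registering subject j back to the template
    should recover f_j (the deformation mapping template space to subject
    space).  Returns (template image, template labels, subjects) where each
    subject is an (image, labels, ground-truth field) triple.
    """
    if n_subjects < 2:
        raise ValueError("a cohort needs at least 2 subjects")
    template, template_labels = make_phantom(spec)
    params = {
        "smoothness_mm": 20.0,
        "magnitude_mm": 4.0,
        "min_jacobian": 0.2,
    }
    if deform_params:
        params.update(deform_params)
    subjects = []
    for j in range(n_subjects):
        fld = make_diffeomorphism(
            spec.shape, spec.spacing, seed=seed + j, **params
        )
        inv = invert(fld, tol=0.05, max_iter=200)
        img = warp(template, inv, interp="linear")
        lab = warp(template_labels, inv, interp="nearest")
        subjects.append((img, lab, fld))
    return template, template_labels, subjects


def make_cohort_table(n_subjects: int, seed: int = 0) -> pd.DataFrame:
    """Synthetic cohort covariates (fat mass kg, height cm) for reference selection."""
    rng = np.random.default_rng(seed)
    return pd.DataFrame(
        {
            "subject_id": [f"SUBJ{j:03d}" for j in range(n_subjects)],
            "fat_mass_kg": np.round(rng.normal(25.0, 6.0, n_subjects).clip(8, 60), 1),
            "height_cm": np.round(rng.normal(168.0, 7.0, n_subjects).clip(145, 200), 1),
        }
    )
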