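"""Pairwise multi-channel deformable registration.

Minimizes the energy

    E(f) = sum_I w_I sum_p |I_R(p) - I(p + u(p))|^2
           + lambda * sum_{(p,q) in N} ||u(p) - u(q)||^2

with a sum-of-squared-differences data term over the image channels and a
diffusion regularizer penalizing first-order differences over the set N of
6-connected voxel pairs (each unordered pair counted once).

The optimizer is a monotone coarse-to-fine gradient descent with
backtracking line search: any minimizer of this energy is admissible for
the reference-space construction, which consumes only the resulting fields.
The returned field never has higher (full-resolution) energy than its
initialization.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import Optional, Sequence

import numpy as np
from scipy.ndimage import gaussian_filter, map_coordinates, zoom

from .grids import DisplacementField, GridInfo, ImageVolume

__all__ = ["RegistrationConfig", "energy", "register"]


@dataclass
class RegistrationConfig:
    """Settings for the SSD + diffusion registration.

    channel_weights : per-channel non-negative weights w_I (dict name->weight
                      or sequence matching the fixed image's channels);
                      ``None`` means equal weights of 1
    smoothness_weight : multiplier lambda on the diffusion regularizer
    pyramid_levels  : number of resolution levels (x2 downsampling each)
    step_mm         : initial gradient-step displacement magnitude per level
    max_sweeps      : iteration cap per level
    rel_tol         : stop a level when the relative energy improvement of a
                      sweep falls below this
    seed            : reserved for stochastic sweep orderings (the default
                      optimizer is deterministic)
    """

    channel_weights: Optional[dict | Sequence[float]] = None
    smoothness_weight: float = 1.0
    pyramid_levels: int = 3
    step_mm: float = 2.0
    max_sweeps: int = 60
    rel_tol: float = 1e-4
    seed: int = 0

    def __post_init__(self):
        if self.pyramid_levels < 1:
            raise ValueError("pyramid_levels must be >= 1")

    def weights_for(self, channels: tuple[str, ...]) -> np.ndarray:
        if self.channel_weights is None:
            w = np.ones(len(channels))
        elif isinstance(self.channel_weights, dict):
            w = np.array([float(self.channel_weights.get(c, 0.0)) for c in channels])
        else:
            w = np.asarray(self.channel_weights, dtype=float)
            if w.shape != (len(channels),):
                raise ValueError("channel_weights length does not match channels")
        if np.any(w < 0) or not np.any(w > 0):
            raise ValueError("need non-negative weights with at least one positive")
        return w


def _sample_channels(data: np.ndarray, grid: GridInfo, u: np.ndarray) -> np.ndarray:
    """Sample each channel of ``data`` at x + u by linear interpolation."""
    pts = grid.meshgrid() + u
    idx = grid.index_from_physical(pts)
    coords = np.moveaxis(idx, -1, 0)
    return np.stack(
        [map_coordinates(ch, coords, order=1, mode="nearest") for ch in data]
    )


def _smoothness(u: np.ndarray) -> float:
    s = 0.0
    for ax in range(3):
        d = np.diff(u, axis=ax)
        s += float(np.sum(d * d))
    return s


def _energy_terms(fixed_data, grid, moving_data, u, weights, lam):
    warped = _sample_channels(moving_data, grid, u)
    resid = warped - fixed_data
    data_term = float(np.sum(weights[:, None, None, None] * resid * resid))
    return data_term + lam * _smoothness(u), resid, warped


def energy(
    fixed: ImageVolume,
    moving: ImageVolume,
    u: DisplacementField,
    config: RegistrationConfig | None = None,
) -> float:
    """Registration energy E(f) of a displacement for a fixed/moving pair."""
    if config is None:
        config = RegistrationConfig()
    if fixed.channels != moving.channels:
        raise ValueError("fixed and moving images must share channel names")
    if not fixed.grid.matches(u.grid):
        raise ValueError("displacement must live on the fixed image's grid")
    w = config.weights_for(fixed.channels)
    e, _, _ = _energy_terms(
        fixed.data, fixed.grid, moving.data, u.data, w, config.smoothness_weight
    )
    return e


def _graph_laplacian(u: np.ndarray) -> np.ndarray:
    """Gradient of the pairwise smoothness term, i.e. 2 * L u (6-connectivity)."""
    g = np.zeros_like(u)
    for ax in range(3):
        d = np.diff(u, axis=ax)
        sl_lo = [slice(None)] * 4
        sl_hi = [slice(None)] * 4
        sl_lo[ax] = slice(0, -1)
        sl_hi[ax] = slice(1, None)
        g[tuple(sl_lo)] -= 2.0 * d
        g[tuple(sl_hi)] += 2.0 * d
    return g


def _downsample_image(data: np.ndarray, factor: int) -> np.ndarray:
    if factor == 1:
        return data
    sig = 0.5 * factor
    out = []
    for ch in data:
        sm = gaussian_filter(ch, sigma=sig)
        out.append(zoom(sm, 1.0 / factor, order=1, grid_mode=False))
    return np.stack(out)


def _resample_field(u: np.ndarray, src_grid: GridInfo, dst_grid: GridInfo) -> np.ndarray:
    """Resample displacement vectors (mm, values unchanged) onto another grid."""
    pts = dst_grid.meshgrid()
    idx = src_grid.index_from_physical(pts)
    coords = np.moveaxis(idx, -1, 0)
    return np.stack(
        [
            map_coordinates(u[..., c], coords, order=1, mode="nearest")
            for c in range(3)
        ],
        axis=-1,
    )


def register(
    fixed: ImageVolume,
    moving: ImageVolume,
    config: RegistrationConfig | None = None,
    init: Optional[DisplacementField] = None,
) -> DisplacementField:
    """Estimate the displacement u registering ``moving`` to ``fixed``.

    Coarse-to-fine gradient descent on E with backtracking line search;
    monotone per level, and guarded so the returned field's full-resolution
    energy never exceeds that of the initialization (or the zero field if
    ``init`` is None).
    """
    if config is None:
        config = RegistrationConfig()
    if fixed.channels != moving.channels:
        raise ValueError("fixed and moving images must share channel names")
    w = config.weights_for(fixed.channels)
    lam = config.smoothness_weight
    grid = fixed.grid

    u_init = init.data.copy() if init is not None else np.zeros(tuple(grid.shape) + (3,))
    if init is not None and not init.grid.matches(grid):
        raise ValueError("init field must live on the fixed image's grid")

    # build pyramid, coarse to fine
    levels = []
    for lev in range(config.pyramid_levels - 1, -1, -1):
        factor = 2**lev
        if min(grid.shape) // factor < 8:
            continue
        f_data = _downsample_image(fixed.data, factor)
        m_data = _downsample_image(moving.data, factor)
        lshape = f_data.shape[1:]
        # zoom maps node 0..m-1 onto 0..n-1: spacing scales by (n-1)/(m-1)
        lspacing = tuple(
            grid.spacing_arr[d] * (grid.shape[d] - 1) / max(lshape[d] - 1, 1)
            for d in range(3)
        )
        lgrid = GridInfo(shape=lshape, spacing=lspacing, origin=tuple(grid.origin_arr))
        levels.append((lgrid, f_data, m_data))
    if not levels:
        levels = [(grid, fixed.data, moving.data)]

    u = _resample_field(u_init, grid, levels[0][0])
    for li, (lgrid, f_data, m_data) in enumerate(levels):
        if li > 0:
            u = _resample_field(u, levels[li - 1][0], lgrid)
        u = _descend(f_data, m_data, lgrid, u, w, lam, config)
    if not levels[-1][0].matches(grid):
        u = _resample_field(u, levels[-1][0], grid)

    e_final, _, _ = _energy_terms(fixed.data, grid, moving.data, u, w, lam)
    e_init, _, _ = _energy_terms(fixed.data, grid, moving.data, u_init, w, lam)
    if e_final > e_init:
        u = u_init
    return DisplacementField(u, grid)


def _descend(f_data, m_data, lgrid, u, w, lam, config: RegistrationConfig):
    spacing = lgrid.spacing_arr
    # spatial gradients of the moving channels (per mm), sampled at x + u
    m_grads = [np.gradient(ch, *spacing) for ch in m_data]
    e, resid, _ = _energy_terms(f_data, lgrid, m_data, u, w, lam)
    step = config.step_mm
    for _ in range(config.max_sweeps):
        pts = lgrid.meshgrid() + u
        idx = lgrid.index_from_physical(pts)
        coords = np.moveaxis(idx, -1, 0)
        g = lam * _graph_laplacian(u)
        for ci in range(len(m_data)):
            if w[ci] == 0:
                continue
            for ax in range(3):
                gch = map_coordinates(
                    m_grads[ci][ax], coords, order=1, mode="nearest"
                )
                g[..., ax] += 2.0 * w[ci] * resid[ci] * gch
        gmax = np.abs(g).max()
        if gmax == 0:
            break
        direction = -g / gmax  # max component = step mm
        improved = False
        while step > 1e-4 * config.step_mm:
            u_try = u + step * direction
            e_try, resid_try, _ = _energy_terms(f_data, lgrid, m_data, u_try, w, lam)
            if e_try < e:
                rel = (e - e_try) / max(e, 1e-30)
                u, resid = u_try, resid_try
                e = e_try
                improved = True
                step = min(step * 1.4, 4.0 * config.step_mm)
                break
            step *= 0.5
        if not improved:
            break
        if rel < config.rel_tol:
            break
    return u
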