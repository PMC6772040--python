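"""Cohort-average Jacobian and prescribed-Jacobian field synthesis.

The correction field d of the average-volume reference space is defined by
requiring its Jacobian to equal the voxel-wise geometric mean of the cohort
Jacobians,

    Jbar(x) = exp( (1/n) * sum_i ln( max{eps, J_i(x)} ) ),

computed under the logarithm for numerical stability, with a lower threshold
eps > 0 removing singularities caused by local folds from registration
errors.  Synthesizing a displacement with a prescribed Jacobian is ill-posed
without boundary conditions; here the displacement is constrained to vanish
on the grid boundary, which requires the target's grid-wide (arithmetic)
mean to be 1 — a global integrability condition enforced by rescaling the
background (outside the body mask) before synthesis.

The synthesis itself is an iterative search on the squared-mismatch
objective F(u) = sum_x (J[id + u](x) - target(x))^2.  Each step computes
the exact gradient of F through the cofactor identity
dDet(A)/dA = cof(A) and the adjoint of the finite-difference operator,
then preconditions it with the inverse Dirichlet Laplacian (solved with a
fast sine transform) — a Newton-like metric, since the Gauss-Newton
Hessian of F is dominated by a grad-div operator.  The preconditioner is
symmetric positive definite, so the preconditioned direction is always a
descent direction and step halving guarantees the objective never
increases.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import Optional

import numpy as np
from scipy.fft import dstn, idstn

from .fields import interior_mask, jacobian_determinant
from .grids import DisplacementField, GridInfo, JacobianMap, MaskVolume

__all__ = [
    "SynthesisConfig",
    "ConvergenceReport",
    "mean_jacobian",
    "displacement_from_jacobian",
]


@dataclass
class SynthesisConfig:
    """Parameters of the correction-field synthesis.

    epsilon : lower clamp applied to Jacobians before log-averaging
    tol     : max absolute Jacobian mismatch on enforced voxels at convergence
    max_iter: iteration cap for the search
    step0   : initial update step (dimensionless multiplier on grad(phi))
    mask    : optional body mask; matching is enforced on interior mask
              voxels and feasibility is restored by rescaling outside it
    """

    epsilon: float = 0.01
    tol: float = 0.01
    max_iter: int = 500
    step0: float = 1.0
    mask: Optional[MaskVolume] = None

    def __post_init__(self):
        if self.epsilon <= 0:
            raise ValueError("epsilon must be > 0")
        if self.tol <= 0:
            raise ValueError("tol must be > 0")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")


@dataclass
class ConvergenceReport:
    converged: bool
    iterations: int
    max_mismatch: float
    objective_trace: list = dc_field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "converged": bool(self.converged),
            "iterations": int(self.iterations),
            "max_mismatch": float(self.max_mismatch),
            "objective_trace": [float(v) for v in self.objective_trace],
        }


def mean_jacobian(jacobians, epsilon: float = 0.01) -> JacobianMap:
    """Clamped log-domain (geometric) mean of cohort Jacobian maps.

    Each input is clamped below at ``epsilon`` before taking logs, so the
    output is strictly >= epsilon even where a registration locally folded.
    """
    jacobians = list(jacobians)
    if not jacobians:
        raise ValueError("mean_jacobian requires at least one map")
    if epsilon <= 0:
        raise ValueError("epsilon must be > 0")
    grid = jacobians[0].grid
    for j in jacobians[1:]:
        if not j.grid.matches(grid):
            raise ValueError("all jacobian maps must share the same grid")
    logs = np.mean(
        [np.log(np.maximum(epsilon, j.data)) for j in jacobians], axis=0
    )
    return JacobianMap(np.exp(logs), grid)


def _poisson_dirichlet(rhs: np.ndarray, spacing) -> np.ndarray:
    """Solve laplace(phi) = rhs with phi = 0 on the grid boundary.

    Standard 7-point Laplacian, diagonalized by the type-I discrete sine
    transform on the interior nodes.
    """
    interior = rhs[1:-1, 1:-1, 1:-1]
    n = interior.shape
    coef = dstn(interior, type=1)
    lam = 0.0
    for d in range(3):
        k = np.arange(1, n[d] + 1)
        lam_d = (2.0 - 2.0 * np.cos(np.pi * k / (n[d] + 1))) / spacing[d] ** 2
        shape = [1, 1, 1]
        shape[d] = n[d]
        lam = lam + lam_d.reshape(shape)
    coef = -coef / lam
    phi = np.zeros_like(rhs)
    phi[1:-1, 1:-1, 1:-1] = idstn(coef, type=1)
    return phi


def _adjust_target(target: JacobianMap, mask: Optional[MaskVolume]) -> np.ndarray:
    """Rescale the target so its grid-wide mean is 1 (zero-boundary feasibility).

    With a body mask, only values outside it (background) are rescaled,
    preserving the anatomically meaningful prescription; without a mask the
    whole map is rescaled uniformly.
    """
    t = target.data.astype(float).copy()
    n = t.size
    if mask is None:
        c = n / t.sum()
        t *= c
    else:
        body = mask.data
        bg = ~body
        need = n - t[body].sum()
        bg_sum = t[bg].sum()
        if bg.sum() == 0 or need <= 0 or bg_sum <= 0:
            raise ValueError(
                "target is infeasible: background rescaling cannot bring the "
                "grid-wide mean Jacobian to 1 with zero-boundary displacement"
            )
        t[bg] *= need / bg_sum
    if abs(t.mean() - 1.0) > 1e-6:
        raise ValueError("target mean could not be adjusted to 1 within 1e-6")
    return t


def _gradient_adjoint(w: np.ndarray, h: float, axis: int) -> np.ndarray:
    """Adjoint of the finite-difference operator used by ``np.gradient``.

    np.gradient uses central differences at interior nodes and one-sided
    differences at the two boundary nodes; this is the exact transpose of
    that linear operator, applied along ``axis``.
    """
    w = np.moveaxis(w, axis, 0)
    out = np.zeros_like(w)
    # interior rows x: +w_x/(2h) at x+1, -w_x/(2h) at x-1
    out[2:] += w[1:-1] / (2.0 * h)
    out[:-2] -= w[1:-1] / (2.0 * h)
    # boundary rows
    out[0] -= w[0] / h
    out[1] += w[0] / h
    out[-2] -= w[-1] / h
    out[-1] += w[-1] / h
    return np.moveaxis(out, 0, axis)


def _jacobian_and_cofactors(u: np.ndarray, spacing):
    """J = det(I + Du) and the cofactor matrix of A = I + Du."""
    a = np.empty((3, 3) + u.shape[:3])
    for i in range(3):
        grads = np.gradient(u[..., i], *spacing)
        for j in range(3):
            a[i, j] = grads[j] + (1.0 if i == j else 0.0)
    cof = np.empty_like(a)
    for i in range(3):
        for j in range(3):
            i1, i2 = [k for k in range(3) if k != i]
            j1, j2 = [k for k in range(3) if k != j]
            minor = a[i1, j1] * a[i2, j2] - a[i1, j2] * a[i2, j1]
            cof[i, j] = (-1.0) ** (i + j) * minor
    jac = a[0, 0] * cof[0, 0] + a[0, 1] * cof[0, 1] + a[0, 2] * cof[0, 2]
    return jac, cof


def _zero_boundary(u: np.ndarray) -> np.ndarray:
    u[0, :, :] = 0.0
    u[-1, :, :] = 0.0
    u[:, 0, :] = 0.0
    u[:, -1, :] = 0.0
    u[:, :, 0] = 0.0
    u[:, :, -1] = 0.0
    return u


def displacement_from_jacobian(
    target: JacobianMap, config: SynthesisConfig | None = None
) -> tuple[DisplacementField, ConvergenceReport]:
    """Synthesize a displacement field whose Jacobian matches ``target``.

    Returns the field (zero on the grid boundary) and a convergence report.
    Matching is enforced on interior voxels (the boundary shell is pinned by
    the boundary condition), intersected with ``config.mask`` when given.
    The squared-mismatch objective is monotonically non-increasing across
    iterations by construction.

    Raises
    ------
    ValueError
        If the target has non-positive values, or cannot be adjusted to
        grid-wide mean 1.
    """
    if config is None:
        config = SynthesisConfig()
    if np.any(target.data <= 0):
        raise ValueError("target jacobian must be strictly positive")
    if config.mask is not None and not config.mask.grid.matches(target.grid):
        raise ValueError("mask grid does not match target grid")

    grid = target.grid
    t = _adjust_target(target, config.mask)

    enforced = interior_mask(grid, margin=1)
    if config.mask is not None:
        enforced &= config.mask.data
    if not enforced.any():
        raise ValueError("no enforced voxels (mask empty on the interior)")

    spacing = grid.spacing_arr

    u = np.zeros(tuple(grid.shape) + (3,))
    jac, cof = _jacobian_and_cofactors(u, spacing)
    resid = jac - t
    obj = float(np.sum(resid * resid))
    trace = [obj]
    mismatch = float(np.max(np.abs(resid)[enforced]))
    step = config.step0
    converged = mismatch <= config.tol
    it = 0

    while not converged and it < config.max_iter:
        it += 1
        # exact gradient of F through the cofactor identity, then the
        # SPD inverse-Laplacian preconditioner => always a descent direction
        g = np.empty_like(u)
        for i in range(3):
            gi = np.zeros(grid.shape)
            for j in range(3):
                gi += _gradient_adjoint(2.0 * resid * cof[i, j], spacing[j], j)
            g[..., i] = gi
        _zero_boundary(g)
        du = np.empty_like(u)
        for i in range(3):
            du[..., i] = _poisson_dirichlet(g[..., i], spacing)
        accepted = False
        for _ in range(30):
            u_try = _zero_boundary(u + step * du)
            jac_try, cof_try = _jacobian_and_cofactors(u_try, spacing)
            resid_try = jac_try - t
            obj_try = float(np.sum(resid_try * resid_try))
            if obj_try <= obj:
                accepted = True
                break
            step *= 0.5
        if not accepted:
            trace.append(obj)
            break
        u, jac, cof, resid, obj = u_try, jac_try, cof_try, resid_try, obj_try
        trace.append(obj)
        step = min(step * 1.5, 64.0 * config.step0)
        mismatch = float(np.max(np.abs(resid)[enforced]))
        converged = mismatch <= config.tol

    report = ConvergenceReport(
        converged=converged,
        iterations=it,
        max_mismatch=mismatch,
        objective_trace=trace,
    )
    return DisplacementField(u, grid), report
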