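"""Grid-attached volume types shared across the package.

All objects live on a regular 3-D grid with node-centred voxels: voxel index
``i`` maps to the physical point ``origin + i * spacing`` (0-based, mm).
Displacements are stored in physical units (mm) so that Jacobians computed
with spacing-normalized derivatives are correct on anisotropic grids such as
the 2.07 x 2.07 x 8.00 mm voxels of whole-body MR protocols.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

__all__ = [
    "GridInfo",
    "ImageVolume",
    "MaskVolume",
    "LabelVolume",
    "JacobianMap",
    "DisplacementField",
]


def _as_triple(x, dtype=float) -> np.ndarray:
    arr = np.asarray(x, dtype=dtype)
    if arr.shape == ():
        arr = np.full(3, arr)
    if arr.shape != (3,):
        raise ValueError(f"expected a length-3 vector, got shape {arr.shape}")
    return arr


@dataclass(frozen=True)
class GridInfo:
    """Geometry of a regular 3-D sampling grid."""

    shape: tuple[int, int, int]
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        if len(self.shape) != 3:
            raise ValueError("grid must be 3-D")
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be strictly positive")

    @property
    def spacing_arr(self) -> np.ndarray:
        return np.asarray(self.spacing, dtype=float)

    @property
    def origin_arr(self) -> np.ndarray:
        return np.asarray(self.origin, dtype=float)

    @property
    def extent(self) -> np.ndarray:
        """Physical size of the grid, mm per axis."""
        return (np.asarray(self.shape) - 1) * self.spacing_arr

    def physical_coordinates(self) -> list[np.ndarray]:
        """Per-axis physical coordinate vectors (mm)."""
        return [
            self.origin[d] + self.spacing[d] * np.arange(self.shape[d])
            for d in range(3)
        ]

    def meshgrid(self) -> np.ndarray:
        """(X, Y, Z, 3) array of physical point coordinates."""
        axes = self.physical_coordinates()
        return np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1)

    def index_from_physical(self, points: np.ndarray) -> np.ndarray:
        """Map physical points (..., 3) to fractional voxel indices."""
        return (points - self.origin_arr) / self.spacing_arr

    def matches(self, other: "GridInfo", atol: float = 1e-6) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing, atol=atol)
            and np.allclose(self.origin, other.origin, atol=atol)
        )


class _GridVolume:
    """Mixin giving grid accessors to volume dataclasses."""

    grid: GridInfo

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.grid.shape

    @property
    def spacing(self) -> np.ndarray:
        return self.grid.spacing_arr

    @property
    def origin(self) -> np.ndarray:
        return self.grid.origin_arr

    def same_grid(self, other: "_GridVolume") -> bool:
        return self.grid.matches(other.grid)


def make_grid(shape, spacing, origin=(0.0, 0.0, 0.0)) -> GridInfo:
    shape = tuple(int(s) for s in np.atleast_1d(shape).repeat(3)[:3]) if np.ndim(shape) == 0 else tuple(int(s) for s in shape)
    return GridInfo(shape=shape, spacing=tuple(_as_triple(spacing)), origin=tuple(_as_triple(origin)))


@dataclass
class ImageVolume(_GridVolume):
    """n-channel scalar volume (e.g. fat, water, body mask channels).

    ``data`` has shape (n_channels,) + grid.shape; intensities are in
    arbitrary units and must be finite.
    """

    data: np.ndarray
    grid: GridInfo
    channels: tuple[str, ...] = ("intensity",)

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim == 3:
            self.data = self.data[None]
        if self.data.ndim != 4:
            raise ValueError("image data must be (channels, X, Y, Z)")
        self.channels = tuple(self.channels)
        if self.data.shape[0] != len(self.channels):
            raise ValueError(
                f"{self.data.shape[0]} data channels but {len(self.channels)} names"
            )
        if self.data.shape[1:] != tuple(self.grid.shape):
            raise ValueError("image data shape does not match grid")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("image intensities must be finite")

    @property
    def n_channels(self) -> int:
        return len(self.channels)

    def channel(self, name: str) -> np.ndarray:
        try:
            return self.data[self.channels.index(name)]
        except ValueError:
            raise KeyError(f"no channel named {name!r}; have {self.channels}") from None

    def with_data(self, data: np.ndarray) -> "ImageVolume":
        return ImageVolume(data=data, grid=self.grid, channels=self.channels)

    def select_channels(self, names: Sequence[str]) -> "ImageVolume":
        idx = [self.channels.index(n) for n in names]
        return ImageVolume(self.data[idx], self.grid, tuple(names))


@dataclass
class MaskVolume(_GridVolume):
    """Boolean region-of-interest volume."""

    data: np.ndarray
    grid: GridInfo

    def __post_init__(self):
        self.data = np.asarray(self.data).astype(bool)
        if self.data.shape != tuple(self.grid.shape):
            raise ValueError("mask shape does not match grid")

    @property
    def n_voxels(self) -> int:
        return int(self.data.sum())


@dataclass
class LabelVolume(_GridVolume):
    """Integer organ-segmentation volume; 0 is background."""

    data: np.ndarray
    grid: GridInfo

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if not np.issubdtype(self.data.dtype, np.integer):
            if np.any(self.data != np.round(self.data)):
                raise ValueError("labels must be integers")
            self.data = self.data.astype(np.int32)
        if np.any(self.data < 0):
            raise ValueError("labels must be non-negative")
        if self.data.shape != tuple(self.grid.shape):
            raise ValueError("label shape does not match grid")

    def labels_present(self) -> np.ndarray:
        return np.unique(self.data)


@dataclass
class JacobianMap(_GridVolume):
    """Per-voxel Jacobian determinant (dimensionless volume ratio)."""

    data: np.ndarray
    grid: GridInfo

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.shape != tuple(self.grid.shape):
            raise ValueError("jacobian shape does not match grid")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("jacobian values must be finite")


@dataclass
class DisplacementField(_GridVolume):
    """Dense displacement u(x) in mm; the deformation is f(x) = x + u(x)."""

    data: np.ndarray
    grid: GridInfo

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 4 or self.data.shape[-1] != 3:
            raise ValueError("displacement data must be (X, Y, Z, 3)")
        if self.data.shape[:3] != tuple(self.grid.shape):
            raise ValueError("displacement shape does not match grid")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("displacements must be finite")

    @classmethod
    def zeros(cls, grid: GridInfo) -> "DisplacementField":
        return cls(np.zeros(tuple(grid.shape) + (3,)), grid)

    @classmethod
    def constant(cls, grid: GridInfo, vector) -> "DisplacementField":
        v = _as_triple(vector)
        data = np.broadcast_to(v, tuple(grid.shape) + (3,)).copy()
        return cls(data, grid)

    def magnitude(self) -> np.ndarray:
        """Per-voxel Euclidean norm of the displacement, mm."""
        return np.linalg.norm(self.data, axis=-1)

    def __neg__(self) -> "DisplacementField":
        return DisplacementField(-self.data, self.grid)
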