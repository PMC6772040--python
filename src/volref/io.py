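"""NIfTI reading and writing for volumes, labels, masks and fields.

Scalar and label volumes are plain 3-D NIfTI; multi-channel images use a
4th dimension with channel names recorded in the header description;
displacement fields use a trailing vector dimension of 3 and the NIfTI
vector intent code.  Spacing and origin are carried in the affine
(axis-aligned; no rotation component is supported).
"""

from __future__ import annotations

import numpy as np
import nibabel as nib

from .grids import (
    DisplacementField,
    GridInfo,
    ImageVolume,
    JacobianMap,
    LabelVolume,
    MaskVolume,
)

__all__ = [
    "read_volume",
    "read_image",
    "read_labels",
    "read_mask",
    "read_field",
    "write_volume",
    "FormatError",
]

_VECTOR_INTENT = 1007  # NIFTI_INTENT_VECTOR


class FormatError(ValueError):
    """Raised when a file's header or payload is not usable."""


def _grid_from_header(img) -> GridInfo:
    zooms = img.header.get_zooms()[:3]
    if any(not np.isfinite(z) or z <= 0 for z in zooms):
        raise FormatError(f"non-positive voxel spacing in header: {zooms}")
    origin = img.affine[:3, 3]
    return GridInfo(
        shape=tuple(int(s) for s in img.shape[:3]),
        spacing=tuple(float(z) for z in zooms),
        origin=tuple(float(o) for o in origin),
    )


def _affine(grid: GridInfo) -> np.ndarray:
    aff = np.diag(list(grid.spacing) + [1.0])
    aff[:3, 3] = grid.origin
    return aff


def _load(path):
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    if not np.all(np.isfinite(data)):
        raise FormatError(f"{path}: payload contains non-finite values")
    return img, data


def read_volume(path):
    """Read a NIfTI file as the most specific volume type.

    4-D with the vector intent code (or a trailing dimension of 3 without
    channel names) -> DisplacementField; integer payload -> LabelVolume;
    otherwise ImageVolume (4th dimension = channels).
    """
    img, data = _load(path)
    grid = _grid_from_header(img)
    if data.ndim == 4:
        intent = img.header.get_intent()[0]
        descrip = img.header["descrip"].tobytes().decode(errors="ignore").strip("\x00")
        is_channel_image = descrip.startswith("channels:")
        if not is_channel_image and (intent == "vector" or data.shape[-1] == 3):
            if data.shape[-1] != 3:
                raise FormatError(f"{path}: vector field must have 3 components")
            return DisplacementField(data.astype(float), grid)
        if is_channel_image:
            names = tuple(descrip[len("channels:"):].split(","))
        else:
            names = tuple(f"ch{i}" for i in range(data.shape[-1]))
        return ImageVolume(np.moveaxis(data, -1, 0), grid, names)
    if data.ndim != 3:
        raise FormatError(f"{path}: expected 3-D or 4-D data, got {data.ndim}-D")
    if np.issubdtype(data.dtype, np.integer):
        return LabelVolume(data, grid)
    return ImageVolume(data[None], grid)


def read_field(path) -> DisplacementField:
    obj = read_volume(path)
    if not isinstance(obj, DisplacementField):
        raise FormatError(f"{path}: not a displacement field (no trailing vector dimension)")
    return obj


def read_image(path) -> ImageVolume:
    obj = read_volume(path)
    if isinstance(obj, LabelVolume):
        return ImageVolume(obj.data.astype(float)[None], obj.grid)
    if not isinstance(obj, ImageVolume):
        raise FormatError(f"{path}: not a scalar image volume")
    return obj


def read_labels(path) -> LabelVolume:
    img, data = _load(path)
    grid = _grid_from_header(img)
    if data.ndim != 3:
        raise FormatError(f"{path}: label volume must be 3-D")
    if not np.all(data == np.round(data)):
        raise FormatError(f"{path}: label volume has non-integer values")
    return LabelVolume(data.astype(np.int32), grid)


def read_mask(path) -> MaskVolume:
    lab = read_labels(path)
    return MaskVolume(lab.data > 0, lab.grid)


def write_volume(obj, path) -> None:
    """Write any grid volume type to NIfTI, preserving spacing and origin."""
    if isinstance(obj, DisplacementField):
        img = nib.Nifti1Image(obj.data.astype(np.float64), _affine(obj.grid))
        img.header.set_intent(_VECTOR_INTENT)
    elif isinstance(obj, ImageVolume):
        if obj.n_channels == 1:
            img = nib.Nifti1Image(obj.data[0].astype(np.float64), _affine(obj.grid))
        else:
            img = nib.Nifti1Image(
                np.moveaxis(obj.data, 0, -1).astype(np.float64), _affine(obj.grid)
            )
            img.header["descrip"] = ("channels:" + ",".join(obj.channels)).encode()[:79]
    elif isinstance(obj, (LabelVolume,)):
        img = nib.Nifti1Image(obj.data.astype(np.int32), _affine(obj.grid))
    elif isinstance(obj, MaskVolume):
        img = nib.Nifti1Image(obj.data.astype(np.int32), _affine(obj.grid))
    elif isinstance(obj, JacobianMap):
        img = nib.Nifti1Image(obj.data.astype(np.float64), _affine(obj.grid))
    else:
        raise TypeError(f"cannot write object of type {type(obj).__name__}")
    zooms = list(obj.grid.spacing)
    img.header.set_zooms(tuple(zooms) + tuple([1.0] * (img.ndim - 3)))
    nib.save(img, str(path))
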