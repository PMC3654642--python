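"""Volume input/output: NIfTI and multi-page TIFF, with tensor sidecars.

Scalar volumes round-trip through standard formats directly.  Tensor
fields have no standard on-disk layout, so one is defined here: the
complex component stack is written as a 4D volume with real and imaginary
planes interleaved per m (m descending from +j), and a JSON sidecar
(`<path>.json`) records rank, m-order, parity type, spacing and origin.
Reading a tensor volume without its sidecar is an error rather than a
guess.
"""

from __future__ import annotations

import json
import os

import numpy as np
import nibabel as nib
import tifffile

from sphtensor.fields import SphericalTensorField

__all__ = ["read_volume", "write_volume", "read_tensor_field", "write_tensor_field"]

_NIFTI_EXTS = (".nii", ".nii.gz")
_TIFF_EXTS = (".tif", ".tiff")


def _ext_kind(path: str) -> str:
    low = path.lower()
    if low.endswith(_NIFTI_EXTS):
        return "nifti"
    if low.endswith(_TIFF_EXTS):
        return "tiff"
    raise ValueError(
        f"unknown volume extension for {path!r} (expected .nii[.gz] or .tif[f])"
    )


def write_volume(field: SphericalTensorField, path: str) -> None:
    """Write a scalar field as NIfTI or multi-page TIFF (float32)."""
    if field.j != 0:
        raise ValueError("write_volume stores scalar volumes; use "
                         "write_tensor_field for rank >= 1")
    arr = np.asarray(np.real(field.data[0]), dtype=np.float32)
    kind = _ext_kind(path)
    if kind == "nifti":
        aff = np.diag([field.spacing] * 3 + [1.0])
        nib.save(nib.Nifti1Image(arr, aff), path)
    else:
        tifffile.imwrite(path, np.moveaxis(arr, 2, 0))  # pages along z


def read_volume(path: str) -> SphericalTensorField:
    """Read a scalar volume; spacing comes from the header when present."""
    kind = _ext_kind(path)
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    if kind == "nifti":
        try:
            img = nib.load(path)
            arr = np.asarray(img.get_fdata(), dtype=float)
        except Exception as e:  # corrupt header etc.
            raise ValueError(f"could not read NIfTI volume {path!r}: {e}") from e
        if arr.ndim != 3:
            raise ValueError(f"{path!r} is not a 3D scalar volume")
        zooms = img.header.get_zooms()[:3]
        if not np.allclose(zooms, zooms[0]):
            raise ValueError("anisotropic voxel spacing is not supported")
        spacing = float(zooms[0]) if zooms[0] > 0 else 1.0
        return SphericalTensorField.from_scalar(arr, spacing)
    try:
        arr = tifffile.imread(path)
    except Exception as e:
        raise ValueError(f"could not read TIFF volume {path!r}: {e}") from e
    if arr.ndim != 3:
        raise ValueError(f"{path!r} is not a 3D scalar volume")
    return SphericalTensorField.from_scalar(np.moveaxis(arr, 0, 2).astype(float))


def write_tensor_field(field: SphericalTensorField, path: str) -> None:
    """Write a tensor field as a 4D volume plus JSON sidecar.

    The 4th axis interleaves (Re, Im) planes per component, m descending.
    """
    kind = _ext_kind(path)
    n = field.data.shape[0]
    stack = np.empty((*field.grid_shape, 2 * n), dtype=np.float32)
    for c in range(n):
        stack[..., 2 * c] = np.real(field.data[c])
        stack[..., 2 * c + 1] = np.imag(field.data[c])
    if kind == "nifti":
        aff = np.diag([field.spacing] * 3 + [1.0])
        nib.save(nib.Nifti1Image(stack, aff), path)
    else:
        tifffile.imwrite(path, np.moveaxis(stack, (2, 3), (1, 0)))
    sidecar = {
        "rank": field.j,
        "m_order": "descending",
        "parity": "imag" if field.imag_type else "real",
        "layout": "re_im_interleaved",
        "spacing": field.spacing,
        "origin": list(field.origin),
    }
    with open(path + ".json", "w") as fh:
        json.dump(sidecar, fh, indent=2)


def read_tensor_field(path: str) -> SphericalTensorField:
    """Read a tensor field written by :func:`write_tensor_field`."""
    sc_path = path + ".json"
    if not os.path.exists(sc_path):
        raise ValueError(
            f"tensor volume {path!r} has no JSON sidecar ({sc_path} missing); "
            "rank and component layout cannot be inferred"
        )
    with open(sc_path) as fh:
        meta = json.load(fh)
    kind = _ext_kind(path)
    if kind == "nifti":
        stack = np.asarray(nib.load(path).get_fdata(), dtype=float)
    else:
        stack = np.moveaxis(tifffile.imread(path), (1, 0), (2, 3)).astype(float)
    j = int(meta["rank"])
    n = 2 * j + 1
    if stack.ndim != 4 or stack.shape[-1] != 2 * n:
        raise ValueError(
            f"{path!r}: expected {2 * n} interleaved planes for rank {j}, "
            f"got shape {stack.shape}"
        )
    data = np.empty((n, *stack.shape[:3]), dtype=complex)
    for c in range(n):
        data[c] = stack[..., 2 * c] + 1j * stack[..., 2 * c + 1]
    return SphericalTensorField(
        j, data, float(meta.get("spacing", 1.0)),
        tuple(meta["origin"]) if "origin" in meta else None,
        meta.get("parity") == "imag",
    )
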