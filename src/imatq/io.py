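"""Readers and writers for images, labels and stage-exchange CSV tables.

NIfTI-1 (spacing from the header) and TIFF (spacing from an explicit
argument or a ``<file>.spacing`` sidecar holding the mm value) are
supported.  3-D inputs reduce to 2-D via a singleton axis or an explicit
slice index.  CSV files written by the pipeline start with a comment
line recording the configuration hash and seed, so every output is
traceable to the run that produced it.
"""

from __future__ import annotations

import os

import nibabel as nib
import numpy as np
import pandas as pd
import tifffile

from .image import Image2D, LabelMask

__all__ = ["read_image", "write_image", "read_labels", "write_labels",
           "write_csv", "read_csv"]

_NIFTI_SUFFIXES = (".nii", ".nii.gz")
_TIFF_SUFFIXES = (".tif", ".tiff")


def _is_nifti(path: str) -> bool:
    return path.endswith(_NIFTI_SUFFIXES)


def _is_tiff(path: str) -> bool:
    return path.lower().endswith(_TIFF_SUFFIXES)


def _reduce_to_2d(data: np.ndarray, slice_index: int | None) -> np.ndarray:
    if data.ndim == 2:
        return data
    if data.ndim == 3:
        if slice_index is not None:
            return data[:, :, slice_index]
        squeezed = np.squeeze(data)
        if squeezed.ndim == 2:
            return squeezed
        raise ValueError(
            "3-D input without a singleton axis requires slice_index"
        )
    raise ValueError(f"cannot reduce array of shape {data.shape} to 2-D")


def read_image(path: str, spacing: float | None = None,
               slice_index: int | None = None) -> Image2D:
    """Read a single-channel image as :class:`Image2D`.

    For NIfTI the spacing comes from the header (and must be isotropic
    in-plane); for TIFF it must be supplied or present in a
    ``<file>.spacing`` sidecar.
    """
    if _is_nifti(path):
        img = nib.load(path)
        data = np.asanyarray(img.dataobj)
        zooms = img.header.get_zooms()[:2]
        if not np.isclose(zooms[0], zooms[1]):
            raise ValueError(f"anisotropic in-plane spacing {zooms} unsupported")
        return Image2D(_reduce_to_2d(data, slice_index).astype(float),
                       float(spacing if spacing is not None else zooms[0]))
    if _is_tiff(path):
        if spacing is None:
            sidecar = path + ".spacing"
            if os.path.exists(sidecar):
                with open(sidecar) as fh:
                    spacing = float(fh.read().strip())
            else:
                raise ValueError(
                    f"TIFF {path!r} carries no spacing: pass spacing= or "
                    "provide a .spacing sidecar"
                )
        data = tifffile.imread(path)
        return Image2D(_reduce_to_2d(data, slice_index).astype(float),
                       float(spacing))
    raise ValueError(f"unknown image format: {path!r}")


def write_image(image: Image2D, path: str) -> None:
    """Write an image; NIfTI keeps the spacing in its header, TIFF writes
    a ``.spacing`` sidecar."""
    if _is_nifti(path):
        affine = np.diag([image.spacing, image.spacing, 1.0, 1.0])
        nib.save(nib.Nifti1Image(image.data.astype(np.float32), affine), path)
    elif _is_tiff(path):
        tifffile.imwrite(path, image.data.astype(np.float32))
        with open(path + ".spacing", "w") as fh:
            fh.write(f"{image.spacing}\n")
    else:
        raise ValueError(f"unknown image format: {path!r}")


def read_labels(path: str, spacing: float | None = None,
                slice_index: int | None = None) -> LabelMask:
    img = read_image(path, spacing=spacing, slice_index=slice_index)
    return LabelMask(np.round(img.data).astype(np.int32), img.spacing)


def write_labels(labels: LabelMask, path: str) -> None:
    if _is_nifti(path):
        affine = np.diag([labels.spacing, labels.spacing, 1.0, 1.0])
        nib.save(nib.Nifti1Image(labels.data.astype(np.int16), affine), path)
    elif _is_tiff(path):
        tifffile.imwrite(path, labels.data.astype(np.int16))
        with open(path + ".spacing", "w") as fh:
            fh.write(f"{labels.spacing}\n")
    else:
        raise ValueError(f"unknown image format: {path!r}")


def write_csv(df: pd.DataFrame, path: str, config_hash: str = "",
              seed: int | None = None) -> None:
    """Write a stage table with a provenance comment line."""
    with open(path, "w") as fh:
        fh.write(f"# config_hash={config_hash} seed={seed}\n")
        df.to_csv(fh, index=False)


def read_csv(path: str) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")
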