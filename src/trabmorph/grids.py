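"""Core image containers: intensity grids and binary masks with physical spacing.

All images in this package are carried as :class:`ImageGrid` (scalar
intensities on a 2D or 3D grid with a physical pixel/voxel spacing in mm and a
modality tag) or :class:`BinaryMask` (boolean solid-phase grid sharing the
spacing of its source image).  Axis order is numpy order: ``(row, col)`` for
2D, ``(slice, row, col)`` for 3D.  Spacing is given per axis in the same
order.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import tifffile

__all__ = ["ImageGrid", "BinaryMask", "read_image", "write_image"]


def _as_spacing(spacing, ndim: int) -> tuple[float, ...]:
    arr = np.atleast_1d(np.asarray(spacing, dtype=float))
    if arr.size == 1:
        arr = np.repeat(arr, ndim)
    if arr.size != ndim:
        raise ValueError(f"spacing has {arr.size} entries for a {ndim}D grid")
    if np.any(arr <= 0) or not np.all(np.isfinite(arr)):
        raise ValueError(f"spacing must be positive and finite, got {arr}")
    return tuple(float(s) for s in arr)


@dataclasses.dataclass(frozen=True)
class ImageGrid:
    """A 2D/3D scalar intensity image with physical spacing.

    Parameters
    ----------
    values : ndarray
        Intensities, float64, 2D ``(row, col)`` or 3D ``(slice, row, col)``.
    spacing : tuple of float
        mm per pixel along each axis (same order as ``values`` axes).
    modality : str
        ``"CT_like"`` (bone bright) or ``"MR_like"`` (bone dark).
    axis_labels : tuple of str
        Orientation metadata; defaults to ``("row", "col")`` / with "slice".
    """

    values: np.ndarray
    spacing: tuple[float, ...]
    modality: str = "CT_like"
    axis_labels: tuple[str, ...] = ()

    def __post_init__(self):
        vals = np.asarray(self.values, dtype=float)
        if vals.ndim not in (2, 3):
            raise ValueError(f"expected a 2D or 3D grid, got ndim={vals.ndim}")
        if not np.all(np.isfinite(vals)):
            raise ValueError("intensities must be finite")
        if self.modality not in ("CT_like", "MR_like"):
            raise ValueError(f"unknown modality {self.modality!r}")
        object.__setattr__(self, "values", vals)
        object.__setattr__(self, "spacing", _as_spacing(self.spacing, vals.ndim))
        if not self.axis_labels:
            labels = ("slice", "row", "col")[-vals.ndim:]
            object.__setattr__(self, "axis_labels", labels)

    @property
    def shape(self) -> tuple[int, ...]:
        return self.values.shape

    @property
    def ndim(self) -> int:
        return self.values.ndim

    def with_values(self, values, spacing=None) -> "ImageGrid":
        return ImageGrid(values, self.spacing if spacing is None else spacing,
                         self.modality)

    def slice2d(self, index: int) -> "ImageGrid":
        """Extract slice ``index`` from a 3D stack as a 2D grid."""
        if self.ndim != 3:
            raise ValueError("slice2d requires a 3D stack")
        return ImageGrid(self.values[index], self.spacing[1:], self.modality)


@dataclasses.dataclass(frozen=True)
class BinaryMask:
    """Boolean solid-phase (bone) grid sharing spacing with its source image.

    ``roi`` is an optional sub-region as ``(row, col, height, width)`` in
    pixels (2D); morphometry restricts to it when present.
    """

    solid: np.ndarray
    spacing: tuple[float, ...]
    roi: tuple[int, int, int, int] | None = None

    def __post_init__(self):
        solid = np.asarray(self.solid, dtype=bool)
        if solid.ndim not in (2, 3):
            raise ValueError(f"expected a 2D or 3D mask, got ndim={solid.ndim}")
        object.__setattr__(self, "solid", solid)
        object.__setattr__(self, "spacing", _as_spacing(self.spacing, solid.ndim))
        if self.roi is not None:
            r, c, h, w = self.roi
            if solid.ndim != 2:
                raise ValueError("roi is only supported on 2D masks")
            if r < 0 or c < 0 or r + h > solid.shape[0] or c + w > solid.shape[1]:
                raise ValueError(f"roi {self.roi} exceeds mask shape {solid.shape}")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.solid.shape

    @property
    def ndim(self) -> int:
        return self.solid.ndim

    def complement(self) -> "BinaryMask":
        return BinaryMask(~self.solid, self.spacing, self.roi)

    def bvf(self) -> float:
        """Solid-pixel fraction over the ROI (whole grid when no ROI)."""
        sub = self.solid
        if self.roi is not None:
            r, c, h, w = self.roi
            sub = sub[r:r + h, c:c + w]
        return float(sub.mean())


def write_image(path, img: ImageGrid | BinaryMask) -> None:
    """Write a grid as TIFF (.tif/.tiff) or NIfTI (.nii/.nii.gz) with spacing.

    Masks are written as uint8 {0, 255}; spacing goes in the TIFF resolution
    tags / NIfTI header, plus a JSON sidecar with full metadata.
    """
    path = Path(path)
    if isinstance(img, BinaryMask):
        data = img.solid.astype(np.uint8) * 255
    else:
        data = img.values.astype(np.float32)
    if path.suffix in (".tif", ".tiff"):
        tifffile.imwrite(path, data)
    elif path.name.endswith((".nii", ".nii.gz")):
        import nibabel as nib
        affine = np.diag(list(img.spacing[::-1]) + [1.0])[:4, :4]
        if affine.shape[0] < 4:  # 2D: pad to a 4x4 affine
            pad = np.eye(4)
            pad[: affine.shape[0] - 1, : affine.shape[1] - 1] = affine[:-1, :-1]
            affine = pad
        nib.save(nib.Nifti1Image(np.asarray(data.T), affine), str(path))
    else:
        raise ValueError(f"unsupported image format: {path.suffix}")
    meta = {"spacing_mm": list(img.spacing), "shape": list(data.shape)}
    if isinstance(img, ImageGrid):
        meta["modality"] = img.modality
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta, indent=2))


def read_image(path, modality: str = "CT_like") -> ImageGrid:
    """Read a TIFF or NIfTI image; spacing from the JSON sidecar when present."""
    path = Path(path)
    sidecar = path.with_suffix(path.suffix + ".json")
    spacing = None
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        spacing = meta.get("spacing_mm")
        modality = meta.get("modality", modality)
    if path.suffix in (".tif", ".tiff"):
        data = np.asarray(tifffile.imread(path), dtype=float)
    elif path.name.endswith((".nii", ".nii.gz")):
        import nibabel as nib
        nii = nib.load(str(path))
        data = np.asarray(nii.get_fdata(), dtype=float).T
        if spacing is None:
            spacing = list(nii.header.get_zooms()[::-1])
    else:
        raise ValueError(f"unsupported image format: {path.suffix}")
    if spacing is None:
        spacing = [1.0] * data.ndim
    return ImageGrid(data, tuple(spacing), modality)
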