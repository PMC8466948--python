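"""Aperture-map morphometry: BVF, Tb.Th, Tb.Sp, Tb.N from a binary mask.

The aperture map assigns to every pixel of a phase (solid bone or marrow
void) the diameter, in mm, of the largest disk fully contained in that phase
which covers the pixel — a 2D local-thickness map with sub-pixel values.
Mean solid-phase aperture is the trabecular thickness Tb.Th, mean void-phase
aperture the trabecular spacing Tb.Sp, and Tb.N = BVF / Tb.Th.

Discrete convention
-------------------
Distances are measured between pixel centers; the maximal inscribed disk
centered on a phase pixel ``c`` reaches the midpoint between the last phase
pixel and the first background pixel, so its diameter is
``2·EDT(c) − spacing``.  A pixel ``p`` counts as contained in that disk when
its center lies within ``EDT(c)`` of ``c`` — half a pixel beyond the disk
edge, i.e. when the pixel's own footprint touches the disk.  With this
convention a band of integer pixel width w has aperture exactly w pixels
everywhere, a rasterized disk of radius R px has aperture 2R ± 1 px on every
solid pixel, and the invariant ``aperture(p) >= 2·EDT(p) − spacing`` holds
(take ``c = p``).
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import ndimage

from .grids import BinaryMask

__all__ = ["ApertureMap", "MorphoSummary", "distance_map", "aperture_map",
           "compute_morphometry"]


@dataclasses.dataclass(frozen=True)
class ApertureMap:
    """Per-pixel maximal-inscribed-disk diameters (mm) over one phase."""

    diameters: np.ndarray  # mm; 0 outside the phase
    phase: str             # "solid" or "void"
    spacing: float         # mm/pixel, isotropic


@dataclasses.dataclass(frozen=True)
class MorphoSummary:
    """Standard 2D trabecular morphometry for one ROI."""

    BVF: float
    Tb_Th: float   # mm
    Tb_Sp: float   # mm
    Tb_N: float    # 1/mm
    n_solid: int
    n_void: int
    roi: tuple[int, int, int, int] | None = None


def _phase_array(mask: BinaryMask, phase: str) -> np.ndarray:
    if phase == "solid":
        return mask.solid
    if phase == "void":
        return ~mask.solid
    raise ValueError(f"phase must be 'solid' or 'void', got {phase!r}")


def _iso_spacing(mask: BinaryMask) -> float:
    if len(set(mask.spacing)) != 1:
        raise ValueError("aperture morphometry requires isotropic spacing")
    return mask.spacing[0]


def distance_map(mask: BinaryMask, phase: str = "solid") -> np.ndarray:
    """Euclidean distance (mm) from each phase pixel to the nearest non-phase
    pixel center; 0 outside the phase."""
    ph = _phase_array(mask, phase)
    if not ph.any():
        raise ValueError(f"{phase} phase is empty")
    return ndimage.distance_transform_edt(ph, sampling=mask.spacing)


def _edt_sq_px(phase: np.ndarray) -> np.ndarray:
    """Exact integer squared EDT in pixel units (distances between centers)."""
    d = ndimage.distance_transform_edt(phase)
    return np.rint(d * d).astype(np.int64)


def aperture_map(mask: BinaryMask, phase: str = "solid") -> ApertureMap:
    """Maximal-inscribed-disk diameter map for one phase.

    For each phase pixel ``p``::

        aperture(p) = max over phase pixels c of 2·(EDT(c) − spacing/2)
                      subject to |p − c| <= EDT(c)

    i.e. the diameter of the largest inscribed disk touching ``p``'s pixel
    footprint.  Implemented by grouping candidate centers by their (integer)
    squared EDT and painting each group with a binary dilation by the
    corresponding disk footprint, from the largest radius down.
    """
    if mask.ndim != 2:
        raise ValueError("aperture_map is 2D only")
    sp = _iso_spacing(mask)
    ph = _phase_array(mask, phase)
    if not ph.any():
        raise ValueError(f"{phase} phase is empty")
    d2 = _edt_sq_px(ph)
    out = np.zeros(ph.shape)
    # descending radius so each pixel keeps the largest covering disk
    for d2val in np.unique(d2[ph])[::-1]:
        edt = np.sqrt(float(d2val))          # center-to-background distance, px
        diam_mm = 2.0 * (edt - 0.5) * sp     # inscribed-disk diameter
        centers = ph & (d2 == d2val)
        reach = int(np.floor(edt))
        if reach > 0:
            off = np.arange(-reach, reach + 1)
            oy, ox = np.meshgrid(off, off, indexing="ij")
            footprint = np.sqrt((oy**2 + ox**2).astype(float)) <= edt
            region = ndimage.binary_dilation(centers, structure=footprint)
        else:
            region = centers
        np.maximum(out, np.where(region, diam_mm, 0.0), out=out)
    out[~ph] = 0.0
    return ApertureMap(out, phase, sp)


def compute_morphometry(mask: BinaryMask,
                        roi: tuple[int, int, int, int] | None = None) -> MorphoSummary:
    """BVF, Tb.Th, Tb.Sp, Tb.N over an ROI.

    Aperture maps are computed on the full mask (disks may extend past the
    ROI boundary and are counted as valid); the phase means are then taken
    over ROI pixels only.  ``roi`` is ``(row, col, height, width)``; default
    is the mask's own ROI or the whole grid.
    """
    if roi is None:
        roi = mask.roi
    if roi is None:
        roi = (0, 0, mask.shape[0], mask.shape[1])
    r, c, h, w = roi
    window = np.s_[r:r + h, c:c + w]
    solid_roi = mask.solid[window]
    n_solid = int(solid_roi.sum())
    n_void = int(solid_roi.size - n_solid)
    if n_solid == 0 or n_void == 0:
        raise ValueError("ROI must contain both bone and marrow pixels")
    ap_solid = aperture_map(mask, "solid").diameters[window]
    ap_void = aperture_map(mask, "void").diameters[window]
    bvf = n_solid / solid_roi.size
    tb_th = float(ap_solid[solid_roi].mean())
    tb_sp = float(ap_void[~solid_roi].mean())
    return MorphoSummary(BVF=bvf, Tb_Th=tb_th, Tb_Sp=tb_sp,
                         Tb_N=bvf / tb_th, n_solid=n_solid, n_void=n_void,
                         roi=roi)
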