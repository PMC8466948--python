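"""Binarization of trabecular images.

MR-like images (bone dark, marrow bright, non-uniform background) are
thresholded with the Sauvola local method; CT-like images (high contrast)
with a single global threshold.  The output is always a solid=bone
:class:`~trabmorph.grids.BinaryMask`.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu

from .grids import BinaryMask, ImageGrid

__all__ = ["sauvola_binarize", "global_binarize"]


def _local_mean_sd(values: np.ndarray, window: int):
    """Local mean and SD over a square window (even sizes allowed)."""
    m = ndimage.uniform_filter(values, size=window, mode="nearest")
    m2 = ndimage.uniform_filter(values**2, size=window, mode="nearest")
    var = np.clip(m2 - m**2, 0.0, None)
    return m, np.sqrt(var)


def _bright_bone(img: ImageGrid) -> np.ndarray:
    """Intensities with bone as the bright phase (MR-like images inverted)."""
    vals = img.values
    if img.modality == "MR_like":
        vals = (vals.max() + vals.min()) - vals
    return vals


def sauvola_binarize(img: ImageGrid, window_px: int = 10, k: float = 0.2,
                     r_dynamic: float | None = None) -> BinaryMask:
    """Sauvola local thresholding (bone = solid).

    The per-pixel threshold is ``T = m * (1 + k * (s / r - 1))`` with ``m``
    and ``s`` the local mean and standard deviation over a
    ``window_px x window_px`` neighbourhood and ``r`` the dynamic range
    normalizer (default: half the image intensity range, per the original
    formulation).  The method was formulated for a *dark* foreground on a
    bright background, so the threshold is applied on the bone-dark
    representation (CT-like images are contrast inverted first; MR-like
    images already have dark bone): a pixel is solid iff its intensity is
    <= T there.  This keeps the degenerate flat-window case on the correct
    side: a zero-variance window ties (``T = m`` at ``k = 0``) and resolves
    to solid, which can only occur inside wide bone, never in bright
    marrow (there ``T = m·(1−k) < m`` strictly).  A constant image with
    ``k = 0`` is therefore deterministically all-solid.  3D stacks are
    thresholded slice-wise with 2D windows.
    """
    if window_px < 3:
        raise ValueError("window_px must be >= 3")
    if img.ndim == 3:
        planes = [
            sauvola_binarize(img.slice2d(i), window_px, k, r_dynamic).solid
            for i in range(img.shape[0])
        ]
        return BinaryMask(np.stack(planes), img.spacing)
    vals = img.values
    if img.modality == "CT_like":  # bone bright -> flip to dark foreground
        vals = (vals.max() + vals.min()) - vals
    if r_dynamic is None:
        r_dynamic = (vals.max() - vals.min()) / 2.0
    if r_dynamic <= 0:
        r_dynamic = 1.0  # constant image: any positive normalizer gives s/r = 0
    m, s = _local_mean_sd(vals, window_px)
    threshold = m * (1.0 + k * (s / r_dynamic - 1.0))
    return BinaryMask(vals <= threshold, img.spacing)


def global_binarize(img: ImageGrid, method: str = "otsu",
                    threshold: float | None = None) -> BinaryMask:
    """Single global threshold (bone = bright phase after MR inversion).

    ``method`` is ``"otsu"`` or ``"fixed"``; the latter requires
    ``threshold`` and marks solid where intensity >= threshold.
    """
    vals = _bright_bone(img)
    if method == "otsu":
        if np.ptp(vals) == 0:
            raise ValueError("cannot Otsu-threshold a constant image")
        t = threshold_otsu(vals)
        return BinaryMask(vals > t, img.spacing)
    if method == "fixed":
        if threshold is None:
            raise ValueError("fixed method requires a threshold")
        return BinaryMask(vals >= threshold, img.spacing)
    raise ValueError(f"unknown method {method!r}")
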