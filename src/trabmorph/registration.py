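"""Slice-to-stack multimodal registration and its quality metrics.

An MR-like slice is upscaled to the reference (CT-like) grid, affinely
registered against each candidate slice of a CT stack with a mutual-
information metric, and scored with normalized cross-correlation (NCC); the
best-scoring candidate is the registered slice.  Stack-level quality is
summarised by ΔIm — the number of reference slices strictly between two
consecutive best-registered slices — compared against the geometry-expected
value expΔIm.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import SimpleITK as sitk
from scipy import ndimage
from skimage.transform import resize

from .grids import ImageGrid

__all__ = [
    "SequenceGeometry", "RegistrationReport", "StackQuality",
    "SEQUENCE_GEOMETRIES", "upscale_to_reference", "ncc_score",
    "register_affine_multimodal", "find_best_slice", "expected_delta_im",
    "delta_im_series",
]


@dataclasses.dataclass(frozen=True)
class SequenceGeometry:
    """Acquisition geometry of one MR sequence relative to the CT reference."""

    slice_thickness_mm: float
    slice_gap_mm: float
    inplane_spacing_mm: float
    ref_slice_thickness_mm: float = 0.05

    def __post_init__(self):
        for f in dataclasses.fields(self):
            if getattr(self, f.name) <= 0:
                raise ValueError(f"{f.name} must be > 0")


#: Published acquisition geometries (slice gap equals slice thickness; the
#: reference micro-CT slice thickness is 0.05 mm).
SEQUENCE_GEOMETRIES = {
    "7T_TSE": SequenceGeometry(1.5, 1.5, 0.13),
    "7T_GRE": SequenceGeometry(1.0, 1.0, 0.18),
    "3T_TSE": SequenceGeometry(1.1, 1.1, 0.21),
    "3T_GRE": SequenceGeometry(1.1, 1.1, 0.23),
}


@dataclasses.dataclass
class RegistrationReport:
    """Best-matching stack slice for one MR slice, with the NCC profile."""

    best_index: int
    ncc: float
    transform: tuple[float, ...]     # 2D affine: A (row-major, 4) + t (2)
    ncc_profile: np.ndarray
    candidate_indices: np.ndarray
    n_reg: int
    converged: bool = True


@dataclasses.dataclass
class StackQuality:
    """ΔIm statistics across consecutive registered slices."""

    delta_im_mean: float
    delta_im_sd: float
    exp_delta_im: int | None = None
    gaps: tuple[int, ...] = ()


def upscale_to_reference(mr: ImageGrid, ref_shape: tuple[int, int]) -> ImageGrid:
    """Bilinear upscaling of an MR slice onto the reference matrix size.

    Intensities stay within the input range (bilinear interpolation does not
    extrapolate).  Spacing is rescaled by the shape ratio per axis.
    """
    if mr.ndim != 2:
        raise ValueError("upscale_to_reference expects a 2D image")
    if any(r < m for r, m in zip(ref_shape, mr.shape)):
        raise ValueError(f"reference shape {ref_shape} smaller than image "
                         f"{mr.shape}")
    out = resize(mr.values, ref_shape, order=1, anti_aliasing=False,
                 preserve_range=True, mode="edge")
    new_spacing = tuple(s * m / r for s, m, r in
                        zip(mr.spacing, mr.shape, ref_shape))
    return ImageGrid(out, new_spacing, mr.modality)


def ncc_score(a: ImageGrid | np.ndarray, b: ImageGrid | np.ndarray) -> float:
    """Zero-lag normalized cross-correlation (Pearson form), in [-1, 1]."""
    av = a.values if isinstance(a, ImageGrid) else np.asarray(a, dtype=float)
    bv = b.values if isinstance(b, ImageGrid) else np.asarray(b, dtype=float)
    if av.shape != bv.shape:
        raise ValueError(f"shape mismatch: {av.shape} vs {bv.shape}")
    ac = av - av.mean()
    bc = bv - bv.mean()
    na, nb = np.linalg.norm(ac), np.linalg.norm(bc)
    if na == 0:
        raise ValueError("first image has zero variance")
    if nb == 0:
        raise ValueError("second image has zero variance")
    return float(np.clip(np.vdot(ac, bc) / (na * nb), -1.0, 1.0))


def _to_sitk(img: ImageGrid) -> sitk.Image:
    out = sitk.GetImageFromArray(img.values.astype(np.float64))
    out.SetSpacing(tuple(float(s) for s in img.spacing[::-1]))
    return out


def _gradient_magnitude(values: np.ndarray, sigma: float = 1.0) -> np.ndarray:
    gr = ndimage.gaussian_filter(values, sigma, order=(1, 0), mode="nearest")
    gc = ndimage.gaussian_filter(values, sigma, order=(0, 1), mode="nearest")
    return np.hypot(gr, gc)


def register_affine_multimodal(moving: ImageGrid, fixed: ImageGrid,
                               bins: int = 32, max_iterations: int = 200):
    """Affine registration with a Mattes mutual-information metric.

    Two deterministic stages: the translation is first initialized by phase
    correlation between the Gaussian gradient-magnitude images (gradient
    magnitude is insensitive to contrast inversion, so the init works across
    modalities), then a full 2D affine transform is refined by regular-step
    gradient descent on the mutual-information metric evaluated over all
    pixels — the standard similarity for cross-modality intensity
    registration.  On optimizer failure the initial transform is returned
    with ``converged=False``.

    Returns ``(report, warped)`` where ``report`` is a
    :class:`RegistrationReport` with ``best_index=-1`` (unset) and
    ``warped`` is the moving image resampled onto the fixed grid.
    """
    if moving.ndim != 2 or fixed.ndim != 2:
        raise ValueError("2D images required")
    from skimage.registration import phase_cross_correlation

    shift_px, _, _ = phase_cross_correlation(
        _gradient_magnitude(fixed.values), _gradient_magnitude(moving.values),
        upsample_factor=10, normalization="phase")
    f, m = _to_sitk(fixed), _to_sitk(moving)
    sy, sx = fixed.spacing
    init = sitk.AffineTransform(2)
    init.SetCenter((fixed.shape[1] / 2 * sx, fixed.shape[0] / 2 * sy))
    # phase correlation returns the (row, col) shift that aligns moving to
    # fixed; the resampling transform maps fixed points to moving points,
    # i.e. the negative of that shift
    init.SetTranslation((-float(shift_px[1]) * sx, -float(shift_px[0]) * sy))
    reg = sitk.ImageRegistrationMethod()
    reg.SetMetricAsMattesMutualInformation(numberOfHistogramBins=bins)
    reg.SetMetricSamplingStrategy(reg.NONE)
    reg.SetInterpolator(sitk.sitkLinear)
    reg.SetOptimizerAsRegularStepGradientDescent(
        learningRate=0.2, minStep=1e-5, numberOfIterations=max_iterations,
        relaxationFactor=0.5, gradientMagnitudeTolerance=1e-8)
    reg.SetOptimizerScalesFromPhysicalShift()
    reg.SetInitialTransform(init, inPlace=False)
    converged = True
    try:
        tf = reg.Execute(f, m)
    except RuntimeError:
        converged = False
        tf = init
    warped_img = sitk.Resample(m, f, tf, sitk.sitkLinear, float(np.min(moving.values)))
    warped = ImageGrid(sitk.GetArrayFromImage(warped_img), fixed.spacing,
                       moving.modality)
    inner = tf
    while isinstance(inner, sitk.CompositeTransform):
        inner = inner.GetNthTransform(0)
    params = tuple(inner.GetParameters())
    report = RegistrationReport(best_index=-1, ncc=np.nan, transform=params,
                                ncc_profile=np.empty(0),
                                candidate_indices=np.empty(0, dtype=int),
                                n_reg=0, converged=converged)
    return report, warped


def find_best_slice(mr: ImageGrid, stack: ImageGrid, center_index: int,
                    n_reg: int = 60, register: bool = True) -> RegistrationReport:
    """Locate the stack slice best matching an MR slice.

    A window of ``n_reg`` candidate slices centered on ``center_index``
    (clipped at the stack ends) is scanned; each candidate is affinely
    registered to the (upscaled) MR slice and scored with NCC on the warped
    pair.  The argmax wins; ties resolve to the lowest candidate index.
    ``register=False`` skips the affine step and scores raw NCC (useful when
    slices are already aligned).
    """
    if stack.ndim != 3:
        raise ValueError("stack must be 3D")
    if n_reg < 3:
        raise ValueError("candidate window must be at least 3 slices")
    n = stack.shape[0]
    lo = max(0, center_index - n_reg // 2)
    hi = min(n, lo + n_reg)
    lo = max(0, hi - n_reg)
    candidates = np.arange(lo, hi)
    ref_shape = stack.shape[1:]
    probe = mr if mr.shape == ref_shape else upscale_to_reference(mr, ref_shape)
    if probe.modality == "MR_like":
        # flip contrast so bone is bright in both images and the NCC score is
        # on the paper-style positive scale; MI registration is unaffected
        v = probe.values
        probe = ImageGrid((v.max() + v.min()) - v, probe.spacing, "CT_like")
    scores = np.empty(len(candidates))
    identity = (1.0, 0.0, 0.0, 1.0, 0.0, 0.0)
    transforms: list[tuple[float, ...]] = []
    convergences: list[bool] = []
    for i, k in enumerate(candidates):
        fixed = stack.slice2d(int(k))
        if register:
            rep, warped = register_affine_multimodal(probe, fixed)
            transforms.append(rep.transform)
            convergences.append(rep.converged)
        else:
            warped = probe
            transforms.append(identity)
            convergences.append(True)
        scores[i] = ncc_score(warped, fixed)
    best = int(np.argmax(scores))  # argmax takes the first (lowest) on ties
    best_tf, best_conv = transforms[best], convergences[best]
    return RegistrationReport(best_index=int(candidates[best]),
                              ncc=float(scores[best]), transform=best_tf,
                              ncc_profile=scores, candidate_indices=candidates,
                              n_reg=len(candidates), converged=best_conv)


def expected_delta_im(g: SequenceGeometry) -> int:
    """Geometry-expected ΔIm: reference slices strictly *between* consecutive
    MR slice positions.

    The MR slice period is ``slice_thickness + slice_gap``; dividing by the
    reference slice thickness gives the index step between registered
    slices, and the exclusive between-count is that step minus one (e.g.
    period 3.0 mm at a 0.05 mm reference → step 60 → 59 slices in between).
    """
    period = g.slice_thickness_mm + g.slice_gap_mm
    ratio = period / g.ref_slice_thickness_mm
    if abs(ratio - round(ratio)) > 1e-6:
        raise ValueError(
            f"reference thickness {g.ref_slice_thickness_mm} does not divide "
            f"the slice period {period}")
    return int(round(ratio)) - 1


def delta_im_series(best_indices, geometry: SequenceGeometry | None = None) -> StackQuality:
    """ΔIm mean ± SD from an ordered series of best-registered indices.

    Gaps are exclusive counts (index difference − 1).  Non-monotone index
    series raise a warning and fall back to absolute differences.  The
    sample SD (ddof=1) is NaN for a single pair.
    """
    idx = np.asarray(best_indices, dtype=int)
    if idx.size < 2:
        raise ValueError("need at least 2 registered slices")
    diffs = np.diff(idx)
    if np.any(diffs < 0):
        warnings.warn("best-index series is not monotone; using absolute "
                      "differences", stacklevel=2)
        diffs = np.abs(diffs)
    gaps = diffs - 1
    sd = float(np.std(gaps, ddof=1)) if gaps.size > 1 else float("nan")
    return StackQuality(delta_im_mean=float(np.mean(gaps)), delta_im_sd=sd,
                        exp_delta_im=None if geometry is None
                        else expected_delta_im(geometry),
                        gaps=tuple(int(x) for x in gaps))
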