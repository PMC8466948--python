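"""Synthetic bone phantoms with exact analytic ground truth.

Every generator returns, alongside the image or mask, a machine-readable
ground-truth record (a plain dict) so downstream stages — segmentation,
morphometry, orientation, registration, BMD — can be validated without any
external scan data.  Phantoms are defined analytically in continuous mm
coordinates and rasterized by pixel-center sampling, so the continuous-level
truth is exact and the discretization error is bounded by one pixel per edge.

Conventions
-----------
* In-plane continuous coordinates: ``x`` along columns (mm), ``y`` along rows
  with +y pointing *up* (row 0 is the top of the image).  Pixel ``(i, j)`` has
  center ``x = (j + 0.5) * sx``, ``y = (H - i - 0.5) * sy``.
* Orientations are degrees in ``[0, 180)``, counterclockwise from +x.
* Fixed seed ⇒ bit-identical output.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import ndimage

from .grids import BinaryMask, ImageGrid

__all__ = [
    "PhantomSpec",
    "DegradationSpec",
    "make_plate_phantom",
    "make_rod_phantom",
    "make_revolution_phantom",
    "make_neck_phantom",
    "degrade_to_mri",
    "make_slice_stack",
]


@dataclasses.dataclass(frozen=True)
class PhantomSpec:
    """Geometry of a synthetic phantom.

    ``kind`` selects the generator; ``geometry`` holds kind-specific lengths
    in mm (see each generator's docstring); ``grid_shape`` is in pixels,
    ``spacing`` in mm/pixel (isotropic in-plane).
    """

    kind: str
    geometry: dict
    grid_shape: tuple[int, ...] = (256, 256)
    spacing: float = 0.05
    seed: int = 0

    def __post_init__(self):
        if self.kind not in ("plates", "rods", "disk", "annulus", "rect", "neck"):
            raise ValueError(f"unknown phantom kind {self.kind!r}")
        if self.spacing <= 0:
            raise ValueError("spacing must be > 0")
        if min(self.grid_shape) < 16:
            raise ValueError("grid_shape must be >= 16 pixels per axis")


@dataclasses.dataclass(frozen=True)
class DegradationSpec:
    """MRI-like degradation: PSF blur, downsampling, noise, inversion, bias.

    ``psf_sigma`` is the Gaussian point-spread sigma in mm;
    ``downsample_factor`` is target spacing / source spacing (>= 1);
    ``noise_sigma`` is the additive-Gaussian SD as a fraction of the dynamic
    range; ``bias_field_amplitude`` is the peak fractional modulation of a
    smooth multiplicative background field.
    """

    psf_sigma: float = 0.0
    downsample_factor: float = 1.0
    noise_sigma: float = 0.0
    invert_contrast: bool = False
    bias_field_amplitude: float = 0.0

    def __post_init__(self):
        if self.downsample_factor < 1:
            raise ValueError("downsample_factor must be >= 1")
        if self.noise_sigma < 0 or self.psf_sigma < 0:
            raise ValueError("sigmas must be >= 0")


def _pixel_centers(shape, spacing):
    """Continuous (x, y) pixel-center coordinates, y up, in mm."""
    h, w = shape
    x = (np.arange(w) + 0.5) * spacing
    y = (h - np.arange(h) - 0.5) * spacing
    return np.meshgrid(x, y)


def _require_pixels(name: str, length_mm: float, spacing: float, minimum=2):
    px = length_mm / spacing
    if px < minimum:
        raise ValueError(
            f"{name}={length_mm} mm is only {px:.2f} px at spacing "
            f"{spacing} mm; need >= {minimum} px"
        )


def make_plate_phantom(spec: PhantomSpec):
    """Periodic parallel plates: thickness ``t`` mm, gaps ``s`` mm.

    Plates run along the x (column) axis; the pattern varies along rows.
    ``geometry`` keys: ``t``, ``s``, optional ``offset`` (mm, phase of the
    pattern; default 0 aligns the first plate edge with the image top).

    Returns ``(mask, truth)`` where ``truth`` records the exact continuous
    morphometry: ``BVF = t/(t+s)``, ``Tb_Th = t``, ``Tb_Sp = s``,
    ``Tb_N = 1/(t+s)``.
    """
    if spec.kind != "plates":
        raise ValueError("spec.kind must be 'plates'")
    t = float(spec.geometry["t"])
    s = float(spec.geometry["s"])
    offset = float(spec.geometry.get("offset", 0.0))
    _require_pixels("t", t, spec.spacing)
    _require_pixels("s", s, spec.spacing)
    _, yy = _pixel_centers(spec.grid_shape, spec.spacing)
    period = t + s
    solid = ((yy - offset) % period) < t
    mask = BinaryMask(solid, (spec.spacing, spec.spacing))
    truth = {
        "BVF": t / period,
        "Tb_Th": t,
        "Tb_Sp": s,
        "Tb_N": 1.0 / period,
        "orientation_deg": 0.0,
    }
    return mask, truth


def make_rod_phantom(spec: PhantomSpec):
    """Families of parallel rods (Gaussian-profile ridges) at given angles.

    ``geometry`` keys:

    * ``angles_deg`` — list of family orientations in ``[0, 180)``;
    * ``weights`` — mixing weights per family (sum to 1); realised by making
      the line density of each family proportional to its weight;
    * ``rod_width`` — rod radius in mm (solid where the distance to the
      nearest rod centerline is <= ``rod_width``); default 0.1;
    * ``base_spacing`` — centerline spacing (mm) a weight-1 family would
      have; default 1.0.  Family *f* uses ``base_spacing / weight_f``;
    * ``envelope`` — amplitude (0..1) of a smooth radial intensity
      modulation emulating large-scale density variation across a sample;
      default 0.3.  It breaks the translational ambiguity of a perfectly
      periodic lattice (the mask and labels are unaffected).

    Returns ``(image, mask, truth)``: a grayscale ridge image (bone bright,
    in [0, 1]), the solid mask, and a truth record with a per-pixel family
    label map (``-1`` outside rods) and the angle list.
    """
    if spec.kind != "rods":
        raise ValueError("spec.kind must be 'rods'")
    angles = [float(a) for a in spec.geometry["angles_deg"]]
    weights = [float(w) for w in spec.geometry.get("weights", [1.0] * len(angles))]
    if len(angles) == 0:
        empty = np.zeros(spec.grid_shape, dtype=bool)
        img = ImageGrid(np.zeros(spec.grid_shape), (spec.spacing,) * 2)
        truth = {"angles_deg": [], "weights": [], "labels": np.full(spec.grid_shape, -1)}
        return img, BinaryMask(empty, (spec.spacing,) * 2), truth
    if any(a < 0 or a >= 180 for a in angles):
        raise ValueError(f"angles must lie in [0, 180), got {angles}")
    if abs(sum(weights) - 1.0) > 1e-9 or any(w <= 0 for w in weights):
        raise ValueError("weights must be positive and sum to 1")
    rod_width = float(spec.geometry.get("rod_width", 0.1))
    base_spacing = float(spec.geometry.get("base_spacing", 1.0))
    envelope = float(spec.geometry.get("envelope", 0.3))
    _require_pixels("rod_width", rod_width, spec.spacing, minimum=1)

    rng = np.random.default_rng(spec.seed)
    xx, yy = _pixel_centers(spec.grid_shape, spec.spacing)
    profile_sigma = rod_width / 1.5  # Gaussian cross-section sigma
    family_response = np.zeros((len(angles),) + tuple(spec.grid_shape))
    family_dist = np.empty_like(family_response)
    for f, (ang, w) in enumerate(zip(angles, weights)):
        theta = np.deg2rad(ang)
        # signed distance coordinate along the family normal
        p = -np.sin(theta) * xx + np.cos(theta) * yy
        line_spacing = base_spacing / w
        phase = rng.uniform(0, line_spacing)
        d = np.abs((p - phase + line_spacing / 2) % line_spacing - line_spacing / 2)
        resp = np.exp(-0.5 * (d / profile_sigma) ** 2)
        resp[d > 3 * rod_width] = 0.0
        family_response[f] = resp
        family_dist[f] = d
    intensity = family_response.max(axis=0)
    solid = family_dist.min(axis=0) <= rod_width
    labels = np.where(solid, np.argmin(family_dist, axis=0), -1)
    if envelope > 0:
        cx = xx.mean() + 0.15 * np.ptp(xx)
        cy = yy.mean() - 0.1 * np.ptp(yy)
        span = max(np.ptp(xx), np.ptp(yy))
        env = np.exp(-(((xx - cx) ** 2 + (yy - cy) ** 2) / (2 * (0.45 * span) ** 2)))
        intensity = intensity * ((1.0 - envelope) + envelope * env)
    img = ImageGrid(intensity, (spec.spacing, spec.spacing))
    mask = BinaryMask(solid, (spec.spacing, spec.spacing))
    truth = {"angles_deg": angles, "weights": weights, "labels": labels}
    return img, mask, truth


def make_revolution_phantom(spec: PhantomSpec):
    """Axis-symmetric 2D mask with the closed-form volume of its 180° revolution.

    The rotation axis is vertical, located on a pixel *boundary* at continuous
    x = ``axis_px * spacing`` (``axis_px`` integer, default the middle
    column boundary), so every pixel lies wholly on one side of the axis.

    Kinds and ``geometry`` keys:

    * ``disk`` — radius ``rho`` mm, centered on the axis.  Revolved 180°
      it sweeps a full sphere: ``V = (4/3) π rho³``.
    * ``annulus`` — radii ``rho_inner < rho_outer``, centered on the axis.
      ``V = (4/3) π (rho_outer³ − rho_inner³)``.
    * ``rect`` — one-sided axial rectangle spanning radii ``[a, b]`` mm at
      height ``h`` mm (half-ring): ``V = π (b² − a²) h / 2``.

    Returns ``(mask, truth)`` with ``truth['V_mm3']`` the analytic volume and
    ``truth['axis_px']`` the axis position in pixel units.
    """
    sp = spec.spacing
    h_px, w_px = spec.grid_shape
    axis_px = int(spec.geometry.get("axis_px", w_px // 2))
    if not 0 <= axis_px <= w_px:
        raise ValueError("axis must lie inside the image")
    xx, yy = _pixel_centers(spec.grid_shape, sp)
    ax = axis_px * sp
    yc = (h_px / 2) * sp
    r_from_axis = np.abs(xx - ax)

    if spec.kind == "disk":
        rho = float(spec.geometry["rho"])
        _require_pixels("rho", rho, sp, minimum=3)
        if rho > min(ax, w_px * sp - ax, yc):
            raise ValueError(f"rho={rho} mm does not fit the grid")
        solid = (xx - ax) ** 2 + (yy - yc) ** 2 <= rho**2
        volume = 4.0 / 3.0 * np.pi * rho**3
    elif spec.kind == "annulus":
        ri = float(spec.geometry["rho_inner"])
        ro = float(spec.geometry["rho_outer"])
        _require_pixels("rho_inner", ri, sp, minimum=3)
        if ro <= ri:
            raise ValueError("rho_outer must exceed rho_inner")
        if ro > min(ax, w_px * sp - ax, yc):
            raise ValueError(f"rho_outer={ro} mm does not fit the grid")
        rr = (xx - ax) ** 2 + (yy - yc) ** 2
        solid = (rr <= ro**2) & (rr > ri**2)
        volume = 4.0 / 3.0 * np.pi * (ro**3 - ri**3)
    elif spec.kind == "rect":
        a = float(spec.geometry["a"])
        b = float(spec.geometry["b"])
        hh = float(spec.geometry["h"])
        if not 0 <= a < b:
            raise ValueError("need 0 <= a < b")
        if b > w_px * sp - ax or hh > h_px * sp:
            raise ValueError("rectangle does not fit the grid")
        solid = (
            (xx - ax >= a) & (xx - ax <= b)
            & (np.abs(yy - yc) <= hh / 2)
        )
        volume = np.pi * (b**2 - a**2) * hh / 2.0
    else:
        raise ValueError("spec.kind must be disk, annulus or rect")
    mask = BinaryMask(solid, (sp, sp))
    truth = {"V_mm3": float(volume), "axis_px": float(axis_px)}
    return mask, truth


def make_neck_phantom(spec: PhantomSpec):
    """Revolution-symmetric 3D "femoral neck" stand-in: a voxelized ball.

    Synthetic construct: a solid sphere of radius ``rho`` mm on an isotropic
    voxel grid.  Its central coronal slice is a disk of the same radius, so
    the 3D volumetric route and the 2D ring-revolution route target the same
    analytic volume ``(4/3) π rho³`` — the fixture for comparing areal BMD
    computed both ways.

    ``grid_shape`` must be 3D.  Returns ``(mask3d, truth)`` with the analytic
    volume, the central slice index, and the axis position in pixel units.
    """
    if spec.kind != "neck":
        raise ValueError("spec.kind must be 'neck'")
    if len(spec.grid_shape) != 3:
        raise ValueError("neck phantom needs a 3D grid_shape")
    rho = float(spec.geometry["rho"])
    sp = spec.spacing
    _require_pixels("rho", rho, sp, minimum=3)
    nz, ny, nx = spec.grid_shape
    axis_px = nx // 2
    z = (np.arange(nz) + 0.5) * sp - (nz / 2) * sp
    y = (np.arange(ny) + 0.5) * sp - (ny / 2) * sp
    x = (np.arange(nx) + 0.5) * sp - axis_px * sp
    zz, yy, xx = np.meshgrid(z, y, x, indexing="ij")
    if rho > min(abs(z[0]), abs(z[-1]), abs(y[0]), abs(y[-1]), abs(x[0]), abs(x[-1])):
        raise ValueError(f"rho={rho} mm does not fit the grid")
    solid = xx**2 + yy**2 + zz**2 <= rho**2
    # central coronal plane: the slice (axis 0) with the largest bone area
    central = int(np.argmax(solid.sum(axis=(1, 2))))
    truth = {"V_mm3": 4.0 / 3.0 * np.pi * rho**3, "central_slice": central,
             "axis_px": float(axis_px), "rho": rho}
    return BinaryMask(solid, (sp, sp, sp)), truth


def _bias_field(shape, amplitude, rng):
    """Smooth multiplicative field in [1-a, 1+a]: random low-order cosine mix."""
    h, w = shape
    ii, jj = np.meshgrid(np.linspace(0, 1, h), np.linspace(0, 1, w), indexing="ij")
    phase = rng.uniform(0, 2 * np.pi, size=3)
    raw = (np.cos(2 * np.pi * ii + phase[0])
           + np.cos(2 * np.pi * jj + phase[1])
           + np.cos(2 * np.pi * (ii + jj) / 2 + phase[2]))
    raw = raw / np.max(np.abs(raw))
    return 1.0 + amplitude * raw


def degrade_to_mri(img: ImageGrid, d: DegradationSpec, seed: int = 0) -> ImageGrid:
    """Turn a high-resolution CT-like image into an MRI-like one.

    Applies, in order: Gaussian PSF blur (partial-volume emulation),
    downsampling to coarser spacing, smooth multiplicative bias field,
    contrast inversion (bone dark, as in marrow-bright MR sequences), and
    additive Gaussian noise.  An all-identity spec returns the input values
    unchanged.  Deterministic under a fixed ``seed``.
    """
    if img.ndim != 2:
        raise ValueError("degrade_to_mri operates on 2D slices")
    rng = np.random.default_rng(seed)
    vals = img.values
    spacing = img.spacing
    if d.psf_sigma > 0:
        sigma_px = [d.psf_sigma / s for s in spacing]
        vals = ndimage.gaussian_filter(vals, sigma_px, mode="nearest")
    if d.downsample_factor > 1:
        f = d.downsample_factor
        vals = ndimage.zoom(vals, 1.0 / f, order=1, mode="nearest", grid_mode=True)
        spacing = tuple(s * f for s in spacing)
    if d.bias_field_amplitude > 0:
        vals = vals * _bias_field(vals.shape, d.bias_field_amplitude, rng)
    lo, hi = float(vals.min()), float(vals.max())
    if d.invert_contrast:
        vals = (hi + lo) - vals
    if d.noise_sigma > 0:
        vals = vals + rng.normal(0.0, d.noise_sigma * max(hi - lo, 1e-12), vals.shape)
    modality = "MR_like" if d.invert_contrast else img.modality
    return ImageGrid(vals, spacing, modality)


def make_slice_stack(base: ImageGrid, n_slices: int, slice_spacing_mm: float,
                     inplane_jitter: float = 0.0, seed: int = 0,
                     warp_px_per_mm: float = 6.0,
                     drift_shift_px_per_mm: float = 0.5) -> ImageGrid:
    """Stack of consecutive slices morphing smoothly away from ``base``.

    Slice ``k`` is the base image deformed by a smooth low-frequency
    displacement field whose amplitude grows linearly with the axial
    position ``k * slice_spacing_mm`` (``warp_px_per_mm`` px of peak
    displacement per mm), plus a small translational drift and an optional
    random in-plane jitter of SD ``inplane_jitter`` px per slice.  The warp
    is deliberately *non-affine*: anatomy changes structurally through a
    stack, so even after affine registration nearby slices must resemble
    each other more than distant ones — the property slice-finding
    registration relies on.
    """
    if n_slices < 3:
        raise ValueError("need at least 3 slices")
    if base.ndim != 2:
        raise ValueError("base must be a 2D image")
    rng = np.random.default_rng(seed)
    h, w = base.shape
    rows, cols = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")
    # unit displacement field: a couple of low-frequency modes, O(1) px peak
    ph = rng.uniform(0, 2 * np.pi, size=4)
    u = np.linspace(0, 2 * np.pi, h)[:, None] * 1.5
    v = np.linspace(0, 2 * np.pi, w)[None, :] * 1.5
    d_row = 0.6 * np.sin(u + ph[0]) * np.cos(v + ph[1]) \
        + 0.4 * np.cos(0.5 * u + ph[2]) * np.sin(1.5 * v + ph[3])
    d_col = 0.6 * np.cos(1.5 * u + ph[1]) * np.sin(v + ph[2]) \
        + 0.4 * np.sin(0.5 * u + ph[3]) * np.cos(0.5 * v + ph[0])
    slices = np.empty((n_slices,) + base.shape)
    for k in range(n_slices):
        zpos = k * slice_spacing_mm
        amp = warp_px_per_mm * zpos
        shift = drift_shift_px_per_mm * zpos
        jit = rng.normal(0.0, inplane_jitter, size=2) if inplane_jitter > 0 \
            else np.zeros(2)
        coords = np.stack([
            rows - amp * d_row - shift - jit[0],
            cols - amp * d_col - 0.5 * shift - jit[1],
        ])
        slices[k] = ndimage.map_coordinates(base.values, coords, order=1,
                                            mode="nearest")
    return ImageGrid(slices, (slice_spacing_mm,) + tuple(base.spacing),
                     base.modality)
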