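# Methods

This note records the models, numeric conventions and design choices behind
trabmorph, in the spirit of a methods appendix: what each stage assumes,
which knobs matter, and what the synthetic validation does and does not
establish about real scan data.

## Coordinate and orientation conventions

Arrays are numpy-ordered: `(row, col)` in 2D, `(slice, row, col)` in 3D,
with physical spacing in mm per axis. Continuous in-plane coordinates put
`x` along columns and `y` along rows pointing *up* (row 0 is the top of the
image). All orientations are degrees in `[0°, 180°)`, measured
counterclockwise from +x. This single convention is used by the phantom
generators, the Hessian orientation estimator and the orientation
statistics, and is pinned by the rotation-equivariance test.

## Synthetic phantoms

No public scan pairs exist for the multimodal femur protocol this package
addresses, so every stage is validated on phantoms with exact continuous
ground truth, rasterized by pixel-center sampling (discretization error at
most one pixel per edge).

- **Plates**: periodic parallel bands of thickness `t` and gap `s`;
  truth BVF = t/(t+s), Tb.Th = t, Tb.Sp = s, Tb.N = 1/(t+s). The default
  study condition is t = 0.25 mm, s = 0.75 mm at 0.05 mm spacing — the
  scale of the cadaveric femoral trabecular values the method targets
  (BVF ≈ 0.23–0.25, Tb.Th ≈ 0.25 mm).
- **Rods**: families of parallel Gaussian-profile ridges at stated angles;
  mixing weights are realised as line densities, so the solid-pixel share
  per family equals its weight. A smooth radial intensity envelope
  (default amplitude 0.3) emulates large-scale density variation across a
  sample; without it a perfectly periodic lattice makes in-plane
  registration translationally ambiguous. The default bimodal condition is
  67°/157° with weights 0.7/0.3 — principal/secondary orientations roughly
  90° apart, as in femoral-head trabecular groups.
- **Slice stacks**: slice k is the base image deformed by a smooth
  low-frequency displacement field whose amplitude grows with axial
  position (default 6 px/mm), plus small translational drift and optional
  jitter. The warp is deliberately non-affine: affine drift would be
  fully compensated by the affine registration step and every candidate
  slice would score identically.
- **MR-like degradation**: Gaussian PSF blur (partial volume), linear
  downsampling to coarser spacing, smooth multiplicative bias field,
  contrast inversion (bone dark), additive Gaussian noise. Gaussian rather
  than Rician noise: magnitude-MR statistics are out of scope and none of
  the validated properties depend on the noise tail. Default degradation
  (blur σ 0.08 mm, factor 2.6 → 0.13 mm pixels, noise 2%, bias ±15%)
  mirrors the 7T TSE acquisition scale.
- **Revolution/neck phantoms**: axis-symmetric 2D masks (disk, annulus,
  one-sided rectangle) with closed-form 180°-revolution volumes
  ((4/3)πρ³; π(b²−a²)h/2), and a voxelized ball as the 3D
  revolution-symmetric "neck" stand-in (synthetic — not anatomical femur
  geometry).

What phantom validation does *not* show: robustness to marrow-fat
heterogeneity, susceptibility artifacts, cortical-shell partial volume, or
anatomically curved trabecular networks. Passing tests bound algorithmic
error, not acquisition physics.

## Segmentation

Sauvola thresholding uses `T = m·(1 + k·(s/r − 1))` with a 10×10 px window,
`k = 0.2` and `r` = half the intensity range (the original formulation's
defaults; the window size is the one fixed study parameter). The method was
designed for a dark foreground on a bright background, so the threshold is
applied on the bone-dark representation (CT-like images are inverted
first; MR-like images already are), with solid ⇔ intensity ≤ T. This
placement decides the degenerate flat-window tie deterministically and
correctly: in a zero-variance window T = m·(1−k) < m strictly whenever the
local mean is positive, so bright flat marrow can never tie into bone,
while wide flat bone (only reachable at k = 0, T = m) ties solid. 3D
stacks are thresholded slice-wise (the analysis is 2D throughout).
CT-like images use Otsu or a fixed threshold; contrast is assumed high.

## Aperture-map morphometry

The aperture map is a 2D local-thickness transform: for each phase pixel,
the diameter of the largest disk fully contained in the phase that covers
it. Discrete definition, with EDT the Euclidean distance between pixel
centers:

- the maximal inscribed disk centered at phase pixel `c` has diameter
  `2·EDT(c) − spacing` (it reaches the midpoint between the last phase
  pixel and the first background pixel);
- pixel `p` counts as covered when `|p − c| ≤ EDT(c)`, i.e. when its
  footprint touches the disk.

This pair of rules makes integer-width bands exact (a 5 px plate has
aperture exactly 5 px everywhere), keeps every solid pixel of a rasterized
disk of radius R within 1 px of 2R, and guarantees the lower bound
`aperture(p) ≥ 2·EDT(p) − spacing`. Squared distances are held as exact
integers so the implementation and the brute-force enumeration oracle agree
to machine precision. Tb.Th/Tb.Sp are arithmetic (area-weighted) means of
the aperture distribution over ROI pixels of the respective phase; disks
may extend past the ROI boundary (no border correction), and Tb.Sp counts
only void pixels inside the ROI. ROIs for periodic phantoms should span
whole periods and stay one structure period away from open image edges,
where the distance transform sees no bounding phase.

## Registration

The moving MR slice is upscaled to the reference matrix with bilinear
interpolation (no extrapolation beyond the input range), contrast-aligned
(bone bright) for scoring, and registered to each candidate stack slice
with a 2D affine transform. The similarity that is optimized is Mattes
mutual information (32 bins, all pixels, no stochastic sampling —
deterministic), the standard choice for cross-modality intensity
registration. Because MI on quasi-periodic trabecular texture has a
narrow global basin flanked by lattice-shifted local optima, the
translation is initialized by phase correlation between Gaussian
gradient-magnitude images (gradient magnitude is insensitive to contrast
inversion), and the affine refinement uses a conservative regular-step
gradient descent (initial step 0.2, min step 1e-5, ≤200 iterations). On
optimizer failure the initial transform is returned and flagged.

Candidates are scored with zero-lag Pearson NCC after warping; the argmax
wins, ties resolving to the lowest index. ΔIm is the exclusive gap between
consecutive best indices (index difference − 1), reported mean ± sample SD;
expΔIm = round(period / reference thickness) − 1. The exclusive count is
used because the published per-sequence values (59/39/43) equal the period
ratio minus one.

## Orientation statistics

For each scale σ ∈ {1,…,5} px (pixels, not mm), the 2×2 Hessian of the
Gaussian-smoothed image is computed with σ²-normalized responses so scales
are comparable; the image mean is subtracted first because truncated
derivative kernels do not sum exactly to zero. Per pixel, the winning scale
maximizes the dominant (largest-magnitude) eigenvalue; the dominant
eigenvector points *across* a ridge, so the structure orientation is its
perpendicular, folded to [0°, 180°). Pixels whose best response is below
1e-8 of the intensity range are invalid (a constant image has no valid
pixels).

The orientation histogram over valid solid pixels (default 1° bins;
2° in the demo pipeline, where slices are small) is fitted by nonlinear
least squares with the six-parameter model `a + m·x + N(μ₁,σ₁) + N(μ₂,σ₂)`,
whose Gaussian components have unit area by construction. Two consequences:
a histogram normalized to unit area is matched with a negative baseline
(a ≈ −1/180 of the surplus component mass), and parameter-recovery
validation feeds curves sampled exactly from the model. Gaussians are
evaluated periodically (images at ±180°) so peaks near 0°/180° are not
split. Fits start from the two highest separated local maxima of the
smoothed histogram plus seeded jittered restarts; lowest SSE wins; the
principal component is the one with the taller peak 1/(σ√2π). Tb.Int is
the density-weighted RMS deviation about μ₁ (not about the distribution
mean), which gives the closed forms 0 for a point mass, Δ/√3 for a uniform
band of half-width Δ, and d·√w for a two-point distribution.

## BMD

ρ defaults to 1.2 g/cm³ (porosity-adjusted bone density, carried in
reports with its conventional "g Ca/cm³" unit string). The 2D route
revolves each bone pixel 180° about a vertical axis placed on a pixel
boundary; per-pixel ring radii are the pixel's edge distances from the
axis, so the ring areas telescope exactly along contiguous rows and
nothing is double-counted; pixels straddling a non-integer axis are split
at the axis. The half-turn factor π/2 reflects that a coronal section
already exposes both the superior and inferior cortical profiles, so a
full 2π sweep of the one-sided profile would double-count them; a
full-turn variant is available (`full_turn=True`) for sensitivity
analysis. Areal normalization uses the bone-pixel area of the central
coronal plane (3D) or of the slice itself (2D), not the ROI box area. VOI
and axis placement are explicit inputs (auto axis = bone centroid column);
nothing anatomical is inferred.

## Agreement statistics

ANOVA is the classic one-way F-test (modality as factor), significant at
p < 0.01; the degenerate zero-within-variance case maps to p = 0 or 1 by
the means. Regression is OLS with R² = squared Pearson r. Bland–Altman
uses d = other − reference, bias ± 1.96·sample SD, percent bias relative
to the reference mean. The ICC is the two-way absolute-agreement
single-measure form ICC(A,1), computed from explicit ANOVA mean squares
(cross-checked against pingouin in the tests); consistency `C,1` and
average-measure `A,k` forms are available. The source the study protocol
cites for its ICC does not pin the estimator; absolute agreement matches
the cross-modality use and is documented here as this package's choice.
Classes: low < 0.5 ≤ good < 0.75 ≤ excellent, boundaries assigned upward.

## Demo pipeline sizes

The end-to-end demo uses a 160² px bimodal rod phantom at 0.05 mm, a
36-slice CT-like stack, three MR-like slices at a 0.6 mm period (expΔIm
11) and an 11-slice registration window — sizes chosen so a full seeded
study, including ~30 affine registrations, completes in well under a
minute on one CPU while every stage still has hundreds of structures to
measure. All sizes are config fields; scaling them up changes runtime, not
code paths.

## Known limitations

- Strictly 2D morphometry and orientation (disks and in-plane Hessians);
  no 3D local thickness, fabric tensors or mean-intercept-length
  anisotropy.
- The two-Gaussian model inherits the printed unit-area constraint; it
  describes peak positions and widths well but its baseline is a fitting
  device, not a density estimate.
- Registration is 2D affine slice-to-slice; no deformable or
  through-plane correction.
- The revolution BMD assumes in-plane axis symmetry; strongly asymmetric
  sections bias V_app in proportion to their asymmetry.
- Phantom realism bounds what the tests certify (see the phantom section).
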