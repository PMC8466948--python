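"""End-to-end demo pipeline: simulate → register → segment → measure → agree.

A single seeded run generates a synthetic study: a CT-like stack of a
trabecular phantom, a few MR-like slices extracted and degraded from it,
slice-to-stack registration with NCC/ΔIm quality metrics, per-slice
morphometry and orientation statistics for both modalities, BMD both ways
on a revolution-symmetric neck phantom, and a modality-agreement panel.
Outputs are CSV/JSON tables plus a markdown report; a re-run with the same
seed reproduces them byte for byte.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import agreement, bmd, morphometry, orientation, phantoms, registration
from .grids import ImageGrid
from .segmentation import global_binarize, sauvola_binarize

__all__ = ["RunConfig", "run_pipeline", "make_report", "slice_parameters"]

MORPHO_PARAMS = ["BVF", "Tb_Th", "Tb_Sp", "Tb_N", "Tb_OrP", "Tb_OrS", "Tb_Int"]


@dataclasses.dataclass
class RunConfig:
    """Configuration of one demo run (all sizes chosen for a single CPU)."""

    out_dir: str = "trabmorph_run"
    seed: int = 0
    # phantom
    grid_px: int = 160
    spacing_mm: float = 0.05
    angles_deg: tuple[float, float] = (67.0, 157.0)
    weights: tuple[float, float] = (0.7, 0.3)
    rod_width_mm: float = 0.12
    base_spacing_mm: float = 0.55
    # stack / sequence geometry
    n_ct_slices: int = 36
    mr_slice_thickness_mm: float = 0.3
    mr_slice_gap_mm: float = 0.3
    n_mr_slices: int = 3
    n_reg: int = 11
    # MR degradation
    psf_sigma_mm: float = 0.08
    downsample_factor: float = 2.6
    noise_sigma: float = 0.02
    bias_field_amplitude: float = 0.15
    # analysis
    sauvola_window_px: int = 10
    sauvola_k: float = 0.2
    roi_margin_px: int = 12
    rho_g_cm3: float = 1.2
    neck_rho_mm: float = 1.5
    # inert acquisition metadata (provenance only, not simulated)
    sequence_metadata: dict = dataclasses.field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for tup in ("angles_deg", "weights"):
            if tup in raw:
                raw[tup] = tuple(raw[tup])
        return cls(**raw)

    def mr_period_ct_slices(self) -> int:
        period = self.mr_slice_thickness_mm + self.mr_slice_gap_mm
        return int(round(period / self.spacing_mm))


def slice_parameters(img: ImageGrid, cfg: RunConfig, roi) -> dict:
    """All seven morphological parameters of one 2D slice."""
    if img.modality == "MR_like":
        mask = sauvola_binarize(img, cfg.sauvola_window_px, cfg.sauvola_k)
    else:
        mask = global_binarize(img, "otsu")
    morpho = morphometry.compute_morphometry(mask, roi)
    field = orientation.hessian_orientation(img)
    dist = orientation.orientation_distribution(field, mask, bin_width_deg=2.0)
    fit = orientation.fit_two_gaussians(dist, restarts=4, seed=cfg.seed)
    summ = orientation.summarize_orientation(fit, dist)
    return {"BVF": morpho.BVF, "Tb_Th": morpho.Tb_Th, "Tb_Sp": morpho.Tb_Sp,
            "Tb_N": morpho.Tb_N, "Tb_OrP": summ.Tb_OrP_mean_deg,
            "Tb_OrP_sd": summ.Tb_OrP_sd_deg, "Tb_OrS": summ.Tb_OrS_deg,
            "Tb_Int": summ.Tb_Int_deg}


def _mr_roi(shape, margin):
    return (margin, margin, shape[0] - 2 * margin, shape[1] - 2 * margin)


def run_pipeline(cfg: RunConfig) -> Path:
    """Execute the full chain; returns the run directory."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng_master = np.random.default_rng(cfg.seed)

    # --- simulate ------------------------------------------------------
    spec = phantoms.PhantomSpec(
        kind="rods",
        geometry={"angles_deg": list(cfg.angles_deg),
                  "weights": list(cfg.weights),
                  "rod_width": cfg.rod_width_mm,
                  "base_spacing": cfg.base_spacing_mm},
        grid_shape=(cfg.grid_px, cfg.grid_px), spacing=cfg.spacing_mm,
        seed=cfg.seed)
    base_img, _, truth = phantoms.make_rod_phantom(spec)
    stack = phantoms.make_slice_stack(base_img, cfg.n_ct_slices,
                                      cfg.spacing_mm, seed=cfg.seed)
    period = cfg.mr_period_ct_slices()
    first = (cfg.n_ct_slices - (cfg.n_mr_slices - 1) * period) // 2
    true_indices = [first + i * period for i in range(cfg.n_mr_slices)]
    if min(true_indices) < 0 or max(true_indices) >= cfg.n_ct_slices:
        raise ValueError("MR slice positions fall outside the CT stack; "
                         "increase n_ct_slices or shrink the MR period")
    dspec = phantoms.DegradationSpec(
        psf_sigma=cfg.psf_sigma_mm, downsample_factor=cfg.downsample_factor,
        noise_sigma=cfg.noise_sigma, invert_contrast=True,
        bias_field_amplitude=cfg.bias_field_amplitude)
    mr_slices = [phantoms.degrade_to_mri(stack.slice2d(k), dspec,
                                         seed=int(rng_master.integers(2**31)))
                 for k in true_indices]
    (out / "ground_truth.json").write_text(json.dumps(
        {"angles_deg": list(cfg.angles_deg), "weights": list(cfg.weights),
         "true_indices": true_indices, "mr_period_ct_slices": period,
         "seed": cfg.seed}, indent=2))

    # --- register ------------------------------------------------------
    geometry = registration.SequenceGeometry(
        cfg.mr_slice_thickness_mm, cfg.mr_slice_gap_mm,
        cfg.spacing_mm * cfg.downsample_factor, cfg.spacing_mm)
    reports = [registration.find_best_slice(mr, stack, center, cfg.n_reg)
               for mr, center in zip(mr_slices, true_indices)]
    quality = registration.delta_im_series([r.best_index for r in reports],
                                           geometry)
    reg_rows = [{"mr_index": i, "true_ct_index": k, "best_ct_index": r.best_index,
                 "ncc": r.ncc, "converged": r.converged}
                for i, (k, r) in enumerate(zip(true_indices, reports))]
    pd.DataFrame(reg_rows).to_csv(out / "registration_slices.csv", index=False)
    nccs = [r.ncc for r in reports]
    reg_table = pd.DataFrame([{
        "sequence": "MR_like", "ncc_mean": np.mean(nccs),
        "ncc_sd": np.std(nccs, ddof=1) if len(nccs) > 1 else np.nan,
        "delta_im_mean": quality.delta_im_mean,
        "delta_im_sd": quality.delta_im_sd,
        "exp_delta_im": quality.exp_delta_im}])
    reg_table.to_csv(out / "registration_quality.csv", index=False)

    # --- morphometry / orientation per modality ------------------------
    rows = []
    for i, (k, r, mr) in enumerate(zip(true_indices, reports, mr_slices)):
        ct_img = stack.slice2d(r.best_index)
        roi_ct = _mr_roi(ct_img.shape, cfg.roi_margin_px)
        margin_mr = max(4, int(round(cfg.roi_margin_px / cfg.downsample_factor)))
        roi_mr = _mr_roi(mr.shape, margin_mr)
        for modality, img, roi in (("uCT", ct_img, roi_ct),
                                   ("MR", mr, roi_mr)):
            rows.append({"slice": i, "modality": modality,
                         **slice_parameters(img, cfg, roi)})
    per_slice = pd.DataFrame(rows)
    per_slice.to_csv(out / "morphometry_slices.csv", index=False)
    summary = (per_slice.drop(columns="slice")
               .groupby("modality").agg(["mean", "std"]))
    summary.columns = [f"{p}_{s}" for p, s in summary.columns]
    summary.reset_index().to_csv(out / "morphometry_summary.csv", index=False)

    # --- BMD (both routes on the neck phantom) -------------------------
    n = max(32, int(2 * cfg.neck_rho_mm / cfg.spacing_mm) + 8)
    neck_spec = phantoms.PhantomSpec(kind="neck",
                                     geometry={"rho": cfg.neck_rho_mm},
                                     grid_shape=(n, n, n),
                                     spacing=cfg.spacing_mm)
    neck, neck_truth = phantoms.make_neck_phantom(neck_spec)
    res3d = bmd.bmd_volumetric(neck, rho=cfg.rho_g_cm3)
    central = morphometry.BinaryMask(neck.solid[neck_truth["central_slice"]],
                                     neck.spacing[1:])
    geom = bmd.RevolutionGeometry(neck_truth["axis_px"], cfg.spacing_mm,
                                  cfg.spacing_mm)
    res2d = bmd.bmd_areal_2d(central, geom, rho=cfg.rho_g_cm3)
    pd.DataFrame([dataclasses.asdict(res3d),
                  dataclasses.asdict(res2d)]).to_csv(out / "bmd.csv",
                                                     index=False)

    # --- agreement -----------------------------------------------------
    agree_rows = []
    wide = per_slice.pivot(index="slice", columns="modality")
    for p in MORPHO_PARAMS:
        ref = wide[(p, "uCT")].to_numpy()
        other = wide[(p, "MR")].to_numpy()
        rep = agreement.agreement_report(ref, other)
        agree_rows.append({"parameter": p, **dataclasses.asdict(rep)})
    pd.DataFrame(agree_rows).to_csv(out / "agreement.csv", index=False)

    (out / "config.json").write_text(json.dumps(
        {k: (list(v) if isinstance(v, tuple) else v)
         for k, v in dataclasses.asdict(cfg).items()}, indent=2))
    make_report(out)
    return out


def _agreement_plots(run_dir: Path) -> Path | None:
    """Bland–Altman and regression panels per parameter (PNG)."""
    per_slice = pd.read_csv(run_dir / "morphometry_slices.csv")
    wide = per_slice.pivot(index="slice", columns="modality")
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(2, len(MORPHO_PARAMS),
                             figsize=(3 * len(MORPHO_PARAMS), 6))
    for j, p in enumerate(MORPHO_PARAMS):
        ref = wide[(p, "uCT")].to_numpy()
        other = wide[(p, "MR")].to_numpy()
        ax = axes[0, j]
        ax.scatter(ref, other, s=12)
        lo = min(ref.min(), other.min())
        hi = max(ref.max(), other.max())
        ax.plot([lo, hi], [lo, hi], "k--", lw=0.8)
        ax.set_title(p)
        if j == 0:
            ax.set_ylabel("MR vs reference")
        ax = axes[1, j]
        mean, diff = (ref + other) / 2, other - ref
        ax.scatter(mean, diff, s=12)
        ax.axhline(diff.mean(), color="k", lw=0.8)
        sd = diff.std(ddof=1) if len(diff) > 1 else 0.0
        for loa in (diff.mean() - 1.96 * sd, diff.mean() + 1.96 * sd):
            ax.axhline(loa, color="gray", ls="--", lw=0.8)
        if j == 0:
            ax.set_ylabel("Bland–Altman")
    fig.tight_layout()
    out = run_dir / "agreement_plots.png"
    fig.savefig(out, dpi=110)
    plt.close(fig)
    return out


def make_report(run_dir) -> Path:
    """Render the run's CSV tables into a markdown report plus agreement
    plots (scatter-with-identity and Bland–Altman per parameter)."""
    run_dir = Path(run_dir)
    required = ["registration_quality.csv", "morphometry_summary.csv",
                "bmd.csv", "agreement.csv"]
    missing = [f for f in required if not (run_dir / f).exists()]
    if missing:
        raise FileNotFoundError(f"incomplete run {run_dir}: missing {missing}")
    if (run_dir / "morphometry_slices.csv").exists():
        _agreement_plots(run_dir)
    parts = ["# trabmorph run report\n"]
    titles = {"registration_quality.csv": "Registration quality (NCC, ΔIm vs expΔIm)",
              "morphometry_summary.csv": "Morphometry by modality (mean ± SD over slices)",
              "bmd.csv": "BMD: volumetric vs 2D revolution",
              "agreement.csv": "Modality agreement per parameter"}
    for fname in required:
        df = pd.read_csv(run_dir / fname)
        parts.append(f"\n## {titles[fname]}\n")
        parts.append("```\n" + df.to_string(index=False,
                                            float_format=lambda v: f"{v:.4g}")
                     + "\n```")
        parts.append("")
    path = run_dir / "report.md"
    path.write_text("\n".join(parts))
    return path
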