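"""Partial-volume correction and map conditioning for calibrated CBF.

Stage order in the standard pipeline is fixed: PVC -> smooth -> clip ->
resample -> screen.  The correction rescales each voxel's measured CBF by
its tissue composition, CBF_corr = CBF_uncorr / (GM + 0.4 * WM), which
assumes CSF contributes no flow and gray matter perfuses 2.5x (= 1/0.4)
white matter.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import affine_transform, gaussian_filter

from .errors import InputError
from .quantify import FWHM_TO_SIGMA, PerfusionMap

#: white-matter weight in the PVC denominator; implies a GM:WM perfusion
#: ratio of 1 / WM_WEIGHT = 2.5
WM_WEIGHT = 0.4

#: minimum PVC denominator; voxels below are dropped from the mask rather
#: than divided (guards CSF-dominated voxels against blow-up)
PVC_DENOM_EPS = 0.1


@dataclass
class TissueFractions:
    """Voxel-wise GM/WM/CSF partial-volume fractions on the analysis grid."""

    gm: np.ndarray
    wm: np.ndarray
    csf: np.ndarray
    affine: np.ndarray

    def __post_init__(self) -> None:
        self.gm = np.asarray(self.gm, dtype=float)
        self.wm = np.asarray(self.wm, dtype=float)
        self.csf = np.asarray(self.csf, dtype=float)
        if not (self.gm.shape == self.wm.shape == self.csf.shape):
            raise InputError("tissue fraction grids differ in shape")
        for name, arr in (("gm", self.gm), ("wm", self.wm), ("csf", self.csf)):
            if arr.min() < -1e-6 or arr.max() > 1 + 1e-6:
                raise InputError(f"{name} fractions outside [0, 1]")
        total = self.gm + self.wm + self.csf
        if not np.allclose(total, 1.0, atol=1e-6):
            raise InputError("GM + WM + CSF must equal 1 per voxel (tolerance 1e-6)")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.gm.shape


def gm_wm_perfusion_ratio(wm_weight: float = WM_WEIGHT) -> float:
    """The GM:WM perfusion ratio implied by the PVC denominator weight."""
    return 1.0 / wm_weight


def partial_volume_correct(
    cbf_uncorr: PerfusionMap,
    fractions: TissueFractions,
    wm_weight: float = WM_WEIGHT,
    eps: float = PVC_DENOM_EPS,
) -> PerfusionMap:
    """CBF_corr = CBF_uncorr / (GM + wm_weight * WM); low-tissue voxels masked out."""
    if fractions.shape != cbf_uncorr.cbf.shape:
        raise InputError(
            f"fraction grid {fractions.shape} does not match CBF grid {cbf_uncorr.cbf.shape}"
        )
    denom = fractions.gm + wm_weight * fractions.wm
    keep = cbf_uncorr.mask & (denom >= eps)
    corrected = np.full_like(cbf_uncorr.cbf, np.nan)
    np.divide(cbf_uncorr.cbf, denom, out=corrected, where=keep)
    out = PerfusionMap(
        cbf=np.where(keep, corrected, np.nan),
        mask=keep,
        affine=cbf_uncorr.affine.copy(),
        provenance=dict(cbf_uncorr.provenance),
    )
    out.provenance["stages"] = list(cbf_uncorr.provenance.get("stages", []))
    out.with_stage("partial_volume_correct", wm_weight=wm_weight, eps=eps,
                   gm_wm_ratio=gm_wm_perfusion_ratio(wm_weight))
    return out


def smooth_map(pmap: PerfusionMap, fwhm_mm: float = 4.0) -> PerfusionMap:
    """Gaussian smoothing within the mask, with renormalized (masked) convolution.

    sigma = fwhm / (2 * sqrt(2 ln 2)) per axis, converted to voxels from the
    affine.  Dividing the smoothed masked map by the smoothed mask avoids
    attenuation at the mask rim and leaves constant maps (and the masked
    mean, to first order) unchanged.  ``fwhm_mm = 0`` is the identity.
    """
    if fwhm_mm < 0:
        raise InputError("fwhm_mm must be non-negative")
    out = PerfusionMap(
        cbf=pmap.cbf.copy(),
        mask=pmap.mask.copy(),
        affine=pmap.affine.copy(),
        provenance=dict(pmap.provenance),
    )
    out.provenance["stages"] = list(pmap.provenance.get("stages", []))
    if fwhm_mm > 0 and pmap.mask.any():
        sigma_vox = fwhm_mm / (FWHM_TO_SIGMA * pmap.voxel_size_mm)
        filled = np.where(pmap.mask, pmap.cbf, 0.0)
        num = gaussian_filter(filled, sigma=sigma_vox, mode="nearest")
        den = gaussian_filter(pmap.mask.astype(float), sigma=sigma_vox, mode="nearest")
        smoothed = np.full_like(pmap.cbf, np.nan)
        np.divide(num, den, out=smoothed, where=den > 1e-12)
        out.cbf = np.where(pmap.mask, smoothed, np.nan)
    out.with_stage("smooth", fwhm_mm=fwhm_mm)
    return out


def clip_negative(pmap: PerfusionMap) -> PerfusionMap:
    """Replace negative intensities with 0 inside the mask (idempotent)."""
    cbf = np.where(pmap.mask, np.maximum(pmap.cbf, 0.0), np.nan)
    out = PerfusionMap(cbf=cbf, mask=pmap.mask.copy(), affine=pmap.affine.copy(),
                       provenance=dict(pmap.provenance))
    out.provenance["stages"] = list(pmap.provenance.get("stages", []))
    out.with_stage("clip_negative")
    return out


def resample_to_grid(
    pmap: PerfusionMap, target_voxel_mm: tuple[float, float, float] = (3.0, 3.0, 3.0)
) -> PerfusionMap:
    """Trilinear resampling to an isotropic target grid (identity if already there)."""
    target = np.asarray(target_voxel_mm, dtype=float)
    if np.any(target <= 0):
        raise InputError("target voxel sizes must be positive")
    current = pmap.voxel_size_mm
    out_provenance = dict(pmap.provenance)
    if np.allclose(current, target):
        out = PerfusionMap(cbf=pmap.cbf.copy(), mask=pmap.mask.copy(),
                           affine=pmap.affine.copy(), provenance=out_provenance)
        out.provenance["stages"] = list(pmap.provenance.get("stages", []))
        out.with_stage("resample", target_voxel_mm=list(map(float, target)), identity=True)
        return out
    scale = target / current  # output voxel -> input voxel index scaling
    out_shape = tuple(int(np.ceil(s * c / t)) for s, c, t in zip(pmap.cbf.shape, current, target))
    filled = np.where(pmap.mask, pmap.cbf, 0.0)
    cbf = affine_transform(filled, np.diag(scale), output_shape=out_shape, order=1, mode="nearest")
    mask = affine_transform(pmap.mask.astype(float), np.diag(scale), output_shape=out_shape,
                            order=1, mode="nearest") >= 0.5
    new_affine = pmap.affine.copy()
    new_affine[:3, :3] = pmap.affine[:3, :3] @ np.diag(scale)
    out = PerfusionMap(cbf=np.where(mask, cbf, np.nan), mask=mask, affine=new_affine,
                       provenance=out_provenance)
    out.provenance["stages"] = list(pmap.provenance.get("stages", []))
    out.with_stage("resample", target_voxel_mm=list(map(float, target)), identity=False)
    return out


def screen_outliers(
    maps: list[PerfusionMap],
    ids: list[str] | None = None,
    z_threshold: float = 3.0,
    level: str = "map",
) -> tuple[list[int], pd.DataFrame]:
    """Quality screening: eliminate values deviating > 3 SD from the mean.

    The default unit of screening is the session map: each map's within-mask
    mean is computed and maps whose mean deviates more than ``z_threshold``
    cohort SDs from the cohort mean of means are excluded (single pass; a
    degenerate zero-SD cohort excludes nothing).  ``level="voxel"`` instead
    removes, within each map, voxels deviating > 3 SD from that map's own
    within-mask mean.

    Returns (kept indices, report) where the report lists every map with
    its mean, z-score and exclusion flag.
    """
    if level not in ("map", "voxel"):
        raise InputError(f"unknown screening level {level!r}")
    if len(maps) < 3:
        raise InputError("outlier screening requires at least 3 maps")
    if ids is None:
        ids = [str(i) for i in range(len(maps))]

    if level == "voxel":
        report_rows = []
        for i, (pmap, sid) in enumerate(zip(maps, ids)):
            vals = pmap.cbf[pmap.mask]
            mu, sd = float(vals.mean()), float(vals.std(ddof=1)) if vals.size > 1 else 0.0
            if sd > 0:
                bad = pmap.mask & (np.abs(pmap.cbf - mu) > z_threshold * sd)
                pmap.mask = pmap.mask & ~bad
                pmap.cbf = np.where(pmap.mask, pmap.cbf, np.nan)
                n_removed = int(bad.sum())
            else:
                n_removed = 0
            pmap.with_stage("screen_outliers", level="voxel", n_removed=n_removed)
            report_rows.append({"id": sid, "n_voxels_removed": n_removed, "excluded": False})
        return list(range(len(maps))), pd.DataFrame(report_rows)

    means = np.array([float(m.cbf[m.mask].mean()) for m in maps])
    grand = means.mean()
    sd = means.std(ddof=1)
    z = (means - grand) / sd if sd > 0 else np.zeros_like(means)
    excluded = np.abs(z) > z_threshold
    report = pd.DataFrame(
        {"id": ids, "mask_mean": means, "z_score": z, "excluded": excluded}
    )
    kept = [i for i in range(len(maps)) if not excluded[i]]
    return kept, report


def pvc_pipeline(
    cbf_uncorr: PerfusionMap,
    fractions: TissueFractions,
    smooth_fwhm_mm: float = 4.0,
    target_voxel_mm: tuple[float, float, float] = (3.0, 3.0, 3.0),
    wm_weight: float = WM_WEIGHT,
    eps: float = PVC_DENOM_EPS,
) -> PerfusionMap:
    """Apply the per-map stages in their fixed order: PVC, smooth, clip, resample."""
    out = partial_volume_correct(cbf_uncorr, fractions, wm_weight=wm_weight, eps=eps)
    out = smooth_map(out, fwhm_mm=smooth_fwhm_mm)
    out = clip_negative(out)
    out = resample_to_grid(out, target_voxel_mm=target_voxel_mm)
    return out
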