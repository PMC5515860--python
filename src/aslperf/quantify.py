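"""Calibrated CBF quantification from pulsed-ASL tag/control time series.

The acquisition is a PICORE QUIPSS-II pulsed ASL sequence: arterial water is
inverted in a tag slab, a saturation pulse at TI1 cuts the labeled bolus to a
fixed temporal width, and images are read out slice by slice starting at TI2.
Under the QUIPSS-II assumptions (bolus fully delivered, no outflow, label
decaying with the T1 of blood) the perfusion-weighted difference signal of a
voxel in slice *s* is

    dM = 2 * alpha * M0_blood * f * TI1 * exp(-TI2_s / T1_blood) / 6000

with ``f`` the cerebral blood flow in mL/100 g tissue/min, ``TI1`` in seconds
and ``TI2_s = TI2 + s * slice_duration`` the slice-specific inversion time.
This module inverts that closed form: it forms the difference series by
surround subtraction, removes coil inhomogeneity with a minimum-contrast
scan, calibrates the equilibrium magnetization of blood from a CSF reference
scan, and solves for ``f`` voxel by voxel.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Any

import numpy as np
from scipy.ndimage import gaussian_filter

from .errors import CalibrationError, ConfigurationError, InputError

FWHM_TO_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))


@dataclass(frozen=True)
class QuantConstants:
    """Physical constants of the quantification model.

    Parameters
    ----------
    alpha:
        Inversion (labeling) efficiency, dimensionless in ``(0, 1]``.
    t1_blood_ms:
        Longitudinal relaxation time of arterial blood at 3 T, in ms.
    blood_csf_density_ratio:
        Conversion factor from the equilibrium magnetization of CSF to that
        of blood.  The full conversion chain involves proton-density and
        T2*-decay terms of the two compartments; here it is collapsed into a
        single dimensionless ratio.
    unit_factor:
        Scaling from (mL blood / g tissue / s) to the conventional
        mL/100 g tissue/min: 100 g * 60 s/min = 6000.

    These constants are shared by the forward model of the digital phantom
    and by the quantifier, so round-trip tests exercise one single set of
    numbers.
    """

    alpha: float = 0.95
    t1_blood_ms: float = 1664.0
    blood_csf_density_ratio: float = 0.76
    unit_factor: float = 6000.0

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha <= 1.0):
            raise ConfigurationError(f"alpha must be in (0, 1], got {self.alpha}")
        if self.t1_blood_ms <= 0:
            raise ConfigurationError("t1_blood_ms must be positive")
        if self.blood_csf_density_ratio <= 0:
            raise ConfigurationError("blood_csf_density_ratio must be positive")
        if self.unit_factor <= 0:
            raise ConfigurationError("unit_factor must be positive")


@dataclass
class AslSession:
    """One subject-visit: raw tag/control series plus calibration scans.

    Attributes
    ----------
    series:
        4D array ``(x, y, z, 2 * n_pairs)`` of interleaved tag/control
        volumes.  ``tag_first`` states whether even volume indices are tags.
    csf_scan, csf_mask:
        3D scan with the excitation pulse disabled, used to estimate the
        equilibrium magnetization of CSF, and a binary mask of pure-CSF
        voxels (ventricle interior).
    min_contrast_reps:
        Two repetitions of the low-contrast scan capturing combined
        transmit/receive coil inhomogeneity.
    brain_mask:
        Binary mask of voxels quantified and used for normalizations.
    affine:
        4x4 voxel-to-world affine (mm), shared by every volume.
    meta:
        Free-form session metadata (subject, group, condition, scanner).
    """

    series: np.ndarray
    tr_ms: float
    ti1_ms: float
    ti2_ms: float
    slice_duration_ms: float
    csf_scan: np.ndarray
    csf_mask: np.ndarray
    min_contrast_reps: tuple[np.ndarray, np.ndarray]
    brain_mask: np.ndarray
    affine: np.ndarray
    meta: dict[str, Any] = field(default_factory=dict)
    tag_first: bool = True

    def __post_init__(self) -> None:
        self.series = np.asarray(self.series, dtype=float)
        if self.series.ndim != 4:
            raise InputError("series must be 4D (x, y, z, volumes)")
        if self.series.shape[-1] % 2 != 0:
            raise InputError("series must hold an even number of volumes (tag/control pairs)")
        if not (0 < self.ti1_ms < self.ti2_ms < self.tr_ms):
            raise ConfigurationError(
                f"timings must satisfy 0 < TI1 < TI2 < TR, got "
                f"TI1={self.ti1_ms}, TI2={self.ti2_ms}, TR={self.tr_ms}"
            )
        if self.slice_duration_ms < 0:
            raise ConfigurationError("slice_duration_ms must be non-negative")
        grid = self.series.shape[:3]
        for name in ("csf_scan", "csf_mask", "brain_mask"):
            if np.asarray(getattr(self, name)).shape != grid:
                raise InputError(f"{name} shape {getattr(self, name).shape} does not match series grid {grid}")
        for rep in self.min_contrast_reps:
            if np.asarray(rep).shape != grid:
                raise InputError("minimum-contrast repetitions must match the series grid")
        self.csf_mask = np.asarray(self.csf_mask, dtype=bool)
        self.brain_mask = np.asarray(self.brain_mask, dtype=bool)

    @property
    def n_pairs(self) -> int:
        return self.series.shape[-1] // 2

    @property
    def voxel_size_mm(self) -> np.ndarray:
        return np.sqrt((self.affine[:3, :3] ** 2).sum(axis=0))


@dataclass
class PerfusionMap:
    """A calibrated CBF volume in mL/100 g tissue/min with a validity mask.

    Values are finite inside ``mask`` and NaN outside; ``provenance`` records
    the session metadata, constants and processing stages that produced it.
    """

    cbf: np.ndarray
    mask: np.ndarray
    affine: np.ndarray
    provenance: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.cbf = np.asarray(self.cbf, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.cbf.shape != self.mask.shape:
            raise InputError("cbf and mask shapes differ")
        if not np.all(np.isfinite(self.cbf[self.mask])):
            raise InputError("non-finite CBF values inside the validity mask")

    @property
    def voxel_size_mm(self) -> np.ndarray:
        return np.sqrt((self.affine[:3, :3] ** 2).sum(axis=0))

    @property
    def voxel_volume_ul(self) -> float:
        """Voxel volume in microliters (1 mm^3 == 1 uL), from the affine."""
        return float(abs(np.linalg.det(self.affine[:3, :3])))

    def with_stage(self, stage: str, **params: Any) -> None:
        self.provenance.setdefault("stages", []).append({"stage": stage, **params})


def surround_subtract(session: AslSession) -> tuple[np.ndarray, np.ndarray]:
    """Form the perfusion-weighted difference series by surround subtraction.

    Each control volume is compared against the average of its two
    neighboring tag volumes in acquisition order, which cancels any signal
    component that varies linearly in time (drift) exactly.  The first/last
    control of the run has a single neighbor and falls back to simple
    subtraction, so all ``n_pairs`` estimates are retained.

    Returns
    -------
    dm_series:
        ``(x, y, z, n_pairs)`` array of per-pair difference volumes.
    dm_mean:
        Mean difference volume across pairs.
    """
    if session.n_pairs < 2:
        raise InputError("surround subtraction requires at least 2 tag/control pairs")
    series = session.series
    n_vol = series.shape[-1]
    control_idx = np.arange(1, n_vol, 2) if session.tag_first else np.arange(0, n_vol, 2)
    dm = np.empty(series.shape[:3] + (session.n_pairs,), dtype=float)
    for i, k in enumerate(control_idx):
        neighbors = [j for j in (k - 1, k + 1) if 0 <= j < n_vol]
        tag_avg = series[..., neighbors].mean(axis=-1)
        dm[..., i] = series[..., k] - tag_avg
    return dm, dm.mean(axis=-1)


def estimate_m0_blood(
    csf_scan: np.ndarray,
    csf_mask: np.ndarray,
    constants: QuantConstants,
) -> tuple[float, float]:
    """Estimate the equilibrium magnetization of blood from the CSF scan.

    The CSF magnetization is taken as the median of the scan inside the CSF
    mask (robust to residual partial volume at the mask edge) and converted
    to blood units by ``blood_csf_density_ratio``.

    Returns ``(m0_blood, m0_csf)`` in signal units.
    """
    csf_mask = np.asarray(csf_mask, dtype=bool)
    if not csf_mask.any():
        raise InputError("CSF mask is empty")
    m0_csf = float(np.median(np.asarray(csf_scan, dtype=float)[csf_mask]))
    if m0_csf <= 0:
        raise CalibrationError(f"non-positive CSF equilibrium magnetization: {m0_csf}")
    return m0_csf * constants.blood_csf_density_ratio, m0_csf


def minimum_contrast_correct(
    volume: np.ndarray,
    min_contrast_reps: tuple[np.ndarray, np.ndarray],
    brain_mask: np.ndarray,
    voxel_size_mm: np.ndarray | tuple[float, float, float],
    smooth_fwhm_mm: float = 6.0,
    min_field: float = 0.05,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Divide out coil sensitivity estimated from the minimum-contrast scans.

    The two repetitions are averaged and lightly smoothed to form the field
    estimate, then normalized to unit mean over the brain mask so the
    correction preserves the volume's brain-mean signal.  Voxels where the
    field drops below ``min_field`` are removed from the validity mask
    instead of being divided by a near-zero number.

    Returns ``(corrected_volume, field, valid_mask)``.
    """
    brain_mask = np.asarray(brain_mask, dtype=bool)
    avg = (np.asarray(min_contrast_reps[0], dtype=float) + np.asarray(min_contrast_reps[1], dtype=float)) / 2.0
    if not np.any(avg != 0):
        raise CalibrationError("minimum-contrast repetitions are identically zero")
    sigma_vox = np.asarray(smooth_fwhm_mm, dtype=float) / (FWHM_TO_SIGMA * np.asarray(voxel_size_mm, dtype=float))
    field = gaussian_filter(avg, sigma=sigma_vox, mode="nearest")
    brain_mean = field[brain_mask].mean() if brain_mask.any() else field.mean()
    if brain_mean == 0:
        raise CalibrationError("minimum-contrast field has zero brain mean")
    field = field / brain_mean
    valid = brain_mask & (field >= min_field)
    corrected = np.full_like(np.asarray(volume, dtype=float), np.nan)
    np.divide(volume, field, out=corrected, where=field >= min_field)
    return corrected, field, valid


def slice_inversion_times_ms(
    n_slices: int, ti2_ms: float, slice_duration_ms: float
) -> np.ndarray:
    """Slice-specific inversion time TI2_s = TI2 + s * slice_duration (ascending order)."""
    return ti2_ms + np.arange(n_slices) * slice_duration_ms


def quantify_cbf(
    dm_mean: np.ndarray,
    m0_blood: float,
    ti1_ms: float,
    ti2_ms: float,
    slice_duration_ms: float,
    constants: QuantConstants,
    mask: np.ndarray,
    affine: np.ndarray,
    provenance: dict[str, Any] | None = None,
) -> PerfusionMap:
    """Invert the QUIPSS-II closed form to obtain CBF in mL/100 g/min.

    Per voxel in slice *s* (the third array axis):

        CBF = unit_factor * dM / (2 * alpha * M0_blood * TI1_s * exp(-TI2_s / T1_blood))

    with TI1 converted to seconds and the exponential evaluated in ms.
    """
    if m0_blood <= 0:
        raise CalibrationError("M0_blood must be positive")
    if ti1_ms <= 0 or ti2_ms <= 0:
        raise InputError("inversion times must be positive")
    dm_mean = np.asarray(dm_mean, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    ti2_s = slice_inversion_times_ms(dm_mean.shape[2], ti2_ms, slice_duration_ms)
    denom = (
        2.0
        * constants.alpha
        * m0_blood
        * (ti1_ms / 1000.0)
        * np.exp(-ti2_s / constants.t1_blood_ms)
    )
    cbf = constants.unit_factor * dm_mean / denom[np.newaxis, np.newaxis, :]
    cbf = np.where(mask, cbf, np.nan)
    prov = dict(provenance or {})
    prov.update(
        {
            "constants": dataclasses.asdict(constants),
            "m0_blood": float(m0_blood),
            "ti1_ms": float(ti1_ms),
            "ti2_ms": float(ti2_ms),
            "slice_duration_ms": float(slice_duration_ms),
        }
    )
    pmap = PerfusionMap(cbf=cbf, mask=mask, affine=np.asarray(affine, dtype=float), provenance=prov)
    pmap.with_stage("quantify_cbf")
    return pmap


def quantify_session(
    session: AslSession,
    constants: QuantConstants | None = None,
    smooth_fwhm_mm: float = 6.0,
) -> PerfusionMap:
    """Full quantification of one session: difference, coil correction, calibration.

    The CSF reference scan is assumed coil-corrected at acquisition (its
    mask sits near the coil-normalization region); the minimum-contrast
    field is divided out of the mean difference volume only.
    """
    constants = constants if constants is not None else QuantConstants()
    _, dm_mean = surround_subtract(session)
    corrected, field, valid = minimum_contrast_correct(
        dm_mean,
        session.min_contrast_reps,
        session.brain_mask,
        session.voxel_size_mm,
        smooth_fwhm_mm=smooth_fwhm_mm,
    )
    m0_blood, m0_csf = estimate_m0_blood(session.csf_scan, session.csf_mask, constants)
    provenance = {
        "session": dict(session.meta),
        "n_pairs": session.n_pairs,
        "m0_csf": m0_csf,
        "coil_field_range": [float(field[valid].min()), float(field[valid].max())] if valid.any() else None,
    }
    pmap = quantify_cbf(
        corrected,
        m0_blood,
        session.ti1_ms,
        session.ti2_ms,
        session.slice_duration_ms,
        constants,
        mask=valid,
        affine=session.affine,
        provenance=provenance,
    )
    pmap.provenance["stages"] = [
        {"stage": "surround_subtract"},
        {"stage": "minimum_contrast_correct", "smooth_fwhm_mm": smooth_fwhm_mm},
        {"stage": "estimate_m0_blood"},
    ] + pmap.provenance["stages"]
    return pmap
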