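"""Digital perfusion phantom: synthetic cohorts with known ground truth.

The phantom emulates the study design this pipeline analyzes: two groups
(controls and patients) scanned in two metabolic conditions (hungry and
fed), each session a pulsed-ASL tag/control series plus a CSF calibration
scan and a minimum-contrast scan pair.  Geometry is deliberately schematic
— concentric ellipsoidal tissue bands on the 3 mm analysis grid rather than
anatomy — because the goal is exact, reconstructible ground truth: every
voxel's CBF, every ROI effect, every coil-field value and every expected
hunger rating is known and serialized so downstream stages can be tested
quantitatively.

Ground-truth CBF is a tissue mixture ``gm * CBF_GM + wm * CBF_WM`` (CSF has
zero flow) plus group-specific hungry-minus-fed offsets planted inside
named ROIs, mirroring the opposite-signed group responses seen in
homeostatic regions (controls perfuse more when hungry, patients less).
The forward signal model uses the same ``QuantConstants`` the quantifier
inverts, so round-trip tests test code, not copied numbers.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .errors import ConfigurationError, InputError
from .quantify import AslSession, QuantConstants, slice_inversion_times_ms

# proton-density-like weights of the static (control) signal per tissue class
STATIC_WEIGHTS = {"gm": 0.90, "wm": 0.75, "csf": 1.00}
MIN_CONTRAST_LEVEL = 500.0


@dataclass(frozen=True)
class RoiSpec:
    """An axis-aligned box ROI given by fractional grid center and voxel size."""

    center_frac: tuple[float, float, float]
    size_vox: tuple[int, int, int]


DEFAULT_ROI_SPECS: dict[str, RoiSpec] = {
    # three multi-voxel "search" ROIs in the cortical gray-matter band
    "vst": RoiSpec((0.72, 0.72, 0.50), (3, 3, 2)),
    "vmpfc": RoiSpec((0.28, 0.72, 0.50), (3, 3, 2)),
    "insula": RoiSpec((0.28, 0.28, 0.50), (3, 3, 2)),
    # one small structure tested whole-ROI (<= 5 voxels)
    "hypothalamus": RoiSpec((0.72, 0.30, 0.42), (1, 2, 2)),
}


def _default_roi_effects() -> dict[str, dict[str, float]]:
    # hungry-minus-fed CBF offsets (mL/100 g/min) per ROI and group:
    # controls respond positively to hunger, patients negatively
    return {
        "vst": {"control": 8.0, "patient": -8.0},
        "vmpfc": {"control": 8.0, "patient": -8.0},
        "insula": {"control": 6.0, "patient": -6.0},
        "hypothalamus": {"control": 0.0, "patient": 0.0},
    }


@dataclass
class PhantomConfig:
    """All knobs of the synthetic cohort generator.

    Acquisition defaults follow the emulated protocol: 20 tag/control pairs
    (40 volumes), TR 2500 ms, TI1 600 ms, TI2 1600 ms, ascending slices with
    a 45 ms per-slice readout offset, on a 3 mm isotropic grid (27 uL
    voxels).  Tissue CBF defaults (GM 60, WM 24 mL/100 g/min) realize the
    2.5:1 gray/white perfusion ratio assumed by the partial-volume
    correction downstream.  ``subject_cbf_sd`` is a per-subject baseline GM
    CBF shift (stable across conditions, so it cancels in hungry-minus-fed
    contrasts but provides realistic between-subject spread for the
    behavioral association); ``subject_effect_sd`` optionally jitters the
    planted ROI offsets per subject (default 0 so planted effects remain
    exactly reconstructible from the configuration).
    """

    grid_shape: tuple[int, int, int] = (24, 24, 12)
    voxel_size_mm: tuple[float, float, float] = (3.0, 3.0, 3.0)
    n_slices: int | None = None
    n_pairs: int = 20
    tr_ms: float = 2500.0
    ti1_ms: float = 600.0
    ti2_ms: float = 1600.0
    slice_duration_ms: float = 45.0
    tissue_cbf: dict[str, float] = field(default_factory=lambda: {"gm": 60.0, "wm": 24.0})
    roi_specs: dict[str, RoiSpec] = field(default_factory=lambda: dict(DEFAULT_ROI_SPECS))
    roi_effects: dict[str, dict[str, float]] = field(default_factory=_default_roi_effects)
    noise_sd: float = 2.0
    drift_per_volume: float = 0.5
    coil_amplitude: float = 0.2
    m0_csf: float = 1200.0
    constants: QuantConstants = field(default_factory=QuantConstants)
    groups: tuple[str, str] = ("control", "patient")
    conditions: tuple[str, str] = ("hungry", "fed")
    n_per_group: dict[str, int] = field(default_factory=lambda: {"control": 16, "patient": 21})
    scanners: tuple[str, ...] = ("scanner_a", "scanner_b")
    subject_cbf_sd: float = 5.0
    subject_effect_sd: float = 0.0
    rating_slope: float = -0.1
    rating_noise_sd: float = 0.5
    rating_link: tuple[str, str, str] = ("patient", "hungry", "insula")
    rating_center: dict[str, float] = field(default_factory=lambda: {"hungry": 5.0, "fed": 1.5})
    tag_first: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_slices is None:
            self.n_slices = self.grid_shape[2]
        if self.n_slices != self.grid_shape[2]:
            raise ConfigurationError("n_slices must equal the number of axial grid slices")
        if not (0 < self.ti1_ms < self.ti2_ms < self.tr_ms):
            raise ConfigurationError("timings must satisfy 0 < TI1 < TI2 < TR")
        last_readout = self.ti2_ms + (self.n_slices - 1) * self.slice_duration_ms
        if last_readout >= self.tr_ms:
            raise ConfigurationError(
                f"last slice readout at {last_readout} ms exceeds TR={self.tr_ms} ms"
            )
        if self.n_pairs < 2:
            raise ConfigurationError("n_pairs must be >= 2")
        if any(v < 0 for v in self.tissue_cbf.values()):
            raise ConfigurationError("tissue CBF values must be non-negative")
        if any(v <= 0 for v in self.voxel_size_mm):
            raise ConfigurationError("voxel sizes must be positive")
        if self.noise_sd < 0 or self.rating_noise_sd < 0:
            raise ConfigurationError("noise standard deviations must be non-negative")
        for roi in self.roi_effects:
            if roi not in self.roi_specs:
                raise ConfigurationError(f"roi_effects names unknown ROI {roi!r}")

    @property
    def affine(self) -> np.ndarray:
        return np.diag(list(self.voxel_size_mm) + [1.0])


@dataclass
class PhantomTruth:
    """Everything the generator knows, serialized alongside its outputs."""

    config: PhantomConfig
    subjects: pd.DataFrame  # subject_id, group, scanner
    cbf_truth: dict[tuple[str, str], np.ndarray]  # (subject_id, condition) -> 3D CBF
    gm: np.ndarray
    wm: np.ndarray
    csf: np.ndarray
    roi_masks: dict[str, np.ndarray]
    brain_mask: np.ndarray
    csf_mask: np.ndarray
    coil_field_truth: np.ndarray
    m0_csf_truth: float
    m0_blood_truth: float
    ratings_truth: pd.DataFrame  # subject_id, group, condition, rating_expected
    seed: int = 0

    def roi_mean_truth(self, subject_id: str, condition: str, roi: str) -> float:
        mask = self.roi_masks[roi]
        return float(self.cbf_truth[(subject_id, condition)][mask].mean())


def _roi_box(spec: RoiSpec, grid: tuple[int, int, int]) -> tuple[slice, slice, slice]:
    slices = []
    for axis in range(3):
        center = int(round(spec.center_frac[axis] * (grid[axis] - 1)))
        half_lo = (spec.size_vox[axis] - 1) // 2
        lo = center - half_lo
        hi = lo + spec.size_vox[axis]
        if lo < 0 or hi > grid[axis]:
            raise ConfigurationError(
                f"ROI box {spec} does not fit inside grid {grid} on axis {axis}"
            )
        slices.append(slice(lo, hi))
    return tuple(slices)


def _build_tissue_and_rois(
    config: PhantomConfig,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, dict[str, np.ndarray], np.ndarray, np.ndarray]:
    """Concentric ellipsoid tissue bands with smoothed (partial-volume) borders.

    A white-matter core sits inside a gray-matter band inside a CSF rim; a
    central ventricle block and all ROI boxes are forced to pure CSF / pure
    GM respectively after smoothing, giving exact calibration and effect
    arithmetic there while boundaries retain genuine mixed voxels.
    """
    nx, ny, nz = config.grid_shape
    ii, jj, kk = np.meshgrid(np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij")
    cx, cy, cz = (nx - 1) / 2.0, (ny - 1) / 2.0, (nz - 1) / 2.0
    r = np.sqrt(
        ((ii - cx) / max(cx, 1e-9)) ** 2
        + ((jj - cy) / max(cy, 1e-9)) ** 2
        + ((kk - cz) / max(cz, 1e-9)) ** 2
    )
    wm_hard = (r <= 0.45).astype(float)
    gm_hard = ((r > 0.45) & (r <= 0.95)).astype(float)
    csf_hard = (r > 0.95).astype(float)

    # partial volumes at tissue borders via truncated Gaussian smoothing
    sigma, truncate = 0.6, 3.0
    gm = gaussian_filter(gm_hard, sigma=sigma, truncate=truncate, mode="nearest")
    wm = gaussian_filter(wm_hard, sigma=sigma, truncate=truncate, mode="nearest")
    csf = gaussian_filter(csf_hard, sigma=sigma, truncate=truncate, mode="nearest")
    total = gm + wm + csf
    gm, wm, csf = gm / total, wm / total, csf / total

    # central ventricle: pure CSF, sized so at least its core stays pure
    vent = tuple(
        slice(max(0, int(round(c)) - 2), min(n, int(round(c)) + 3))
        for c, n in ((cx, nx), (cy, ny), (cz, nz))
    )
    gm[vent], wm[vent], csf[vent] = 0.0, 0.0, 1.0
    vent_core = tuple(
        slice(max(0, int(round(c)) - 1), min(n, int(round(c)) + 2))
        for c, n in ((cx, nx), (cy, ny), (cz, nz))
    )
    csf_mask = np.zeros(config.grid_shape, dtype=bool)
    csf_mask[vent_core] = True

    roi_masks: dict[str, np.ndarray] = {}
    occupied = np.zeros(config.grid_shape, dtype=bool)
    for name, spec in config.roi_specs.items():
        box = _roi_box(spec, config.grid_shape)
        mask = np.zeros(config.grid_shape, dtype=bool)
        mask[box] = True
        if (mask & occupied).any():
            raise ConfigurationError(f"ROI {name!r} overlaps a previously placed ROI")
        if (mask & csf_mask).any():
            raise ConfigurationError(f"ROI {name!r} overlaps the ventricle")
        occupied |= mask
        roi_masks[name] = mask
        # ROIs live in homogeneous cortical gray matter
        gm[mask], wm[mask], csf[mask] = 1.0, 0.0, 0.0

    total = gm + wm + csf
    assert np.allclose(total, 1.0, atol=1e-9), "tissue fractions must sum to 1"
    brain_mask = (gm + wm) >= 0.5
    return gm, wm, csf, roi_masks, brain_mask, csf_mask


def _coil_field(config: PhantomConfig, rng: np.random.Generator, brain_mask: np.ndarray) -> np.ndarray:
    """Smooth multiplicative sensitivity: random second-order polynomial,
    scaled to +/- ``coil_amplitude`` and normalized to unit brain mean."""
    nx, ny, nz = config.grid_shape
    u = np.linspace(-1.0, 1.0, nx)[:, None, None]
    v = np.linspace(-1.0, 1.0, ny)[None, :, None]
    w = np.linspace(-1.0, 1.0, nz)[None, None, :]
    c = rng.normal(size=9)
    raw = (
        c[0] * u + c[1] * v + c[2] * w
        + c[3] * u * v + c[4] * u * w + c[5] * v * w
        + c[6] * u ** 2 + c[7] * v ** 2 + c[8] * w ** 2
    )
    raw = np.broadcast_to(raw, config.grid_shape).copy()
    dev = raw - raw.mean()
    peak = np.abs(dev).max()
    if peak > 0 and config.coil_amplitude > 0:
        fld = 1.0 + config.coil_amplitude * dev / peak
    else:
        fld = np.ones(config.grid_shape)
    return fld / fld[brain_mask].mean()


def make_phantom(config: PhantomConfig) -> PhantomTruth:
    """Generate the cohort ground truth (deterministic given ``config.seed``)."""
    gm, wm, csf, roi_masks, brain_mask, csf_mask = _build_tissue_and_rois(config)
    rng = np.random.default_rng(np.random.SeedSequence([int(config.seed), 0]))
    coil = _coil_field(config, rng, brain_mask)

    rows = []
    for group in config.groups:
        for i in range(config.n_per_group[group]):
            rows.append(
                {
                    "subject_id": f"{group}{i + 1:02d}",
                    "group": group,
                    "scanner": config.scanners[i % len(config.scanners)],
                }
            )
    subjects = pd.DataFrame(rows)

    base_mix = gm * config.tissue_cbf["gm"] + wm * config.tissue_cbf.get("wm", 0.0)
    cbf_truth: dict[tuple[str, str], np.ndarray] = {}
    for _, row in subjects.iterrows():
        baseline_shift = rng.normal(0.0, config.subject_cbf_sd) if config.subject_cbf_sd > 0 else 0.0
        base = base_mix + gm * baseline_shift
        offsets = np.zeros(config.grid_shape)
        for roi, per_group in config.roi_effects.items():
            eff = per_group.get(row["group"], 0.0)
            if config.subject_effect_sd > 0:
                eff = eff + rng.normal(0.0, config.subject_effect_sd)
            offsets[roi_masks[roi]] += eff
        for condition in config.conditions:
            vol = base + (offsets if condition == "hungry" else 0.0)
            cbf_truth[(row["subject_id"], condition)] = np.maximum(vol, 0.0) if (vol < 0).any() else vol

    m0_blood_truth = config.m0_csf * config.constants.blood_csf_density_ratio

    link_group, link_condition, link_roi = config.rating_link
    ref_cbf = config.tissue_cbf["gm"]
    rating_rows = []
    for _, row in subjects.iterrows():
        for condition in config.conditions:
            expected = config.rating_center[condition]
            if row["group"] == link_group and condition == link_condition:
                roi_cbf = float(cbf_truth[(row["subject_id"], condition)][roi_masks[link_roi]].mean())
                expected = expected + config.rating_slope * (roi_cbf - ref_cbf)
            rating_rows.append(
                {
                    "subject_id": row["subject_id"],
                    "group": row["group"],
                    "condition": condition,
                    "rating_expected": float(np.clip(expected, 0.0, 7.0)),
                }
            )

    return PhantomTruth(
        config=config,
        subjects=subjects,
        cbf_truth=cbf_truth,
        gm=gm,
        wm=wm,
        csf=csf,
        roi_masks=roi_masks,
        brain_mask=brain_mask,
        csf_mask=csf_mask,
        coil_field_truth=coil,
        m0_csf_truth=config.m0_csf,
        m0_blood_truth=m0_blood_truth,
        ratings_truth=pd.DataFrame(rating_rows),
        seed=int(config.seed),
    )


def _session_rng(config: PhantomConfig, subject_index: int, condition_index: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence([int(config.seed), 1, int(subject_index), int(condition_index)])
    )


def forward_dm(truth: PhantomTruth, cbf: np.ndarray) -> np.ndarray:
    """Forward QUIPSS-II difference signal for a CBF volume (signal units).

    Uses the same constants and slice-timing rule the quantifier inverts.
    """
    cfg = truth.config
    k = cfg.constants
    ti2_s = slice_inversion_times_ms(cfg.grid_shape[2], cfg.ti2_ms, cfg.slice_duration_ms)
    decay = np.exp(-ti2_s / k.t1_blood_ms)[np.newaxis, np.newaxis, :]
    return (
        2.0 * k.alpha * truth.m0_blood_truth * cbf * (cfg.ti1_ms / 1000.0) * decay
        / k.unit_factor
    )


def simulate_asl_session(
    truth: PhantomTruth, subject_id: str, condition: str, config: PhantomConfig | None = None
) -> AslSession:
    """Simulate one tag/control session plus calibration scans.

    Control volume k: ``static * coil + drift * k + noise``; tag volume:
    control minus the forward difference signal (scaled by the coil field).
    The CSF reference scan carries no coil modulation (treated as acquired
    coil-corrected); the two minimum-contrast repetitions are proportional
    to the coil field plus thermal noise.
    """
    config = config if config is not None else truth.config
    subjects = truth.subjects
    match = subjects.index[subjects["subject_id"] == subject_id]
    if len(match) == 0:
        raise InputError(f"unknown subject {subject_id!r}")
    if condition not in config.conditions:
        raise InputError(f"unknown condition {condition!r}")
    subject_index = int(match[0])
    condition_index = config.conditions.index(condition)
    rng = _session_rng(config, subject_index, condition_index)

    cbf = truth.cbf_truth[(subject_id, condition)]
    dm = forward_dm(truth, cbf)
    static = config.m0_csf * (
        STATIC_WEIGHTS["gm"] * truth.gm
        + STATIC_WEIGHTS["wm"] * truth.wm
        + STATIC_WEIGHTS["csf"] * truth.csf
    )
    coil = truth.coil_field_truth

    n_vol = 2 * config.n_pairs
    series = np.empty(config.grid_shape + (n_vol,))
    for k in range(n_vol):
        vol = static * coil + config.drift_per_volume * k
        if config.noise_sd > 0:
            vol = vol + rng.normal(0.0, config.noise_sd, size=config.grid_shape)
        is_tag = (k % 2 == 0) if config.tag_first else (k % 2 == 1)
        if is_tag:
            vol = vol - dm * coil
        series[..., k] = vol

    csf_scan = static.copy()
    if config.noise_sd > 0:
        csf_scan = csf_scan + rng.normal(0.0, config.noise_sd, size=config.grid_shape)
    reps = []
    for _ in range(2):
        rep = MIN_CONTRAST_LEVEL * coil
        if config.noise_sd > 0:
            rep = rep + rng.normal(0.0, config.noise_sd, size=config.grid_shape)
        reps.append(rep)

    row = subjects.loc[subject_index]
    return AslSession(
        series=series,
        tr_ms=config.tr_ms,
        ti1_ms=config.ti1_ms,
        ti2_ms=config.ti2_ms,
        slice_duration_ms=config.slice_duration_ms,
        csf_scan=csf_scan,
        csf_mask=truth.csf_mask,
        min_contrast_reps=(reps[0], reps[1]),
        brain_mask=truth.brain_mask,
        affine=config.affine,
        meta={
            "subject_id": subject_id,
            "group": row["group"],
            "condition": condition,
            "scanner": row["scanner"],
            "seed": int(config.seed),
        },
        tag_first=config.tag_first,
    )


def simulate_ratings(truth: PhantomTruth, config: PhantomConfig | None = None) -> pd.DataFrame:
    """Noisy 0-7 Likert hunger ratings per session.

    rating = clamp(expected + noise, 0, 7), where the expected value embeds
    the configured CBF->rating slope for the linked group/condition only.
    """
    config = config if config is not None else truth.config
    rng = np.random.default_rng(np.random.SeedSequence([int(config.seed), 2]))
    out = truth.ratings_truth.copy()
    noise = (
        rng.normal(0.0, config.rating_noise_sd, size=len(out))
        if config.rating_noise_sd > 0
        else np.zeros(len(out))
    )
    out["rating"] = np.clip(out["rating_expected"].to_numpy() + noise, 0.0, 7.0)
    return out[["subject_id", "group", "condition", "rating"]]


def noiseless_config(**overrides: Any) -> PhantomConfig:
    """A convenience configuration with every stochastic nuisance disabled."""
    params: dict[str, Any] = dict(
        noise_sd=0.0,
        drift_per_volume=0.0,
        coil_amplitude=0.0,
        subject_cbf_sd=0.0,
        subject_effect_sd=0.0,
        rating_noise_sd=0.0,
    )
    params.update(overrides)
    return PhantomConfig(**params)


def phantom_config_to_dict(config: PhantomConfig) -> dict[str, Any]:
    d = dataclasses.asdict(config)
    d["constants"] = dataclasses.asdict(config.constants)
    d["roi_specs"] = {
        name: {"center_frac": list(s.center_frac), "size_vox": list(s.size_vox)}
        for name, s in config.roi_specs.items()
    }
    return d


def phantom_config_from_dict(d: dict[str, Any]) -> PhantomConfig:
    d = dict(d)
    if "constants" in d and isinstance(d["constants"], dict):
        d["constants"] = QuantConstants(**d["constants"])
    if "roi_specs" in d:
        d["roi_specs"] = {
            name: RoiSpec(tuple(s["center_frac"]), tuple(s["size_vox"]))
            for name, s in d["roi_specs"].items()
        }
    for key in ("grid_shape", "voxel_size_mm", "groups", "conditions", "scanners", "rating_link"):
        if key in d and isinstance(d[key], list):
            d[key] = tuple(d[key])
    return PhantomConfig(**d)
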