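"""File formats: NIfTI volumes, TSV manifests, JSON sidecars, YAML configs."""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .errors import InputError
from .phantom import (
    PhantomConfig,
    PhantomTruth,
    phantom_config_from_dict,
    phantom_config_to_dict,
)
from .quantify import AslSession, PerfusionMap, QuantConstants

MANIFEST_COLUMNS = ["session_id", "subject_id", "group", "condition", "scanner", "rating_prescan"]
MANIFEST_SCHEMA_VERSION = 1


def save_volume(path: Path | str, data: np.ndarray, affine: np.ndarray) -> None:
    nib.save(nib.Nifti1Image(np.asarray(data, dtype=np.float64), np.asarray(affine)), str(path))


def load_volume(path: Path | str) -> tuple[np.ndarray, np.ndarray]:
    img = nib.load(str(path))
    return np.asarray(img.get_fdata(), dtype=float), np.asarray(img.affine, dtype=float)


def check_affine_match(a: np.ndarray, b: np.ndarray, what: str = "volumes") -> None:
    if not np.allclose(a, b, atol=1e-6):
        raise InputError(f"affine mismatch between {what}:\n{a}\nvs\n{b}")


def save_perfusion_map(pmap: PerfusionMap, path: Path | str) -> None:
    """NIfTI map + JSON provenance sidecar (same stem, .json)."""
    path = Path(path)
    save_volume(path, np.where(pmap.mask, pmap.cbf, np.nan), pmap.affine)
    sidecar = path.with_suffix("").with_suffix(".json") if path.suffix == ".gz" else path.with_suffix(".json")
    sidecar.write_text(json.dumps(pmap.provenance, indent=2, default=str))


def load_perfusion_map(path: Path | str) -> PerfusionMap:
    path = Path(path)
    data, affine = load_volume(path)
    sidecar = path.with_suffix("").with_suffix(".json") if path.suffix == ".gz" else path.with_suffix(".json")
    provenance = json.loads(sidecar.read_text()) if sidecar.exists() else {}
    mask = np.isfinite(data)
    return PerfusionMap(cbf=data, mask=mask, affine=affine, provenance=provenance)


def write_session(session: AslSession, out_dir: Path | str) -> Path:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    save_volume(out_dir / "series.nii.gz", session.series, session.affine)
    save_volume(out_dir / "csf.nii.gz", session.csf_scan, session.affine)
    save_volume(out_dir / "csf_mask.nii.gz", session.csf_mask.astype(float), session.affine)
    save_volume(out_dir / "brain_mask.nii.gz", session.brain_mask.astype(float), session.affine)
    save_volume(out_dir / "min_contrast_1.nii.gz", session.min_contrast_reps[0], session.affine)
    save_volume(out_dir / "min_contrast_2.nii.gz", session.min_contrast_reps[1], session.affine)
    meta = {
        "tr_ms": session.tr_ms,
        "ti1_ms": session.ti1_ms,
        "ti2_ms": session.ti2_ms,
        "slice_duration_ms": session.slice_duration_ms,
        "tag_first": session.tag_first,
        "meta": session.meta,
    }
    (out_dir / "session.json").write_text(json.dumps(meta, indent=2, default=str))
    return out_dir


def read_session(session_dir: Path | str) -> AslSession:
    session_dir = Path(session_dir)
    series, affine = load_volume(session_dir / "series.nii.gz")
    csf, a2 = load_volume(session_dir / "csf.nii.gz")
    check_affine_match(affine, a2, "series and CSF scan")
    csf_mask, a3 = load_volume(session_dir / "csf_mask.nii.gz")
    check_affine_match(affine, a3, "series and CSF mask")
    brain_mask, _ = load_volume(session_dir / "brain_mask.nii.gz")
    rep1, _ = load_volume(session_dir / "min_contrast_1.nii.gz")
    rep2, _ = load_volume(session_dir / "min_contrast_2.nii.gz")
    meta = json.loads((session_dir / "session.json").read_text())
    return AslSession(
        series=series,
        tr_ms=meta["tr_ms"],
        ti1_ms=meta["ti1_ms"],
        ti2_ms=meta["ti2_ms"],
        slice_duration_ms=meta["slice_duration_ms"],
        csf_scan=csf,
        csf_mask=csf_mask > 0.5,
        min_contrast_reps=(rep1, rep2),
        brain_mask=brain_mask > 0.5,
        affine=affine,
        meta=meta.get("meta", {}),
        tag_first=meta.get("tag_first", True),
    )


def session_id(subject_id: str, condition: str) -> str:
    return f"{subject_id}_{condition}"


def write_manifest(df: pd.DataFrame, path: Path | str) -> None:
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise InputError(f"manifest missing columns {missing}")
    df[MANIFEST_COLUMNS].to_csv(path, sep="\t", index=False)


def read_manifest(
    path: Path | str,
    known_groups: tuple[str, ...] = ("control", "patient"),
    known_conditions: tuple[str, ...] = ("hungry", "fed"),
) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise InputError(f"manifest missing columns {missing}")
    for i, row in df.iterrows():
        if row["condition"] not in known_conditions:
            raise InputError(
                f"manifest row {i} (session {row['session_id']}): unknown condition {row['condition']!r}"
            )
        if row["group"] not in known_groups:
            raise InputError(
                f"manifest row {i} (session {row['session_id']}): unknown group {row['group']!r}"
            )
    return df


def write_phantom_dataset(truth: PhantomTruth, out_dir: Path | str) -> Path:
    """Serialize a full phantom cohort: sessions, fractions, ROIs, truth sidecar."""
    from .phantom import simulate_asl_session, simulate_ratings

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    config = truth.config
    affine = config.affine

    save_volume(out_dir / "gm.nii.gz", truth.gm, affine)
    save_volume(out_dir / "wm.nii.gz", truth.wm, affine)
    save_volume(out_dir / "csf_frac.nii.gz", truth.csf, affine)
    save_volume(out_dir / "brain_mask.nii.gz", truth.brain_mask.astype(float), affine)
    save_volume(out_dir / "coil_field_truth.nii.gz", truth.coil_field_truth, affine)
    roi_dir = out_dir / "rois"
    roi_dir.mkdir(exist_ok=True)
    for name, mask in truth.roi_masks.items():
        save_volume(roi_dir / f"{name}.nii.gz", mask.astype(float), affine)

    ratings = simulate_ratings(truth, config)
    (out_dir / "truth_cbf").mkdir(exist_ok=True)
    rows = []
    for _, srow in truth.subjects.iterrows():
        for condition in config.conditions:
            sid = session_id(srow["subject_id"], condition)
            session = simulate_asl_session(truth, srow["subject_id"], condition, config)
            write_session(session, out_dir / "sessions" / sid)
            save_volume(out_dir / "truth_cbf" / f"{sid}.nii.gz",
                        truth.cbf_truth[(srow["subject_id"], condition)], affine)
            sel = (ratings["subject_id"] == srow["subject_id"]) & (ratings["condition"] == condition)
            rating = float(ratings.loc[sel, "rating"].iloc[0])
            rows.append(
                {
                    "session_id": sid,
                    "subject_id": srow["subject_id"],
                    "group": srow["group"],
                    "condition": condition,
                    "scanner": srow["scanner"],
                    "rating_prescan": rating,
                }
            )
    write_manifest(pd.DataFrame(rows), out_dir / "manifest.tsv")
    sidecar = {
        "schema_version": MANIFEST_SCHEMA_VERSION,
        "seed": truth.seed,
        "m0_csf_truth": truth.m0_csf_truth,
        "m0_blood_truth": truth.m0_blood_truth,
        "config": phantom_config_to_dict(config),
        "ratings_truth": truth.ratings_truth.to_dict(orient="records"),
    }
    (out_dir / "truth.json").write_text(json.dumps(sidecar, indent=2, default=str))
    return out_dir


@dataclass
class StatsSettings:
    voxel_p: float = 0.001
    cluster_p: float = 0.05
    n_perm: int = 10_000
    connectivity: str = "faces"
    scheme: str = "label"


@dataclass
class AssocSettings:
    tuning: float = 1.345
    m_tests: int = 6
    alpha: float = 0.05


@dataclass
class RunConfig:
    """End-to-end run configuration; YAML round-trips losslessly."""

    phantom: PhantomConfig = field(default_factory=PhantomConfig)
    constants: QuantConstants = field(default_factory=QuantConstants)
    stats: StatsSettings = field(default_factory=StatsSettings)
    assoc: AssocSettings = field(default_factory=AssocSettings)
    pvc_smooth_fwhm_mm: float = 4.0
    target_voxel_mm: tuple[float, float, float] = (3.0, 3.0, 3.0)
    seed: int = 0
    log_level: str = "INFO"

    def to_dict(self) -> dict[str, Any]:
        return {
            "phantom": phantom_config_to_dict(self.phantom),
            "constants": dataclasses.asdict(self.constants),
            "stats": dataclasses.asdict(self.stats),
            "assoc": dataclasses.asdict(self.assoc),
            "pvc_smooth_fwhm_mm": self.pvc_smooth_fwhm_mm,
            "target_voxel_mm": list(self.target_voxel_mm),
            "seed": self.seed,
            "log_level": self.log_level,
        }

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "RunConfig":
        d = dict(d)
        kwargs: dict[str, Any] = {}
        if "phantom" in d:
            kwargs["phantom"] = phantom_config_from_dict(d["phantom"])
        if "constants" in d:
            kwargs["constants"] = QuantConstants(**d["constants"])
        if "stats" in d:
            kwargs["stats"] = StatsSettings(**d["stats"])
        if "assoc" in d:
            kwargs["assoc"] = AssocSettings(**d["assoc"])
        for key in ("pvc_smooth_fwhm_mm", "seed", "log_level"):
            if key in d:
                kwargs[key] = d[key]
        if "target_voxel_mm" in d:
            kwargs["target_voxel_mm"] = tuple(d["target_voxel_mm"])
        return cls(**kwargs)


def save_run_config(config: RunConfig, path: Path | str) -> None:
    Path(path).write_text(yaml.safe_dump(config.to_dict(), sort_keys=False))


def load_run_config(path: Path | str) -> RunConfig:
    return RunConfig.from_dict(yaml.safe_load(Path(path).read_text()))
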