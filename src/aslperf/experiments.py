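"""Cohort-level simulation experiments used for calibration and validation.

These functions run the package's own stages end to end on freshly
generated phantoms and measure recovery, calibration and error-rate
properties (round-trip bias, cluster-level false-positive rate, planted
effect-direction recovery, association detection).  They are used by the
test suite and by the reproduction script, and are exported so users can
rerun the same experiments at other settings.
"""

from __future__ import annotations

import dataclasses
from typing import Any

import numpy as np
import pandas as pd

from .assoc import association_scan
from .phantom import (
    PhantomConfig,
    PhantomTruth,
    make_phantom,
    simulate_asl_session,
    simulate_ratings,
)
from .pvc import TissueFractions, pvc_pipeline
from .quantify import PerfusionMap, quantify_session
from .stats import RoiSet, group_contrast, hungry_minus_fed, roi_means

SEARCH_ROIS = ("vst", "vmpfc", "insula")


def zero_effects() -> dict[str, dict[str, float]]:
    return {
        roi: {"control": 0.0, "patient": 0.0}
        for roi in ("vst", "vmpfc", "insula", "hypothalamus")
    }


def null_cohort_config(seed: int, **overrides: Any) -> PhantomConfig:
    """A reduced-size cohort with no planted effects, for error-rate studies.

    Scaled to 10 subjects per group, 6 tag/control pairs and a 16x16x8 grid
    so hundreds of replicates stay cheap; every stochastic component of the
    acquisition (thermal noise, drift, coil field) keeps its default value.
    """
    params: dict[str, Any] = dict(
        grid_shape=(16, 16, 8),
        n_pairs=6,
        n_per_group={"control": 10, "patient": 10},
        roi_effects=zero_effects(),
        seed=seed,
    )
    params.update(overrides)
    return PhantomConfig(**params)


def quantify_cohort(
    truth: PhantomTruth, config: PhantomConfig
) -> dict[tuple[str, str], PerfusionMap]:
    """Simulate and fully process (quantify + PVC stages) every session."""
    fractions = TissueFractions(gm=truth.gm, wm=truth.wm, csf=truth.csf, affine=config.affine)
    maps: dict[tuple[str, str], PerfusionMap] = {}
    for _, row in truth.subjects.iterrows():
        for condition in config.conditions:
            session = simulate_asl_session(truth, row["subject_id"], condition, config)
            pmap = quantify_session(session, config.constants)
            maps[(row["subject_id"], condition)] = pvc_pipeline(pmap, fractions)
    return maps


def cohort_differences(
    truth: PhantomTruth,
    config: PhantomConfig,
    maps: dict[tuple[str, str], PerfusionMap] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Stacked per-subject Hungry - Fed maps for (group A, group B)."""
    if maps is None:
        maps = quantify_cohort(truth, config)
    diffs: dict[str, list[np.ndarray]] = {g: [] for g in config.groups}
    for _, row in truth.subjects.iterrows():
        diff, _ = hungry_minus_fed({c: maps[(row["subject_id"], c)] for c in config.conditions})
        diffs[row["group"]].append(np.nan_to_num(diff))
    return np.stack(diffs[config.groups[0]]), np.stack(diffs[config.groups[1]])


def gm_recovery_bias(seed: int, noiseless: bool = False) -> float:
    """Relative bias of recovered GM CBF for one single-subject phantom."""
    if noiseless:
        from .phantom import noiseless_config

        cfg = noiseless_config(n_per_group={"control": 1, "patient": 1}, seed=seed)
    else:
        cfg = PhantomConfig(n_per_group={"control": 1, "patient": 1}, seed=seed)
    truth = make_phantom(cfg)
    session = simulate_asl_session(truth, "control01", "hungry", cfg)
    pmap = quantify_session(session, cfg.constants)
    gm_mask = (truth.gm > 0.99) & pmap.mask
    recovered = float(np.nanmean(pmap.cbf[gm_mask]))
    expected = float(truth.cbf_truth[("control01", "hungry")][gm_mask].mean())
    return recovered / expected - 1.0


def null_fwer_replicate(seed: int, roi: str = "vst", n_perm: int = 1000) -> bool:
    """One null-cohort replicate: True when any cluster survives the threshold.

    The cluster-extent threshold is derived from the replicate's own
    randomization null and then applied to the observed (null) data, so the
    long-run fraction of True estimates the cluster-level family-wise
    false-positive rate for one search ROI.
    """
    cfg = null_cohort_config(seed)
    truth = make_phantom(cfg)
    diffs_a, diffs_b = cohort_differences(truth, cfg)
    roi_set = RoiSet(masks=dict(truth.roi_masks), affine=cfg.affine)
    res = group_contrast(
        diffs_a, diffs_b, roi_set, roi, n_perm=n_perm, seed=int(seed) + 90_001
    )
    return len(res.clusters) > 0


def direction_replicate(
    seed: int, n_perm: int = 1000
) -> dict[str, Any]:
    """Planted opposite-sign effects at default study conditions: recovery check.

    Returns per-replicate indicators: correct group-mean signs in every
    planted ROI (controls positive, patients negative hungry-minus-fed),
    whether any cluster was detected per ROI, and whether all reported
    cluster voxels lie inside planted ROIs.
    """
    cfg = PhantomConfig(seed=seed)
    truth = make_phantom(cfg)
    diffs_a, diffs_b = cohort_differences(truth, cfg)
    planted = [
        roi for roi in SEARCH_ROIS
        if any(v != 0 for v in cfg.roi_effects.get(roi, {}).values())
    ]
    signs_ok = True
    for roi in planted:
        mean_control = float(roi_means(diffs_a, truth.roi_masks[roi]).mean())
        mean_patient = float(roi_means(diffs_b, truth.roi_masks[roi]).mean())
        if not (mean_control > 0 and mean_patient < 0):
            signs_ok = False
    roi_set = RoiSet(masks=dict(truth.roi_masks), affine=cfg.affine)
    planted_union = np.zeros(cfg.grid_shape, dtype=bool)
    for roi in planted:
        planted_union |= truth.roi_masks[roi]
    confined = True
    detected: dict[str, bool] = {}
    for i, roi in enumerate(SEARCH_ROIS):
        res = group_contrast(
            diffs_a, diffs_b, roi_set, roi, n_perm=n_perm, seed=int(seed) + 70_001 + i
        )
        detected[roi] = len(res.clusters) > 0
        if len(res.clusters) and roi not in planted:
            confined = False
    return {"signs_ok": signs_ok, "confined": confined, "detected": detected}


def truth_roi_cbf_table(truth: PhantomTruth, config: PhantomConfig) -> pd.DataFrame:
    """Per-session ROI-mean ground-truth CBF in the association-scan schema."""
    rows = []
    for _, row in truth.subjects.iterrows():
        for condition in config.conditions:
            for roi in SEARCH_ROIS:
                rows.append(
                    {
                        "subject_id": row["subject_id"],
                        "group": row["group"],
                        "condition": condition,
                        "region": roi,
                        "cbf": truth.roi_mean_truth(row["subject_id"], condition, roi),
                    }
                )
    return pd.DataFrame(rows)


def association_replicate(seed: int, rating_slope: float | None = None) -> dict[str, Any]:
    """One association-scan run on a phantom with the given planted slope.

    Regional CBF enters at ground-truth resolution (the scan's sensitivity
    to imaging noise is exercised separately through the full pipeline);
    ratings carry their configured noise.  Returns which cells were flagged.
    """
    overrides: dict[str, Any] = {"seed": seed}
    if rating_slope is not None:
        overrides["rating_slope"] = rating_slope
    cfg = PhantomConfig(**overrides)
    truth = make_phantom(cfg)
    table = association_scan(
        truth_roi_cbf_table(truth, cfg), simulate_ratings(truth, cfg), m_tests=6
    )
    link_group, link_condition, link_roi = cfg.rating_link
    planted_cell = table[
        (table["group"] == link_group)
        & (table["condition"] == link_condition)
        & (table["region"] == link_roi)
    ]
    other_group = table[table["group"] != link_group]
    return {
        "planted_flagged": bool(planted_cell["significant"].iloc[0]),
        "other_group_flagged": bool(other_group["significant"].any()),
        "n_cells": int(len(table)),
        "n_flagged": int(table["significant"].sum()),
    }


def pooled_t_discrepancy(n_cohorts: int, seed: int) -> float:
    """Max |GLM t - closed-form pooled t| over random small cohorts.

    The oracle is the textbook pooled two-sample t computed directly from
    group means and variances, evaluated voxel-wise on random data.
    """
    from .stats import voxelwise_group_ttest

    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_cohorts):
        n_a = int(rng.integers(3, 8))
        n_b = int(rng.integers(3, 8))
        n_vox = int(rng.integers(2, 12))
        a = rng.normal(size=(n_a, n_vox, 1, 1))
        b = rng.normal(size=(n_b, n_vox, 1, 1))
        t_map, df = voxelwise_group_ttest(a, b)
        m_a, m_b = a.mean(axis=0), b.mean(axis=0)
        v_a, v_b = a.var(axis=0, ddof=1), b.var(axis=0, ddof=1)
        sp2 = ((n_a - 1) * v_a + (n_b - 1) * v_b) / (n_a + n_b - 2)
        t_ref = (m_a - m_b) / np.sqrt(sp2 * (1 / n_a + 1 / n_b))
        worst = max(worst, float(np.abs(t_map - t_ref).max()))
        assert df == n_a + n_b - 2
    return worst
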