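"""End-to-end driver: simulate -> quantify -> pvc -> diffs -> contrast -> associate.

Every stage logs its parameters and timing; the run directory receives the
resolved configuration, a cluster table, the whole-ROI test, anatomical
effect sizes and the association table, all as TSV/JSON so reruns with the
same seed are byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from . import io as aio
from .assoc import association_scan
from .errors import InputError
from .phantom import PhantomTruth, make_phantom, simulate_asl_session, simulate_ratings
from .pvc import TissueFractions, pvc_pipeline, screen_outliers
from .quantify import PerfusionMap, quantify_session
from .stats import (
    RoiSet,
    cohens_d_anatomical_roi,
    group_contrast,
    hungry_minus_fed,
    roi_means,
    whole_roi_ttest,
)

logger = logging.getLogger(__name__)


@dataclass
class PipelineResult:
    cluster_table: pd.DataFrame
    whole_roi: pd.DataFrame
    effect_sizes: pd.DataFrame
    associations: pd.DataFrame
    exclusions: pd.DataFrame
    diffs: dict[str, np.ndarray] = field(default_factory=dict)
    truth: PhantomTruth | None = None
    run_record: dict[str, Any] = field(default_factory=dict)


def _scanner_covariate(groups_df: pd.DataFrame, scanners: tuple[str, ...]) -> np.ndarray:
    codes = pd.Categorical(groups_df["scanner"], categories=list(scanners)).codes
    return codes.astype(float)[:, None]


def run_pipeline(config: aio.RunConfig, out_dir: Path | str | None = None) -> PipelineResult:
    """Run the whole analysis on a freshly generated phantom cohort."""
    record: dict[str, Any] = {"config": config.to_dict(), "stages": []}

    def stage(name: str, **params: Any):
        t0 = time.perf_counter()
        logger.info("stage %s: %s", name, params)

        def done():
            record["stages"].append(
                {"stage": name, "params": params, "seconds": round(time.perf_counter() - t0, 3)}
            )

        return done

    pcfg = dataclasses.replace(config.phantom, seed=config.seed, constants=config.constants)

    done = stage("simulate", seed=config.seed)
    truth = make_phantom(pcfg)
    done()

    conditions = pcfg.conditions
    fractions = TissueFractions(gm=truth.gm, wm=truth.wm, csf=truth.csf, affine=pcfg.affine)

    done = stage("quantify_and_pvc", smooth_fwhm_mm=config.pvc_smooth_fwhm_mm)
    maps: dict[tuple[str, str], PerfusionMap] = {}
    for _, row in truth.subjects.iterrows():
        for condition in conditions:
            session = simulate_asl_session(truth, row["subject_id"], condition, pcfg)
            pmap = quantify_session(session, config.constants)
            pmap = pvc_pipeline(
                pmap,
                fractions,
                smooth_fwhm_mm=config.pvc_smooth_fwhm_mm,
                target_voxel_mm=config.target_voxel_mm,
            )
            maps[(row["subject_id"], condition)] = pmap
    done()

    done = stage("screen_outliers")
    ids = [aio.session_id(s, c) for (s, c) in maps]
    kept_idx, exclusions = screen_outliers(list(maps.values()), ids=ids)
    kept_ids = {ids[i] for i in kept_idx}
    done()

    done = stage("differences")
    diffs: dict[str, np.ndarray] = {}
    for _, row in truth.subjects.iterrows():
        sid = row["subject_id"]
        if not all(aio.session_id(sid, c) in kept_ids for c in conditions):
            logger.warning("subject %s dropped by quality screening", sid)
            continue
        diff, _ = hungry_minus_fed({c: maps[(sid, c)] for c in conditions})
        diffs[sid] = diff
    done()

    groups_df = truth.subjects[truth.subjects["subject_id"].isin(diffs)].reset_index(drop=True)
    group_a, group_b = pcfg.groups
    ids_a = groups_df.loc[groups_df["group"] == group_a, "subject_id"].tolist()
    ids_b = groups_df.loc[groups_df["group"] == group_b, "subject_id"].tolist()
    if len(ids_a) < 2 or len(ids_b) < 2:
        raise InputError("fewer than 2 usable subjects per group after screening")
    diffs_a = np.stack([diffs[s] for s in ids_a])
    diffs_b = np.stack([diffs[s] for s in ids_b])
    ordered = pd.concat(
        [
            groups_df.set_index("subject_id").loc[ids_a].reset_index(),
            groups_df.set_index("subject_id").loc[ids_b].reset_index(),
        ]
    )
    covariates = _scanner_covariate(ordered, pcfg.scanners)

    search_rois = tuple(n for n in truth.roi_masks if n != "hypothalamus")
    roi_set = RoiSet(
        masks=dict(truth.roi_masks),
        affine=pcfg.affine,
        search_rois=search_rois,
        whole_rois=("hypothalamus",) if "hypothalamus" in truth.roi_masks else (),
    )

    done = stage("contrast", n_perm=config.stats.n_perm, voxel_p=config.stats.voxel_p,
                 cluster_p=config.stats.cluster_p)
    cluster_tables = []
    for i, roi in enumerate(search_rois):
        res = group_contrast(
            diffs_a,
            diffs_b,
            roi_set,
            roi,
            voxel_p=config.stats.voxel_p,
            cluster_p=config.stats.cluster_p,
            n_perm=config.stats.n_perm,
            seed=int(config.seed) + 1000 + i,
            covariates=covariates,
        )
        tab = res.clusters.copy()
        tab["k_min"] = res.threshold.k_min
        tab["k_min_ul"] = res.threshold.k_min_ul
        cluster_tables.append(tab)
        record["stages"].append(
            {
                "stage": f"cluster_threshold[{roi}]",
                "k_min": res.threshold.k_min,
                "n_perm": res.threshold.n_perm,
                "exhaustive": res.threshold.exhaustive,
            }
        )
    cluster_table = (
        pd.concat(cluster_tables, ignore_index=True)
        if cluster_tables
        else pd.DataFrame()
    )
    done()

    done = stage("whole_roi")
    whole_rows = []
    for roi in roi_set.whole_rois:
        res = whole_roi_ttest(diffs_a, diffs_b, truth.roi_masks[roi])
        whole_rows.append(
            {
                "roi": roi,
                "t": res.t,
                "p": res.p,
                "df": res.df,
                f"mean_{group_a}": res.mean_a,
                f"mean_{group_b}": res.mean_b,
            }
        )
    whole_roi = pd.DataFrame(whole_rows)
    done()

    done = stage("effect_sizes")
    effect_rows = []
    for roi in truth.roi_masks:
        effect_rows.append(
            {
                "roi": roi,
                "cohens_d": cohens_d_anatomical_roi(diffs_a, diffs_b, truth.roi_masks[roi]),
                f"mean_{group_a}": float(roi_means(diffs_a, truth.roi_masks[roi]).mean()),
                f"mean_{group_b}": float(roi_means(diffs_b, truth.roi_masks[roi]).mean()),
            }
        )
    effect_sizes = pd.DataFrame(effect_rows)
    done()

    done = stage("associate", m_tests=config.assoc.m_tests)
    ratings = simulate_ratings(truth, pcfg)
    cbf_rows = []
    for _, row in groups_df.iterrows():
        for condition in conditions:
            pmap = maps[(row["subject_id"], condition)]
            for roi in search_rois:
                cbf_rows.append(
                    {
                        "subject_id": row["subject_id"],
                        "group": row["group"],
                        "condition": condition,
                        "region": roi,
                        "cbf": float(np.nanmean(pmap.cbf[truth.roi_masks[roi] & pmap.mask])),
                    }
                )
    cbf_table = pd.DataFrame(cbf_rows)
    associations = association_scan(
        cbf_table,
        ratings,
        m_tests=config.assoc.m_tests,
        alpha=config.assoc.alpha,
        tuning=config.assoc.tuning,
    )
    done()

    result = PipelineResult(
        cluster_table=cluster_table,
        whole_roi=whole_roi,
        effect_sizes=effect_sizes,
        associations=associations,
        exclusions=exclusions,
        diffs=diffs,
        truth=truth,
        run_record=record,
    )

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        cluster_table.to_csv(out_dir / "cluster_table.tsv", sep="\t", index=False)
        whole_roi.to_csv(out_dir / "whole_roi.tsv", sep="\t", index=False)
        effect_sizes.to_csv(out_dir / "effect_sizes.tsv", sep="\t", index=False)
        associations.to_csv(out_dir / "associations.tsv", sep="\t", index=False)
        exclusions.to_csv(out_dir / "exclusions.tsv", sep="\t", index=False)
        (out_dir / "run_record.json").write_text(json.dumps(record, indent=2, default=str))
        aio.save_run_config(config, out_dir / "config.yaml")
    return result


def render_report(run_dir: Path | str) -> str:
    """Human-readable summary of a finished run, mirroring the cluster-table layout."""
    run_dir = Path(run_dir)
    lines = []
    clusters = pd.read_csv(run_dir / "cluster_table.tsv", sep="\t")
    lines.append("Group contrast (Hungry - Fed), significant clusters")
    lines.append("=" * 60)
    if clusters.empty:
        lines.append("(no clusters survived the randomization threshold)")
    else:
        cols = ["roi", "side", "direction", "volume_ul", "peak_i", "peak_j", "peak_k", "peak_t"]
        lines.append(clusters[cols].to_string(index=False))
    whole = pd.read_csv(run_dir / "whole_roi.tsv", sep="\t")
    if not whole.empty:
        lines.append("")
        lines.append("Whole-ROI tests")
        lines.append(whole.to_string(index=False))
    effects = pd.read_csv(run_dir / "effect_sizes.tsv", sep="\t")
    lines.append("")
    lines.append("Anatomical-ROI effect sizes (Cohen's d on ROI-averaged contrast)")
    lines.append(effects.to_string(index=False))
    assoc_path = run_dir / "associations.tsv"
    if assoc_path.exists():
        lines.append("")
        lines.append("Rating-CBF robust associations (Bonferroni-adjusted)")
        lines.append(pd.read_csv(assoc_path, sep="\t").to_string(index=False))
    return "\n".join(lines)
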