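"""Group statistics for the Hungry - Fed perfusion contrast.

The contrast is tested voxel-wise inside a small set of a-priori search
ROIs.  Cluster-level significance uses a randomization scheme: group labels
are permuted, the voxel-wise t-map is recomputed for each relabeling,
binarized at the voxel threshold, and the maximum suprathreshold cluster
extent inside the ROI is recorded; the observed clusters are then required
to exceed the (1 - cluster_p) quantile of that null distribution.  No
parametric model of the spatial autocorrelation is involved.  A structure
too small for cluster inference (the hypothalamus) is instead tested on
its whole-ROI mean.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations
from typing import Any

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy import stats as sps

from .errors import InputError
from .quantify import PerfusionMap

FACE_CONNECTIVITY = ndimage.generate_binary_structure(3, 1)


@dataclass
class RoiSet:
    """Named binary ROI masks sharing one grid, plus grid metadata."""

    masks: dict[str, np.ndarray]
    affine: np.ndarray
    search_rois: tuple[str, ...] = ()
    whole_rois: tuple[str, ...] = ()
    k_min: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        shapes = {m.shape for m in self.masks.values()}
        if len(shapes) > 1:
            raise InputError("ROI masks differ in shape")
        for name, mask in self.masks.items():
            self.masks[name] = np.asarray(mask, dtype=bool)
            if not self.masks[name].any():
                raise InputError(f"ROI {name!r} is empty")

    @property
    def voxel_volume_ul(self) -> float:
        return float(abs(np.linalg.det(self.affine[:3, :3])))


@dataclass
class ClusterThreshold:
    """Randomization-derived minimum cluster extent for one ROI."""

    k_min: int
    k_min_ul: float
    cluster_p: float
    voxel_p: float
    n_perm: int
    exhaustive: bool
    mc_se: float
    seed: int | None
    null_max_sizes: np.ndarray | None = None


@dataclass
class ContrastResult:
    """Voxel t-map plus cluster-level inference for one search ROI."""

    roi: str
    t_map: np.ndarray
    df: int
    voxel_p: float
    cluster_p: float
    threshold: ClusterThreshold
    clusters: pd.DataFrame
    n_permutations: int
    seed: int | None


def hungry_minus_fed(maps_by_condition: dict[str, PerfusionMap]) -> tuple[np.ndarray, np.ndarray]:
    """Per-subject voxel-wise Hungry - Fed difference on the common valid grid."""
    try:
        hungry = maps_by_condition["hungry"]
        fed = maps_by_condition["fed"]
    except KeyError as exc:
        raise InputError("both 'hungry' and 'fed' maps are required") from exc
    if hungry.cbf.shape != fed.cbf.shape:
        raise InputError("condition maps are on different grids")
    mask = hungry.mask & fed.mask
    diff = np.where(mask, hungry.cbf - fed.cbf, np.nan)
    return diff, mask


def _design_matrix(n_a: int, n_b: int, covariates: np.ndarray | None) -> np.ndarray:
    g = np.concatenate([np.ones(n_a), np.zeros(n_b)])
    cols = [np.ones(n_a + n_b), g]
    if covariates is not None:
        covariates = np.atleast_2d(np.asarray(covariates, dtype=float))
        if covariates.shape[0] != n_a + n_b:
            covariates = covariates.T
        if covariates.shape[0] != n_a + n_b:
            raise InputError("covariate rows must match the number of subjects")
        cols.extend(covariates.T)
    X = np.column_stack(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise InputError("rank-deficient design matrix (collinear covariates?)")
    return X


def _glm_t(Y: np.ndarray, X: np.ndarray, coef_index: int = 1) -> tuple[np.ndarray, int]:
    """t-statistic of one coefficient of a per-column least-squares fit.

    Y is (n_subjects, n_voxels); returns (t per voxel, residual df).
    """
    n, p = X.shape
    df = n - p
    if df <= 0:
        raise InputError("not enough subjects for the requested design")
    xtx_inv = np.linalg.inv(X.T @ X)
    beta = xtx_inv @ (X.T @ Y)
    resid = Y - X @ beta
    sigma2 = (resid ** 2).sum(axis=0) / df
    se = np.sqrt(sigma2 * xtx_inv[coef_index, coef_index])
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, beta[coef_index] / se, 0.0)
    return t, df


def voxelwise_group_ttest(
    diffs_a: np.ndarray,
    diffs_b: np.ndarray,
    covariates: np.ndarray | None = None,
    mask: np.ndarray | None = None,
) -> tuple[np.ndarray, int]:
    """Per-voxel group comparison via a linear model (group + covariates).

    ``diffs_a``/``diffs_b`` are stacked subject volumes, shape
    ``(n_subjects, x, y, z)``.  With no covariates the group t equals the
    textbook pooled two-sample t exactly.  Returns ``(t_map, df)`` with the
    sign convention group A minus group B.
    """
    diffs_a = np.asarray(diffs_a, dtype=float)
    diffs_b = np.asarray(diffs_b, dtype=float)
    n_a, n_b = diffs_a.shape[0], diffs_b.shape[0]
    if n_a < 2 or n_b < 2:
        raise InputError("each group needs at least 2 subjects")
    vol_shape = diffs_a.shape[1:]
    if diffs_b.shape[1:] != vol_shape:
        raise InputError("group stacks are on different grids")
    if mask is None:
        mask = np.ones(vol_shape, dtype=bool)
    X = _design_matrix(n_a, n_b, covariates)
    Y = np.concatenate([diffs_a, diffs_b], axis=0)[:, mask]
    t, df = _glm_t(Y, X)
    t_map = np.full(vol_shape, np.nan)
    t_map[mask] = t
    return t_map, df


def _max_cluster_size(
    sup: np.ndarray, bbox_shape: tuple[int, ...], coords: tuple[np.ndarray, ...]
) -> int:
    """Largest face-connected component among suprathreshold ROI voxels."""
    vol = np.zeros(bbox_shape, dtype=bool)
    vol[coords] = sup
    labels, n = ndimage.label(vol, structure=FACE_CONNECTIVITY)
    if n == 0:
        return 0
    return int(np.bincount(labels.ravel())[1:].max())


def _perm_t_two_sample(Y: np.ndarray, assign: np.ndarray) -> np.ndarray:
    """Pooled two-sample t for many permutations at once.

    Y is (n, v); assign is (n_perm, n) boolean, True = group A.  Returns
    (n_perm, v) t-values.
    """
    n = Y.shape[0]
    n_a = int(assign[0].sum())
    n_b = n - n_a
    A = assign.astype(float)
    s1 = A @ Y
    s2 = (1.0 - A) @ Y
    sq1 = A @ (Y ** 2)
    sq2 = (1.0 - A) @ (Y ** 2)
    m1, m2 = s1 / n_a, s2 / n_b
    ss1 = sq1 - n_a * m1 ** 2
    ss2 = sq2 - n_b * m2 ** 2
    sp2 = (ss1 + ss2) / (n_a + n_b - 2)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (m1 - m2) / np.sqrt(sp2 * (1.0 / n_a + 1.0 / n_b))
    return np.nan_to_num(t, nan=0.0, posinf=0.0, neginf=0.0)


def randomization_cluster_threshold(
    diffs_a: np.ndarray,
    diffs_b: np.ndarray,
    roi_mask: np.ndarray,
    voxel_p: float = 0.001,
    cluster_p: float = 0.05,
    n_perm: int = 10_000,
    seed: int | None = None,
    covariates: np.ndarray | None = None,
    voxel_volume_ul: float = 27.0,
    exhaustive_limit: int = 20_000,
    keep_null: bool = False,
) -> ClusterThreshold:
    """Minimum cluster extent controlling the cluster-level FWER at ``cluster_p``.

    Group labels are permuted (exhaustively when the number of distinct
    relabelings is below ``exhaustive_limit``, otherwise ``n_perm`` random
    draws); for each relabeling the voxel t-map is recomputed, thresholded
    two-sided at ``voxel_p``, and the maximum face-connected cluster size
    inside ``roi_mask`` recorded.  ``k_min`` is the smallest k with
    P(max cluster >= k) <= cluster_p under that null.  Deterministic given
    ``seed``; the Monte-Carlo standard error of the exceedance estimate is
    reported (0 for exhaustive enumeration).
    """
    roi_mask = np.asarray(roi_mask, dtype=bool)
    if not roi_mask.any():
        raise InputError("ROI mask is empty")
    diffs_a = np.asarray(diffs_a, dtype=float)
    diffs_b = np.asarray(diffs_b, dtype=float)
    n_a, n_b = diffs_a.shape[0], diffs_b.shape[0]
    n = n_a + n_b
    Y = np.concatenate([diffs_a, diffs_b], axis=0)[:, roi_mask]

    n_distinct = math.comb(n, n_a)
    if n_distinct < int(round(1.0 / cluster_p)):
        import warnings

        warnings.warn(
            f"only {n_distinct} distinct relabelings exist; the permutation "
            f"null cannot resolve cluster_p={cluster_p}; enumerating exactly",
            stacklevel=2,
        )
    exhaustive = n_distinct <= exhaustive_limit
    if exhaustive:
        assign = np.zeros((n_distinct, n), dtype=bool)
        for i, combo in enumerate(combinations(range(n), n_a)):
            assign[i, list(combo)] = True
        n_used = n_distinct
    else:
        rng = np.random.default_rng(seed)
        assign = np.zeros((n_perm, n), dtype=bool)
        for i in range(n_perm):
            assign[i, rng.choice(n, size=n_a, replace=False)] = True
        n_used = n_perm

    # t-maps for every relabeling; covariates force a per-permutation GLM
    if covariates is None:
        T = _perm_t_two_sample(Y, assign)
        df = n - 2
    else:
        # relabelings that make the covariate collinear with the permuted
        # group indicator leave the group effect unidentified; drop them
        rows = []
        df = None
        for i in range(n_used):
            order = np.concatenate([np.where(assign[i])[0], np.where(~assign[i])[0]])
            try:
                X = _design_matrix(int(assign[i].sum()), int((~assign[i]).sum()),
                                   np.asarray(covariates)[order])
                t_row, df = _glm_t(Y[order], X)
            except (InputError, np.linalg.LinAlgError):
                continue
            rows.append(t_row)
        if df is None:
            raise InputError("no estimable relabeling exists for this design")
        T = np.asarray(rows)
        n_used = len(rows)
    t_crit = sps.t.ppf(1.0 - voxel_p / 2.0, df)

    # clustering restricted to the ROI bounding box for speed
    idx = np.argwhere(roi_mask)
    lo, hi = idx.min(axis=0), idx.max(axis=0) + 1
    bbox_shape = tuple(hi - lo)
    coords = tuple((idx - lo).T)
    sup_all = np.abs(T) > t_crit
    max_sizes = np.fromiter(
        (_max_cluster_size(sup_all[i], bbox_shape, coords) for i in range(n_used)),
        dtype=int,
        count=n_used,
    )

    k_max = int(roi_mask.sum())
    k_min = k_max + 1
    for k in range(1, k_max + 2):
        exceed = float((max_sizes >= k).mean())
        if exceed <= cluster_p:
            k_min = k
            break
    p_hat = float((max_sizes >= k_min).mean()) if k_min <= k_max else 0.0
    mc_se = 0.0 if exhaustive else math.sqrt(max(p_hat, 1e-12) * (1 - p_hat) / n_used)
    return ClusterThreshold(
        k_min=k_min,
        k_min_ul=k_min * voxel_volume_ul,
        cluster_p=cluster_p,
        voxel_p=voxel_p,
        n_perm=n_used,
        exhaustive=exhaustive,
        mc_se=mc_se,
        seed=seed,
        null_max_sizes=max_sizes if keep_null else None,
    )


def extract_clusters(
    t_map: np.ndarray,
    df: int,
    voxel_p: float,
    k_min: int,
    roi_mask: np.ndarray,
    voxel_volume_ul: float,
    affine: np.ndarray | None = None,
) -> pd.DataFrame:
    """Suprathreshold face-connected clusters of extent >= k_min, per sign.

    Returns one row per surviving cluster with its direction, voxel count,
    volume in uL (count x voxel volume), peak |t| coordinate and peak t.
    """
    roi_mask = np.asarray(roi_mask, dtype=bool)
    t_crit = sps.t.ppf(1.0 - voxel_p / 2.0, df)
    t_clean = np.nan_to_num(np.asarray(t_map, dtype=float), nan=0.0)
    rows = []
    for direction, sup in (("+", (t_clean > t_crit)), ("-", (t_clean < -t_crit))):
        sup = sup & roi_mask
        labels, n = ndimage.label(sup, structure=FACE_CONNECTIVITY)
        for lab in range(1, n + 1):
            member = labels == lab
            size = int(member.sum())
            if size < k_min:
                continue
            tv = np.where(member, np.abs(t_clean), -np.inf)
            peak = np.unravel_index(int(np.argmax(tv)), t_clean.shape)
            rows.append(
                {
                    "direction": direction,
                    "n_voxels": size,
                    "volume_ul": size * voxel_volume_ul,
                    "peak_i": int(peak[0]),
                    "peak_j": int(peak[1]),
                    "peak_k": int(peak[2]),
                    "peak_t": float(t_clean[peak]),
                }
            )
    cols = ["direction", "n_voxels", "volume_ul", "peak_i", "peak_j", "peak_k", "peak_t"]
    out = pd.DataFrame(rows, columns=cols)
    if affine is not None and len(out):
        xyz = (np.asarray(affine) @ np.column_stack(
            [out[["peak_i", "peak_j", "peak_k"]].to_numpy(), np.ones(len(out))]
        ).T).T[:, :3]
        out[["peak_x_mm", "peak_y_mm", "peak_z_mm"]] = xyz
    return out.sort_values(["direction", "n_voxels"], ascending=[True, False]).reset_index(drop=True)


@dataclass
class WholeRoiResult:
    t: float
    p: float
    df: int
    mean_a: float
    mean_b: float
    n_a: int
    n_b: int


def roi_means(diffs: np.ndarray, roi_mask: np.ndarray) -> np.ndarray:
    """Per-subject mean of a stacked volume array within a mask (NaN-aware)."""
    roi_mask = np.asarray(roi_mask, dtype=bool)
    vals = np.asarray(diffs, dtype=float)[:, roi_mask]
    return np.nanmean(vals, axis=1)


def whole_roi_ttest(
    diffs_a: np.ndarray, diffs_b: np.ndarray, roi_mask: np.ndarray
) -> WholeRoiResult:
    """Pooled two-sample t-test on per-subject whole-ROI mean differences."""
    a = roi_means(diffs_a, roi_mask)
    b = roi_means(diffs_b, roi_mask)
    if len(a) < 2 or len(b) < 2:
        raise InputError("each group needs at least 2 subjects")
    res = sps.ttest_ind(a, b, equal_var=True)
    return WholeRoiResult(
        t=float(res.statistic),
        p=float(res.pvalue),
        df=len(a) + len(b) - 2,
        mean_a=float(a.mean()),
        mean_b=float(b.mean()),
        n_a=len(a),
        n_b=len(b),
    )


def cohens_d_anatomical_roi(
    diffs_a: np.ndarray, diffs_b: np.ndarray, roi_mask: np.ndarray
) -> float:
    """Cohen's d of the group difference in ROI-averaged contrast values.

    Computed on the full anatomical ROI average (not on significant
    clusters) to avoid non-independence inflation.
    """
    a = roi_means(diffs_a, roi_mask)
    b = roi_means(diffs_b, roi_mask)
    n_a, n_b = len(a), len(b)
    pooled = math.sqrt(
        ((n_a - 1) * a.var(ddof=1) + (n_b - 1) * b.var(ddof=1)) / (n_a + n_b - 2)
    )
    if pooled == 0:
        return 0.0
    return float((a.mean() - b.mean()) / pooled)


def group_contrast(
    diffs_a: np.ndarray,
    diffs_b: np.ndarray,
    roi_set: RoiSet,
    roi: str,
    voxel_p: float = 0.001,
    cluster_p: float = 0.05,
    n_perm: int = 10_000,
    seed: int | None = None,
    covariates: np.ndarray | None = None,
) -> ContrastResult:
    """Full search-ROI analysis: t-map, randomization threshold, cluster table."""
    roi_mask = roi_set.masks[roi]
    t_map, df = voxelwise_group_ttest(diffs_a, diffs_b, covariates=covariates, mask=roi_mask)
    thr = randomization_cluster_threshold(
        diffs_a,
        diffs_b,
        roi_mask,
        voxel_p=voxel_p,
        cluster_p=cluster_p,
        n_perm=n_perm,
        seed=seed,
        covariates=covariates,
        voxel_volume_ul=roi_set.voxel_volume_ul,
    )
    roi_set.k_min[roi] = thr.k_min
    clusters = extract_clusters(
        t_map, df, voxel_p, thr.k_min, roi_mask, roi_set.voxel_volume_ul, affine=roi_set.affine
    )
    clusters.insert(0, "roi", roi)
    mid_x = (t_map.shape[0] - 1) / 2.0
    clusters.insert(1, "side", ["L" if i <= mid_x else "R" for i in clusters["peak_i"]])
    return ContrastResult(
        roi=roi,
        t_map=t_map,
        df=df,
        voxel_p=voxel_p,
        cluster_p=cluster_p,
        threshold=thr,
        clusters=clusters,
        n_permutations=thr.n_perm,
        seed=seed,
    )
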