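"""Group contrast statistics: GLM t-tests, randomization thresholds, clusters."""

import numpy as np
import pytest
from scipy import stats as sps

from aslperf.errors import InputError
from aslperf.stats import (
    RoiSet,
    cohens_d_anatomical_roi,
    extract_clusters,
    group_contrast,
    hungry_minus_fed,
    randomization_cluster_threshold,
    voxelwise_group_ttest,
    whole_roi_ttest,
)
from conftest import make_map

GRID = (5, 5, 3)


def vols(values):
    """Stack per-subject scalars into constant (n, x, y, z) volumes."""
    return np.stack([np.full(GRID, v, dtype=float) for v in values])


class TestHungryMinusFed:
    def test_identical_maps_give_zero(self):
        m = make_map(np.random.default_rng(0).normal(50, 5, GRID))
        diff, mask = hungry_minus_fed({"hungry": m, "fed": m})
        np.testing.assert_allclose(diff[mask], 0.0)

    def test_constant_shift_recovered(self):
        fed = make_map(np.random.default_rng(1).normal(50, 5, GRID))
        hungry = make_map(fed.cbf + 5.0)
        diff, mask = hungry_minus_fed({"hungry": hungry, "fed": fed})
        np.testing.assert_allclose(diff[mask], 5.0)

    def test_missing_condition_rejected(self):
        with pytest.raises(InputError):
            hungry_minus_fed({"hungry": make_map(np.zeros(GRID))})

    def test_mask_is_intersection(self):
        a = make_map(np.ones(GRID))
        b_mask = np.ones(GRID, bool)
        b_mask[0, 0, 0] = False
        b = make_map(np.where(b_mask, 1.0, np.nan), mask=b_mask)
        _, mask = hungry_minus_fed({"hungry": a, "fed": b})
        assert not mask[0, 0, 0]
        assert mask.sum() == np.prod(GRID) - 1


class TestVoxelwiseTtest:
    def test_closed_form_pooled_t(self):
        t_map, df = voxelwise_group_ttest(vols([1, 2, 3]), vols([4, 5, 6]))
        expected = -3.0 / np.sqrt(1.0 * (1 / 3 + 1 / 3))
        assert df == 4
        np.testing.assert_allclose(t_map, expected, rtol=1e-12)
        assert expected == pytest.approx(-3.674, abs=1e-3)

    def test_identical_groups_give_zero(self):
        t_map, _ = voxelwise_group_ttest(vols([1, 2, 3]), vols([1, 2, 3]))
        np.testing.assert_allclose(t_map, 0.0, atol=1e-12)

    def test_matches_scipy_on_random_cohorts(self, rng):
        for _ in range(20):
            a = rng.normal(size=(5, *GRID))
            b = rng.normal(size=(7, *GRID))
            t_map, df = voxelwise_group_ttest(a, b)
            ref = sps.ttest_ind(a, b, axis=0, equal_var=True)
            np.testing.assert_allclose(t_map, ref.statistic, atol=1e-10)
            assert df == 10

    def test_orthogonal_covariate_leaves_group_slope_unchanged(self, rng):
        # regression algebra: a covariate orthogonal to intercept and group
        # leaves the group coefficient itself untouched; the full fit must
        # agree with an independent normal-equations oracle
        a = rng.normal(size=(6, 1, 1, 1))
        b = rng.normal(size=(6, 1, 1, 1))
        cov = np.concatenate([np.tile([1.0, -1.0], 3), np.tile([1.0, -1.0], 3)])[:, None]
        t_with, df_with = voxelwise_group_ttest(a, b, covariates=cov)
        y = np.concatenate([a, b]).ravel()
        X = np.column_stack([np.ones(12), np.r_[np.ones(6), np.zeros(6)], cov.ravel()])
        beta = np.linalg.lstsq(X, y, rcond=None)[0]
        resid = y - X @ beta
        sigma2 = (resid**2).sum() / (12 - 3)
        se = np.sqrt(sigma2 * np.linalg.inv(X.T @ X)[1, 1])
        assert df_with == 9
        assert t_with[0, 0, 0] == pytest.approx(beta[1] / se, abs=1e-10)
        # group coefficient equals the plain two-group mean difference
        assert beta[1] == pytest.approx(a.mean() - b.mean(), abs=1e-10)

    def test_rank_deficient_design_rejected(self):
        group_copy = np.r_[np.ones(3), np.zeros(3)][:, None]
        with pytest.raises(InputError):
            voxelwise_group_ttest(vols([1, 2, 3]), vols([4, 5, 6]), covariates=group_copy)

    def test_too_few_subjects_rejected(self):
        with pytest.raises(InputError):
            voxelwise_group_ttest(vols([1]), vols([2, 3]))


class TestRandomizationThreshold:
    def make_null(self, seed, n_per_group=8):
        rng = np.random.default_rng(seed)
        a = rng.normal(size=(n_per_group, *GRID))
        b = rng.normal(size=(n_per_group, *GRID))
        return a, b

    def test_single_voxel_roi_k_min_is_one(self):
        a, b = self.make_null(0)
        roi = np.zeros(GRID, bool)
        roi[2, 2, 1] = True
        thr = randomization_cluster_threshold(a, b, roi, n_perm=500, seed=1)
        assert thr.k_min == 1
        assert thr.k_min_ul == pytest.approx(27.0)

    def test_determinism_under_fixed_seed(self):
        a, b = self.make_null(3, n_per_group=12)
        roi = np.ones(GRID, bool)
        t1 = randomization_cluster_threshold(a, b, roi, n_perm=400, seed=7)
        t2 = randomization_cluster_threshold(a, b, roi, n_perm=400, seed=7)
        assert t1.k_min == t2.k_min
        assert t1.n_perm == t2.n_perm

    def test_exhaustive_enumeration_for_small_cohorts(self):
        a, b = self.make_null(4, n_per_group=4)
        thr = randomization_cluster_threshold(a, b, np.ones(GRID, bool), n_perm=10_000, seed=0)
        assert thr.exhaustive
        assert thr.n_perm == 70  # C(8, 4)
        assert thr.mc_se == 0.0

    def test_warning_when_permutations_cannot_resolve_cluster_p(self):
        a, b = self.make_null(5, n_per_group=2)
        with pytest.warns(UserWarning, match="distinct relabelings"):
            randomization_cluster_threshold(a, b, np.ones(GRID, bool), n_perm=100, seed=0)

    def test_empty_roi_rejected(self):
        a, b = self.make_null(6)
        with pytest.raises(InputError):
            randomization_cluster_threshold(a, b, np.zeros(GRID, bool))


class TestExtractClusters:
    def t_field(self, coords, value=10.0):
        t = np.zeros(GRID)
        for c in coords:
            t[c] = value
        return t

    def test_two_face_adjacent_voxels_form_54_microliter_cluster(self):
        t = self.t_field([(1, 1, 1), (1, 2, 1)])
        table = extract_clusters(t, df=20, voxel_p=0.001, k_min=1,
                                 roi_mask=np.ones(GRID, bool), voxel_volume_ul=27.0)
        assert len(table) == 1
        assert table["n_voxels"].iloc[0] == 2
        assert table["volume_ul"].iloc[0] == pytest.approx(54.0)

    def test_diagonal_adjacency_splits_under_face_connectivity(self):
        t = self.t_field([(1, 1, 1), (2, 2, 1)])
        table = extract_clusters(t, df=20, voxel_p=0.001, k_min=1,
                                 roi_mask=np.ones(GRID, bool), voxel_volume_ul=27.0)
        assert len(table) == 2

    def test_subthreshold_extent_dropped(self):
        t = self.t_field([(1, 1, 1), (1, 2, 1)])
        table = extract_clusters(t, df=20, voxel_p=0.001, k_min=3,
                                 roi_mask=np.ones(GRID, bool), voxel_volume_ul=27.0)
        assert table.empty

    def test_signed_clusters_reported_separately_with_peaks(self):
        t = self.t_field([(0, 0, 0)], value=8.0) + self.t_field([(4, 4, 2)], value=-9.0)
        table = extract_clusters(t, df=20, voxel_p=0.001, k_min=1,
                                 roi_mask=np.ones(GRID, bool), voxel_volume_ul=27.0)
        assert set(table["direction"]) == {"+", "-"}
        neg = table[table["direction"] == "-"].iloc[0]
        assert (neg["peak_i"], neg["peak_j"], neg["peak_k"]) == (4, 4, 2)
        assert neg["peak_t"] == pytest.approx(-9.0)

    def test_clusters_limited_to_roi(self):
        t = self.t_field([(1, 1, 1), (3, 3, 1)])
        roi = np.zeros(GRID, bool)
        roi[1, 1, 1] = True
        table = extract_clusters(t, df=20, voxel_p=0.001, k_min=1,
                                 roi_mask=roi, voxel_volume_ul=27.0)
        assert len(table) == 1
        assert table["peak_i"].iloc[0] == 1


class TestWholeRoiAndEffectSize:
    def test_equal_groups_give_zero_t(self):
        res = whole_roi_ttest(vols([1, 2, 3]), vols([1, 2, 3]), np.ones(GRID, bool))
        assert res.t == pytest.approx(0.0, abs=1e-12)

    def test_closed_form_example(self):
        res = whole_roi_ttest(vols([1, 2, 3]), vols([4, 5, 6]), np.ones(GRID, bool))
        assert res.t == pytest.approx(-3.674, abs=1e-3)
        assert res.df == 4
        assert res.mean_a == pytest.approx(2.0)
        assert res.mean_b == pytest.approx(5.0)

    def test_null_p_values_uniform(self):
        # calibration: under the null the p-value must be uniform on (0, 1)
        rng = np.random.default_rng(11)
        ps = []
        for _ in range(200):
            res = whole_roi_ttest(
                vols(rng.normal(size=8)), vols(rng.normal(size=8)), np.ones(GRID, bool)
            )
            ps.append(res.p)
        assert sps.kstest(ps, "uniform").pvalue > 0.01

    def test_cohens_d_unit_case(self):
        d = cohens_d_anatomical_roi(vols([0, 1, 2]), vols([-1, 0, 1]), np.ones(GRID, bool))
        assert d == pytest.approx(1.0)

    def test_cohens_d_identical_groups_zero(self):
        d = cohens_d_anatomical_roi(vols([1, 2, 3]), vols([1, 2, 3]), np.ones(GRID, bool))
        assert d == pytest.approx(0.0)

    def test_cohens_d_sampling_recovery_at_study_sizes(self):
        # planted standardized effect 0.8 at the study's 16/21 split
        rng = np.random.default_rng(5)
        ds = [
            cohens_d_anatomical_roi(
                vols(rng.normal(0.8, 1.0, 16)), vols(rng.normal(0.0, 1.0, 21)),
                np.ones(GRID, bool),
            )
            for _ in range(100)
        ]
        assert np.mean(ds) == pytest.approx(0.8, abs=0.1)
        assert np.std(ds) < 0.5


class TestGroupContrast:
    def test_planted_effect_detected_inside_roi_only(self):
        rng = np.random.default_rng(9)
        roi = np.zeros(GRID, bool)
        roi[1:4, 1:4, 1] = True
        a = rng.normal(0.0, 1.0, size=(10, *GRID))
        b = rng.normal(0.0, 1.0, size=(10, *GRID))
        a[:, roi] += 6.0  # strong planted group effect
        roi_set = RoiSet(masks={"target": roi}, affine=np.diag([3, 3, 3, 1.0]))
        res = group_contrast(a, b, roi_set, "target", n_perm=500, seed=3)
        assert len(res.clusters) >= 1
        assert (res.clusters["direction"] == "+").all()
        for _, row in res.clusters.iterrows():
            assert roi[row["peak_i"], row["peak_j"], row["peak_k"]]
        assert res.threshold.k_min >= 1
        np.testing.assert_allclose(
            res.clusters["volume_ul"], res.clusters["n_voxels"] * 27.0
        )
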