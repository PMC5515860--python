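"""Quantification: surround subtraction, calibration, and the kinetic closed form."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from aslperf.errors import CalibrationError, ConfigurationError, InputError
from aslperf.phantom import make_phantom, noiseless_config, simulate_asl_session
from aslperf.quantify import (
    QuantConstants,
    estimate_m0_blood,
    minimum_contrast_correct,
    quantify_cbf,
    quantify_session,
    surround_subtract,
)
from conftest import make_session

GRID = (4, 4, 3)


def interleave(tags, controls):
    """Stack per-pair tag and control volumes into an ordered 4D series."""
    vols = []
    for t, c in zip(tags, controls):
        vols.extend([t, c])
    return np.stack(vols, axis=-1)


class TestSurroundSubtract:
    def test_constant_series_gives_constant_difference(self):
        tags = [np.full(GRID, 8.0)] * 5
        controls = [np.full(GRID, 10.0)] * 5
        dm, dm_mean = surround_subtract(make_session(interleave(tags, controls)))
        assert dm.shape == GRID + (5,)
        np.testing.assert_allclose(dm, 2.0)
        np.testing.assert_allclose(dm_mean, 2.0)

    def test_linear_drift_cancels_exactly_on_interior_pairs(self):
        rng = np.random.default_rng(0)
        base_tags = [rng.normal(100, 5, GRID) for _ in range(6)]
        base_controls = [rng.normal(102, 5, GRID) for _ in range(6)]
        clean, _ = surround_subtract(make_session(interleave(base_tags, base_controls)))
        b = 0.37
        drift_tags = [t + b * (2 * i) for i, t in enumerate(base_tags)]
        drift_controls = [c + b * (2 * i + 1) for i, c in enumerate(base_controls)]
        drifted, _ = surround_subtract(make_session(interleave(drift_tags, drift_controls)))
        # every control with two tag neighbors sees the drift cancel analytically
        np.testing.assert_allclose(drifted[..., :-1], clean[..., :-1], rtol=0, atol=1e-10)

    def test_endpoint_uses_single_neighbor(self):
        tags = [np.full(GRID, float(i)) for i in range(3)]
        controls = [np.full(GRID, 10.0)] * 3
        dm, _ = surround_subtract(make_session(interleave(tags, controls)))
        # last control has only the preceding tag
        np.testing.assert_allclose(dm[..., -1], 10.0 - 2.0)

    def test_control_first_ordering(self):
        tags = [np.full(GRID, 8.0)] * 4
        controls = [np.full(GRID, 10.0)] * 4
        series = interleave(controls, tags)  # control comes first per pair
        dm, _ = surround_subtract(make_session(series, tag_first=False))
        np.testing.assert_allclose(dm, 2.0)

    def test_single_pair_rejected(self):
        tags = [np.full(GRID, 8.0)]
        controls = [np.full(GRID, 10.0)]
        with pytest.raises(InputError):
            surround_subtract(make_session(interleave(tags, controls)))


class TestM0Calibration:
    def test_direct_product(self):
        scan = np.full(GRID, 1000.0)
        mask = np.ones(GRID, dtype=bool)
        m0b, m0csf = estimate_m0_blood(scan, mask, QuantConstants(blood_csf_density_ratio=0.76))
        assert m0b == pytest.approx(760.0)
        assert m0csf == pytest.approx(1000.0)

    def test_unit_ratio_is_identity(self):
        scan = np.full(GRID, 1234.0)
        m0b, m0csf = estimate_m0_blood(
            scan, np.ones(GRID, bool), QuantConstants(blood_csf_density_ratio=1.0)
        )
        assert m0b == m0csf

    def test_median_is_robust_to_edge_voxels(self, rng):
        scan = np.full(GRID, 1200.0)
        scan[0, 0, 0] = 300.0  # partial-volume contaminated edge voxel
        m0b, m0csf = estimate_m0_blood(scan, np.ones(GRID, bool), QuantConstants())
        assert m0csf == pytest.approx(1200.0)

    def test_empty_mask_rejected(self):
        with pytest.raises(InputError):
            estimate_m0_blood(np.ones(GRID), np.zeros(GRID, bool), QuantConstants())

    def test_nonpositive_signal_rejected(self):
        with pytest.raises(CalibrationError):
            estimate_m0_blood(np.full(GRID, -5.0), np.ones(GRID, bool), QuantConstants())

    def test_noisy_phantom_estimate_within_one_percent(self):
        estimates = []
        for seed in range(20):
            from aslperf.phantom import PhantomConfig

            cfg = PhantomConfig(
                grid_shape=(16, 16, 8), n_pairs=2, noise_sd=10.0,
                n_per_group={"control": 1, "patient": 1}, seed=seed,
            )
            truth = make_phantom(cfg)
            session = simulate_asl_session(truth, "control01", "fed", cfg)
            _, m0csf = estimate_m0_blood(session.csf_scan, session.csf_mask, cfg.constants)
            estimates.append(m0csf)
        assert abs(np.mean(estimates) / 1200.0 - 1.0) < 0.01


class TestMinimumContrast:
    def test_flat_reps_are_identity(self):
        vol = np.random.default_rng(0).normal(50, 5, GRID)
        ones = np.ones(GRID)
        corrected, field, valid = minimum_contrast_correct(
            vol, (ones, ones), np.ones(GRID, bool), (3.0, 3.0, 3.0)
        )
        np.testing.assert_allclose(field, 1.0)
        np.testing.assert_allclose(corrected, vol)
        assert valid.all()

    def test_pure_inhomogeneity_cancels(self):
        # a perfectly smooth unit-mean field is recovered and divided out
        z = np.linspace(0.9, 1.1, GRID[2])
        fld = np.broadcast_to(z, GRID).copy()
        fld = fld / fld.mean()
        corrected, _, valid = minimum_contrast_correct(
            fld.copy(), (fld.copy(), fld.copy()), np.ones(GRID, bool), (3.0, 3.0, 3.0),
            smooth_fwhm_mm=0.0,
        )
        np.testing.assert_allclose(corrected[valid], 1.0, rtol=1e-12)

    def test_zero_reps_rejected(self):
        zeros = np.zeros(GRID)
        with pytest.raises(CalibrationError):
            minimum_contrast_correct(np.ones(GRID), (zeros, zeros), np.ones(GRID, bool), (3, 3, 3))

    def test_phantom_coil_field_variation_reduced_fivefold(self):
        from aslperf.phantom import PhantomConfig

        cfg = PhantomConfig(noise_sd=0.0, n_per_group={"control": 1, "patient": 1}, seed=3)
        truth = make_phantom(cfg)
        session = simulate_asl_session(truth, "control01", "fed", cfg)
        flat = np.full(cfg.grid_shape, 100.0) * truth.coil_field_truth
        corrected, _, valid = minimum_contrast_correct(
            flat, session.min_contrast_reps, truth.brain_mask, cfg.voxel_size_mm
        )
        cov_before = flat[truth.brain_mask].std() / flat[truth.brain_mask].mean()
        cov_after = corrected[valid].std() / corrected[valid].mean()
        assert cov_before / cov_after >= 5.0


class TestQuantifyCbf:
    def closed_form(self, dm, m0b, alpha, ti1_s, ti2_s, t1b_s):
        return 6000.0 * dm / (2.0 * alpha * m0b * ti1_s * math.exp(-ti2_s / t1b_s))

    def test_matches_independent_closed_form(self):
        dm = np.ones(GRID)
        constants = QuantConstants(alpha=0.95, t1_blood_ms=1664.0)
        pmap = quantify_cbf(
            dm, 1000.0, 600.0, 1600.0, 0.0, constants, np.ones(GRID, bool), np.eye(4)
        )
        expected = self.closed_form(1.0, 1000.0, 0.95, 0.6, 1.6, 1.664)
        assert expected == pytest.approx(13.77, abs=0.01)
        np.testing.assert_allclose(pmap.cbf, expected, rtol=1e-12)

    def test_zero_signal_gives_zero_flow(self):
        pmap = quantify_cbf(
            np.zeros(GRID), 1000.0, 600.0, 1600.0, 45.0, QuantConstants(),
            np.ones(GRID, bool), np.eye(4),
        )
        np.testing.assert_allclose(pmap.cbf, 0.0)

    def test_linear_in_dm_and_inverse_in_m0(self):
        dm = np.random.default_rng(1).uniform(0.5, 2.0, GRID)
        args = (600.0, 1600.0, 45.0, QuantConstants(), np.ones(GRID, bool), np.eye(4))
        base = quantify_cbf(dm, 1000.0, *args).cbf
        doubled = quantify_cbf(2 * dm, 1000.0, *args).cbf
        half_m0 = quantify_cbf(dm, 2000.0, *args).cbf
        np.testing.assert_allclose(doubled, 2 * base, rtol=1e-12)
        np.testing.assert_allclose(half_m0, base / 2, rtol=1e-12)

    def test_later_slices_yield_larger_cbf_for_equal_signal(self):
        pmap = quantify_cbf(
            np.ones(GRID), 1000.0, 600.0, 1600.0, 45.0, QuantConstants(),
            np.ones(GRID, bool), np.eye(4),
        )
        per_slice = pmap.cbf[0, 0, :]
        assert np.all(np.diff(per_slice) > 0)

    def test_nonpositive_m0_rejected(self):
        with pytest.raises(CalibrationError):
            quantify_cbf(np.ones(GRID), 0.0, 600.0, 1600.0, 0.0, QuantConstants(),
                         np.ones(GRID, bool), np.eye(4))


@given(st.floats(min_value=0.05, max_value=1.0), st.floats(min_value=500.0, max_value=3000.0))
def test_constants_validation_accepts_physical_values(alpha, t1b):
    QuantConstants(alpha=alpha, t1_blood_ms=t1b)


@pytest.mark.parametrize("bad", [{"alpha": 0.0}, {"alpha": 1.5}, {"t1_blood_ms": -1.0}])
def test_constants_validation_rejects_unphysical_values(bad):
    with pytest.raises(ConfigurationError):
        QuantConstants(**bad)


class TestRoundTrip:
    def test_noiseless_phantom_recovers_truth_to_numerical_precision(self):
        cfg = noiseless_config(n_per_group={"control": 1, "patient": 1}, seed=11)
        truth = make_phantom(cfg)
        for condition in cfg.conditions:
            session = simulate_asl_session(truth, "patient01", condition, cfg)
            pmap = quantify_session(session, cfg.constants)
            expected = truth.cbf_truth[("patient01", condition)]
            sel = pmap.mask & (expected > 1.0)
            rel = np.abs(pmap.cbf[sel] - expected[sel]) / expected[sel]
            assert rel.max() < 1e-6

    def test_zero_perfusion_means_tag_equals_control(self):
        cfg = noiseless_config(
            tissue_cbf={"gm": 0.0, "wm": 0.0},
            roi_effects={},
            n_per_group={"control": 1, "patient": 1},
            seed=2,
        )
        truth = make_phantom(cfg)
        session = simulate_asl_session(truth, "control01", "hungry", cfg)
        tags = session.series[..., 0::2]
        controls = session.series[..., 1::2]
        # drift is off, so paired volumes are identical when nothing is labeled
        np.testing.assert_allclose(tags, controls, atol=1e-12)
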