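import numpy as np
import pytest

import cortexmpm as cm
from cortexmpm.mpm_fit import (
    average_echoes,
    calibrate_pdstar,
    compute_mtsat,
    fit_all_maps,
    fit_r1_vfa,
    fit_r2star_estatics,
)
from cortexmpm.phantom import (
    GM,
    WM,
    FieldMaps,
    SubjectSpec,
    TissueGroundTruth,
    WeightedVolumeSet,
    flash_signal,
    simulate_weighted_volumes,
)
from cortexmpm.protocols import WEIGHTINGS, cohort1_protocol, cohort2_protocol

from conftest import deterministic_spec


def _uniform_gt(shape=(6, 5, 4), r1=1.0, r2star=15.0, delta=0.012, a=800.0):
    """Hand-built ground truth: WM in the bottom z-slab, GM above."""
    label = np.full(shape, GM, dtype=np.int16)
    label[..., :2] = WM
    ones = np.ones(shape)
    return TissueGroundTruth(
        r1=r1 * ones,
        r2star=r2star * ones,
        delta=delta * ones * (label == GM),
        a=a * ones,
        label=label,
        region=np.where(label == GM, 0, -1),
        depth=np.where(label == GM, 0.5, np.nan),
        affine=np.eye(4),
        subject=SubjectSpec(0, 25, "F", 1, seed=0),
    )


def _unit_fields(shape):
    return FieldMaps(np.ones(shape), np.ones(shape), np.eye(4))


def _simulate(gt, protocol, signal_model, f_t=None, noise_sd=0.0, seed=0):
    fields = _unit_fields(gt.label.shape)
    if f_t is not None:
        fields.f_transmit = f_t * np.ones(gt.label.shape)
    return simulate_weighted_volumes(
        gt, fields, protocol, noise_sd=noise_sd, seed=seed, signal_model=signal_model
    )


class TestEstatics:
    def test_exact_recovery_noiseless(self):
        gt = _uniform_gt(r2star=20.0)
        vols = _simulate(gt, cohort1_protocol(), "ernst")
        fit = fit_r2star_estatics(vols)
        assert np.allclose(fit.r2star[fit.valid], 20.0, rtol=1e-10)

    def test_varying_r2star_recovered(self):
        shape = (5, 4, 3)
        rng = np.random.default_rng(0)
        gt = _uniform_gt(shape)
        gt.r2star = rng.uniform(10.0, 30.0, size=shape)
        vols = _simulate(gt, cohort1_protocol(), "ernst")
        fit = fit_r2star_estatics(vols)
        assert np.allclose(fit.r2star[fit.valid], gt.r2star[fit.valid], rtol=1e-9)

    def test_two_point_single_weighting_slope(self):
        """Single weighting, two echoes: slope is the two-point formula."""
        proto = cohort1_protocol()
        from cortexmpm.protocols import AcquisitionProtocol, WeightingProtocol

        p2 = AcquisitionProtocol(
            weightings={
                "PDw": WeightingProtocol(5.0, 25.0, (2.0, 10.0)),
                "T1w": WeightingProtocol(29.0, 25.0, (2.0, 10.0)),
                "MTw": WeightingProtocol(9.0, 25.0, (2.0,), mt_pulse=True),
            }
        )
        s1, s2 = 50.0, 30.0
        vols = WeightedVolumeSet(
            signals={"PDw": np.array([[[[s1, s2]]]])},
            protocol=p2,
            fields=_unit_fields((1, 1, 1)),
            label=np.full((1, 1, 1), GM, dtype=np.int16),
            affine=np.eye(4),
        )
        fit = fit_r2star_estatics(vols)
        expected = (np.log(s1) - np.log(s2)) / (0.010 - 0.002)
        assert fit.r2star[0, 0, 0] == pytest.approx(expected, rel=1e-12)

    def test_equals_normal_equations_oracle(self, rng):
        """Joint OLS equals a per-voxel brute-force normal-equations solve."""
        proto = cohort1_protocol()
        shape = (10, 5, 2)
        signals = {
            w: np.exp(rng.normal(3.0, 0.3, size=shape + (proto[w].n_echoes,)))
            for w in WEIGHTINGS
        }
        vols = WeightedVolumeSet(
            signals=signals, protocol=proto, fields=_unit_fields(shape),
            label=np.full(shape, GM, dtype=np.int16), affine=np.eye(4),
        )
        fit = fit_r2star_estatics(vols)
        # independent oracle: assemble X'X beta = X'y voxel by voxel
        te = {w: np.asarray(proto[w].te_s) for w in WEIGHTINGS}
        for idx in [(0, 0, 0), (3, 2, 1), (9, 4, 0)]:
            x_rows, y_rows = [], []
            for j, w in enumerate(WEIGHTINGS):
                for i, t in enumerate(te[w]):
                    row = [0.0] * 4
                    row[0] = -t
                    row[1 + j] = 1.0
                    x_rows.append(row)
                    y_rows.append(np.log(signals[w][idx][i]))
            x = np.asarray(x_rows)
            y = np.asarray(y_rows)
            beta = np.linalg.solve(x.T @ x, x.T @ y)
            assert fit.r2star[idx] == pytest.approx(beta[0], rel=1e-10)
            for j, w in enumerate(WEIGHTINGS):
                assert fit.ln_intercepts[w][idx] == pytest.approx(
                    beta[1 + j], rel=1e-10
                )

    def test_matches_nonlinear_least_squares_oracle(self, rng):
        """Noisy voxel: log-linear estimate within the SE of an NLS fit."""
        from scipy.optimize import curve_fit

        proto = cohort1_protocol()
        te = np.asarray(proto["PDw"].te_s)
        true_a, true_r2s = 60.0, 18.0
        clean = true_a * np.exp(-te * true_r2s)
        shape = (1, 1, 1)
        noisy = {
            w: (clean + rng.normal(0, 0.5, size=te.size)).reshape(shape + (8,))
            for w in WEIGHTINGS
        }
        vols = WeightedVolumeSet(
            signals=noisy, protocol=proto, fields=_unit_fields(shape),
            label=np.full(shape, GM, dtype=np.int16), affine=np.eye(4),
        )
        fit = fit_r2star_estatics(vols)
        all_te = np.concatenate([te] * 3)
        all_sig = np.concatenate([noisy[w].ravel() for w in WEIGHTINGS])
        popt, pcov = curve_fit(
            lambda t, a, r: a * np.exp(-t * r), all_te, all_sig, p0=(50.0, 15.0)
        )
        se_r2s = np.sqrt(pcov[1, 1])
        assert abs(fit.r2star[0, 0, 0] - popt[1]) < se_r2s

    def test_shared_slope_pools_snr(self, rng):
        """MC variance of the joint slope <= any single-weighting slope."""
        proto = cohort1_protocol()
        te = np.asarray(proto["PDw"].te_s)
        clean = {w: 60.0 * np.exp(-te * 18.0) for w in WEIGHTINGS}
        n_rep = 200
        joint, single = [], []
        for _ in range(n_rep):
            sig = {
                w: (clean[w] + rng.normal(0, 0.8, te.size)).reshape(1, 1, 1, 8)
                for w in WEIGHTINGS
            }
            vols = WeightedVolumeSet(
                signals=sig, protocol=proto, fields=_unit_fields((1, 1, 1)),
                label=np.full((1, 1, 1), GM, dtype=np.int16), affine=np.eye(4),
            )
            joint.append(fit_r2star_estatics(vols).r2star[0, 0, 0])
            solo = WeightedVolumeSet(
                signals={"PDw": sig["PDw"]}, protocol=proto,
                fields=_unit_fields((1, 1, 1)),
                label=np.full((1, 1, 1), GM, dtype=np.int16), affine=np.eye(4),
            )
            single.append(fit_r2star_estatics(solo).r2star[0, 0, 0])
        assert np.std(joint) <= np.std(single)

    def test_nonpositive_signal_masks_voxel(self):
        gt = _uniform_gt()
        vols = _simulate(gt, cohort1_protocol(), "ernst")
        vols.signals["T1w"][2, 2, 2, 5] = -1.0
        fit = fit_r2star_estatics(vols)
        assert not fit.valid[2, 2, 2]
        assert np.isnan(fit.r2star[2, 2, 2])
        assert fit.valid[1, 1, 1]

    def test_background_not_fitted(self):
        gt = _uniform_gt()
        gt.label[0, 0, :] = 0
        vols = _simulate(gt, cohort1_protocol(), "ernst")
        fit = fit_r2star_estatics(vols)
        assert not fit.valid[0, 0, 0]


class TestAverageEchoes:
    def test_identical_echoes_average_to_any(self):
        gt = _uniform_gt(r2star=1e-9)
        vols = _simulate(gt, cohort1_protocol(), "ernst")
        avg = average_echoes(vols)
        assert np.allclose(avg["PDw"], vols.signals["PDw"][..., 0], rtol=1e-7)

    def test_cohort2_uses_first_six(self):
        gt = _uniform_gt()
        vols = _simulate(gt, cohort2_protocol(), "ernst")
        avg = average_echoes(vols)
        assert np.allclose(avg["PDw"], vols.signals["PDw"][..., :6].mean(axis=-1))
        assert np.allclose(avg["MTw"], vols.signals["MTw"].mean(axis=-1))

    def test_mean_between_first_and_last_echo(self):
        gt = _uniform_gt(r2star=25.0)
        vols = _simulate(gt, cohort1_protocol(), "ernst")
        avg = average_echoes(vols)
        tissue = gt.tissue_mask
        assert np.all(avg["PDw"][tissue] < vols.signals["PDw"][..., 0][tissue])
        assert np.all(avg["PDw"][tissue] > vols.signals["PDw"][..., -1][tissue])

    def test_zero_echoes_rejected(self):
        gt = _uniform_gt()
        vols = _simulate(gt, cohort1_protocol(), "ernst")
        with pytest.raises(ValueError):
            average_echoes(vols, 0)
        with pytest.raises(ValueError):
            average_echoes(vols, 9)


class TestVfaR1:
    def test_exact_inverse_of_small_angle_forward(self):
        rng = np.random.default_rng(2)
        shape = (6, 5, 4)
        gt = _uniform_gt(shape)
        gt.r1 = rng.uniform(0.5, 1.8, size=shape)
        gt.a = rng.uniform(600.0, 900.0, size=shape)
        vols = _simulate(gt, cohort1_protocol(), "small_angle")
        avg = average_echoes(vols)
        r1, a, valid = fit_r1_vfa(avg["PDw"], avg["T1w"], vols.protocol)
        assert np.allclose(r1[valid], gt.r1[valid], rtol=1e-9)
        # amplitude recovered up to the (uniform here) echo-decay factor
        ratio = a[valid] / gt.a[valid]
        assert np.allclose(ratio, ratio.flat[0], rtol=1e-9)

    def test_transmit_correction_contract(self):
        """Known f_T=1.1 with correct correction == f_T=1 recovery."""
        gt = _uniform_gt()
        v_unit = _simulate(gt, cohort1_protocol(), "small_angle")
        v_ft = _simulate(gt, cohort1_protocol(), "small_angle", f_t=1.1)
        a_unit = average_echoes(v_unit)
        a_ft = average_echoes(v_ft)
        r1_u, _, ok_u = fit_r1_vfa(a_unit["PDw"], a_unit["T1w"], v_unit.protocol, 1.0)
        r1_c, _, ok_c = fit_r1_vfa(a_ft["PDw"], a_ft["T1w"], v_ft.protocol, 1.1)
        assert np.allclose(r1_c[ok_c], r1_u[ok_u], rtol=1e-9)

    def test_ernst_forward_bias_within_5_percent(self):
        """Exact-Ernst phantom at cohort-1 angles: R1 within 5% of truth."""
        gt = _uniform_gt(r1=1.0)
        vols = _simulate(gt, cohort1_protocol(), "ernst")
        avg = average_echoes(vols)
        r1, _, valid = fit_r1_vfa(avg["PDw"], avg["T1w"], vols.protocol)
        assert np.all(np.abs(r1[valid] - 1.0) < 0.05)

    def test_equal_flip_angles_rejected(self):
        from cortexmpm.protocols import AcquisitionProtocol, WeightingProtocol

        bad = AcquisitionProtocol(
            weightings={
                "PDw": WeightingProtocol(6.0, 25.0, (2.34,)),
                "T1w": WeightingProtocol(6.0, 25.0, (2.34,)),
                "MTw": WeightingProtocol(6.0, 25.0, (2.34,), mt_pulse=True),
            }
        )
        with pytest.raises(ValueError, match="unidentifiable"):
            fit_r1_vfa(np.ones((2, 2, 2)), np.ones((2, 2, 2)), bad)


class TestMtsat:
    def test_exact_inverse_small_angle(self):
        gt = _uniform_gt(delta=0.01)
        gt.delta = np.full(gt.label.shape, 0.01)
        vols = _simulate(gt, cohort1_protocol(), "small_angle")
        avg = average_echoes(vols)
        r1, a, valid = fit_r1_vfa(avg["PDw"], avg["T1w"], vols.protocol)
        mtsat, ok = compute_mtsat(avg["MTw"], a, r1, vols.protocol, mask=valid)
        assert np.allclose(mtsat[ok], 1.0, atol=1e-9)

    def test_zero_delta_gives_zero(self):
        gt = _uniform_gt(delta=0.0)
        vols = _simulate(gt, cohort1_protocol(), "small_angle")
        avg = average_echoes(vols)
        r1, a, valid = fit_r1_vfa(avg["PDw"], avg["T1w"], vols.protocol)
        mtsat, ok = compute_mtsat(avg["MTw"], a, r1, vols.protocol, mask=valid)
        assert np.allclose(mtsat[ok], 0.0, atol=1e-9)

    def test_ernst_cohort2_bias_within_5_percent(self):
        """delta=0.015 under the exact Ernst model, cohort-2 preset."""
        gt = _uniform_gt(delta=0.015)
        gt.delta = np.full(gt.label.shape, 0.015)
        vols = _simulate(gt, cohort2_protocol(), "ernst")
        avg = average_echoes(vols)
        r1, a, valid = fit_r1_vfa(avg["PDw"], avg["T1w"], vols.protocol)
        mtsat, ok = compute_mtsat(avg["MTw"], a, r1, vols.protocol, mask=valid)
        assert np.all(np.abs(mtsat[ok] - 1.5) / 1.5 < 0.05)

    def test_nonpositive_signal_masked(self):
        gt = _uniform_gt()
        vols = _simulate(gt, cohort1_protocol(), "small_angle")
        avg = average_echoes(vols)
        r1, a, valid = fit_r1_vfa(avg["PDw"], avg["T1w"], vols.protocol)
        avg["MTw"][1, 1, 1] = 0.0
        mtsat, ok = compute_mtsat(avg["MTw"], a, r1, vols.protocol, mask=valid)
        assert not ok[1, 1, 1]
        assert np.isnan(mtsat[1, 1, 1])


class TestPdstarCalibration:
    def test_wm_mean_is_69_exactly(self, rng):
        a = rng.uniform(500, 900, size=(8, 8, 8))
        g = rng.uniform(0.8, 1.2, size=a.shape)
        wm = np.zeros(a.shape, dtype=bool)
        wm[:3] = True
        pd = calibrate_pdstar(a, g, wm)
        assert np.nanmean(pd[wm]) == pytest.approx(69.0, abs=1e-12)

    def test_uniform_inputs_give_69_everywhere(self):
        pd = calibrate_pdstar(
            np.full((4, 4, 4), 555.0), np.full((4, 4, 4), 1.3),
            np.ones((4, 4, 4), dtype=bool),
        )
        assert np.allclose(pd, 69.0)

    def test_receive_scale_invariance(self, rng):
        a = rng.uniform(500, 900, size=(5, 5, 5))
        g = rng.uniform(0.8, 1.2, size=a.shape)
        wm = a > 600
        assert np.allclose(
            calibrate_pdstar(a, g, wm), calibrate_pdstar(a, 2.0 * g, wm)
        )

    def test_idempotent(self, rng):
        a = rng.uniform(500, 900, size=(5, 5, 5))
        wm = a > 600
        once = calibrate_pdstar(a, 1.0, wm)
        twice = calibrate_pdstar(once, 1.0, wm)
        assert np.allclose(once, twice)

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            calibrate_pdstar(np.ones((3, 3, 3)), 1.0, np.zeros((3, 3, 3), bool))

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="congruent"):
            calibrate_pdstar(np.ones((3, 3, 3)), 1.0, np.ones((2, 2, 2), bool))


class TestFitAllMaps:
    def test_noiseless_small_angle_phantom_recovers_all(self):
        rng = np.random.default_rng(7)
        shape = (8, 6, 6)
        gt = _uniform_gt(shape)
        gt.r1 = rng.uniform(0.6, 1.6, size=shape)
        gt.delta = rng.uniform(0.004, 0.02, size=shape) * (gt.label == GM)
        gt.a = rng.uniform(650.0, 900.0, size=shape)
        gt.r2star = np.full(shape, 16.0)  # uniform: echo-decay scale cancels
        vols = _simulate(gt, cohort1_protocol(), "small_angle")
        maps = fit_all_maps(vols)
        ok = maps.valid
        assert np.allclose(maps.r1[ok], gt.r1[ok], rtol=1e-9)
        assert np.allclose(maps.r2star[ok], 16.0, rtol=1e-9)
        assert np.allclose(maps.mtsat[ok], 100.0 * gt.delta[ok], atol=1e-9)
        # PD* proportional to true amplitude, WM mean pinned at 69
        wm_ok = (gt.label == WM) & ok
        assert np.nanmean(maps.pdstar[wm_ok]) == pytest.approx(69.0, abs=1e-9)
        ratio = maps.pdstar[ok] / gt.a[ok]
        assert np.allclose(ratio, ratio.flat[0], rtol=1e-9)

    def test_background_invalid(self):
        gt = _uniform_gt()
        gt.label[0, :, :] = 0
        vols = _simulate(gt, cohort1_protocol(), "ernst")
        maps = fit_all_maps(vols)
        assert not maps.valid[0].any()
        assert np.all(np.isnan(maps.r1[0]))

    def test_depth_gradient_recovered(self, folded_model):
        """GM near the white surface: higher R1/MT/R2*, lower PD*."""
        spec = deterministic_spec()
        sub = cm.make_cohort(2, effect_spec=spec, seed=1, cohort2_fraction=0.0,
                             n_regions=folded_model.n_regions)[0]
        gt = cm.build_ground_truth(folded_model, sub, spec)
        fields = _unit_fields(folded_model.vol_shape)
        vols = simulate_weighted_volumes(gt, fields, cohort1_protocol(),
                                         noise_sd=0.0, seed=0)
        maps = fit_all_maps(vols)
        deep = (gt.depth < 0.25) & maps.valid
        sup = (gt.depth > 0.75) & maps.valid
        assert np.nanmean(maps.r1[deep]) > np.nanmean(maps.r1[sup])
        assert np.nanmean(maps.mtsat[deep]) > np.nanmean(maps.mtsat[sup])
        assert np.nanmean(maps.r2star[deep]) > np.nanmean(maps.r2star[sup])
        assert np.nanmean(maps.pdstar[deep]) < np.nanmean(maps.pdstar[sup])
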