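"""PIV engine: correlation, subpixel fit, validation, multipass accuracy."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from xylemflow import piv as pivmod
from xylemflow.piv import (
    CorrelationPlane,
    PivConfig,
    VelocityField,
    correlate_window,
    ensemble_average,
    extract_profile,
    multipass_piv,
    subpixel_peak,
    validate_adaptive_median,
    validate_snr,
)
from xylemflow.synthgen import (
    ParticleImageParams,
    ParticleImagePair,
    make_particle_image_pair,
    poiseuille_field,
    uniform_field,
)

from conftest import PIV_SHAPE, run_uniform_ensemble


def _noise_window(seed, shape=(16, 32)):
    return np.random.default_rng(seed).normal(100, 10, shape)


class TestCorrelateWindow:
    def test_autocorrelation_peaks_at_origin(self):
        win = _noise_window(0)
        plane = correlate_window(win, win)
        assert plane.peak_lag == (0, 0)
        assert plane.primary == pytest.approx(1.0, abs=1e-6)

    def test_integer_translation_recovered_exactly(self):
        a = _noise_window(1)
        b = np.roll(np.roll(a, 1, axis=0), 3, axis=1)
        plane = correlate_window(a, b)
        assert plane.peak_lag == (1, 3)

    def test_zero_variance_window_is_invalid(self):
        flat = np.full((8, 32), 7.0)
        plane = correlate_window(flat, _noise_window(2, (8, 32)))
        assert not plane.valid
        assert plane.snr == 0.0

    def test_independent_noise_has_low_snr(self):
        # pre-build Monte-Carlo (2000 trials) found 100% below threshold 2
        below = sum(
            correlate_window(_noise_window(3 + i, (8, 32)),
                             _noise_window(5003 + i, (8, 32))).snr < 2.0
            for i in range(300)
        )
        assert below >= 285  # >= 95 %

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            correlate_window(np.zeros((8, 8)), np.zeros((8, 16)))


class TestSubpixelPeak:
    @staticmethod
    def _plane_from_triple(vals):
        v = np.zeros((3, 3))
        v[1] = vals
        v[:, 1] = vals
        v[1, 1] = vals[1]
        return CorrelationPlane(v, np.arange(-1, 2), np.arange(-1, 2),
                                (1, 1), float(vals[1]), 0.0)

    def test_symmetric_triple_gives_zero_offset(self):
        plane = self._plane_from_triple(np.array([0.5, 1.0, 0.5]))
        assert subpixel_peak(plane) == (0.0, 0.0)

    def test_pure_gaussian_recovered_exactly(self):
        vals = np.exp(-((np.arange(-1, 2) - 0.3) ** 2) / (2 * 0.7**2))
        plane = self._plane_from_triple(vals)
        dx, dy = subpixel_peak(plane)
        assert dx == pytest.approx(0.3, abs=1e-12)

    @settings(derandomize=True, max_examples=50)
    @given(delta=st.floats(-0.45, 0.45), sigma=st.floats(0.5, 2.0))
    def test_gaussian_estimator_exact_for_any_offset(self, delta, sigma):
        vals = np.exp(-((np.arange(-1, 2) - delta) ** 2) / (2 * sigma**2))
        plane = self._plane_from_triple(vals)
        dx, _ = subpixel_peak(plane)
        assert dx == pytest.approx(delta, abs=1e-9)

    def test_not_a_local_maximum_is_an_error(self):
        v = np.zeros((3, 3))
        v[1] = [1.2, 1.0, 0.5]  # rising to the left of the claimed peak
        plane = CorrelationPlane(v, np.arange(-1, 2), np.arange(-1, 2),
                                 (1, 1), 1.0, 0.0)
        with pytest.raises(ValueError, match="maximum"):
            subpixel_peak(plane)

    def test_border_peak_rejected(self):
        v = np.zeros((3, 3))
        v[0, 1] = 1.0
        plane = CorrelationPlane(v, np.arange(-1, 2), np.arange(-1, 2),
                                 (0, 1), 1.0, 0.0)
        with pytest.raises(ValueError, match="border"):
            subpixel_peak(plane)

    def test_non_positive_triple_falls_back_to_parabola(self):
        plane = self._plane_from_triple(np.array([-0.1, 1.0, 0.4]))
        dx, _ = subpixel_peak(plane)
        expected = 0.5 * (-0.1 - 0.4) / (-0.1 - 2.0 + 0.4)
        assert dx == pytest.approx(expected)


def _uniform_vf(u=3.0, v=0.0, shape=(9, 9), snr=5.0):
    ny, nx = shape
    return VelocityField(
        x=np.arange(nx, dtype=float), y=np.arange(ny, dtype=float),
        u=np.full(shape, u), v=np.full(shape, v),
        snr=np.full(shape, snr), valid=np.ones(shape, bool))


class TestValidation:
    def test_snr_threshold_flags_only_low_nodes(self):
        fld = _uniform_vf()
        fld.snr[2, 2] = 1.5
        fld.snr[3, 3] = 2.5
        out = validate_snr(fld, 2.0)
        assert not out.valid[2, 2]
        assert out.valid[3, 3]
        # identity when everything passes
        clean = validate_snr(_uniform_vf(), 2.0)
        assert clean.valid.all()

    def test_uniform_field_unchanged_by_median_test(self):
        fld = _uniform_vf()
        out = validate_adaptive_median(fld)
        assert out.valid.all()
        np.testing.assert_array_equal(out.u, fld.u)

    def test_single_outlier_flagged_and_replaced(self):
        fld = _uniform_vf(u=3.0)
        fld.u[4, 4] = 30.0
        out = validate_adaptive_median(fld)
        assert not out.valid[4, 4]
        assert out.replaced[4, 4]
        assert out.u[4, 4] == pytest.approx(3.0)

    def test_two_adjacent_outliers_both_flagged(self):
        fld = _uniform_vf(u=3.0)
        fld.u[4, 4] = 30.0
        fld.u[4, 5] = 28.0
        out = validate_adaptive_median(fld, region=(7, 7))
        assert not out.valid[4, 4] and not out.valid[4, 5]
        assert out.u[4, 4] == pytest.approx(3.0)
        assert out.u[4, 5] == pytest.approx(3.0)

    def test_two_stage_validation_is_order_stable(self):
        fld = _uniform_vf(u=3.0)
        fld.u[4, 4] = 30.0
        fld.snr[1, 1] = 1.2
        once = validate_adaptive_median(validate_snr(fld, 2.0))
        twice = validate_adaptive_median(validate_snr(once, 2.0))
        np.testing.assert_array_equal(once.valid, twice.valid)
        np.testing.assert_allclose(once.u, twice.u)
        np.testing.assert_allclose(once.v, twice.v)

    def test_even_or_oversized_region_rejected(self):
        with pytest.raises(ValueError):
            validate_adaptive_median(_uniform_vf(), region=(6, 7))
        with pytest.raises(ValueError, match="larger than grid"):
            validate_adaptive_median(_uniform_vf(shape=(3, 3)), region=(21, 21))


class TestEnsembleAverage:
    def test_idempotent_on_copies(self):
        fld = _uniform_vf()
        out = ensemble_average([fld.copy() for _ in range(5)])
        np.testing.assert_allclose(out.u, fld.u)
        assert out.valid.all()

    def test_majority_validity_rule(self):
        fields = [_uniform_vf() for _ in range(4)]
        for f in fields[:3]:
            f.valid[0, 0] = False
        out = ensemble_average(fields)
        assert not out.valid[0, 0]

    def test_rms_error_shrinks_as_inverse_sqrt_n(self):
        rng = np.random.default_rng(42)

        def rms_of_mean(n, reps=40):
            errs = []
            for _ in range(reps):
                fields = []
                for _ in range(n):
                    f = _uniform_vf(u=3.0)
                    f.u = f.u + rng.normal(0, 0.5, f.u.shape)
                    fields.append(f)
                m = ensemble_average(fields)
                errs.append(np.sqrt(np.mean((m.u - 3.0) ** 2)))
            return np.mean(errs)

        ns = np.array([10, 40, 160])
        rms = np.array([rms_of_mean(n) for n in ns])
        slope = np.polyfit(np.log(ns), np.log(rms), 1)[0]
        assert slope == pytest.approx(-0.5, abs=0.1)

    def test_mismatched_grids_rejected(self):
        with pytest.raises(ValueError):
            ensemble_average([_uniform_vf(shape=(9, 9)), _uniform_vf(shape=(8, 9))])


class TestMultipass:
    def test_zero_displacement_recovers_null_flow(self):
        pair = make_particle_image_pair(uniform_field(0, 0, PIV_SHAPE), seed=11)
        fld = multipass_piv(pair)
        assert np.abs(fld.u[fld.valid]).max() < 0.05
        assert np.abs(fld.v[fld.valid]).max() < 0.05

    def test_uniform_8px_shift_within_tenth_pixel(self):
        means = run_uniform_ensemble(8.0, n_pairs=6, seed0=100)
        assert np.mean(np.abs(means - 8.0)) <= 0.1
        assert abs(means.mean() - 8.0) / 8.0 <= 0.01

    def test_translation_equivariance_to_common_integer_shift(self):
        pair = make_particle_image_pair(
            uniform_field(2.0, 0.0, PIV_SHAPE),
            ParticleImageParams(noise_sigma=0.0), seed=12)
        rolled = ParticleImagePair(
            frame_a=np.roll(pair.frame_a, (8, 32), axis=(0, 1)),
            frame_b=np.roll(pair.frame_b, (8, 32), axis=(0, 1)),
            truth=pair.truth, params=pair.params, seed=pair.seed)
        f0 = multipass_piv(pair)
        f1 = multipass_piv(rolled)
        # exclude nodes whose final window straddles the wrap seams, and
        # the image-border band where windows are particle-starved
        X, Y = np.meshgrid(f0.x, f0.y)
        near_seam = (np.abs(X - 32) < 24) | (np.abs(Y - 8) < 8)
        near_border = (X < 48) | (X > PIV_SHAPE[1] - 48) | (Y < 12) | (Y > PIV_SHAPE[0] - 12)
        keep = ~near_seam & ~near_border & f0.valid & f1.valid
        assert keep.sum() > 50
        np.testing.assert_allclose(f0.u[keep], f1.u[keep], atol=0.05)
        np.testing.assert_allclose(f0.u[keep], 2.0, atol=0.05)

    def test_poiseuille_centerline_to_mean_ratio(self, poiseuille_truth,
                                                 poiseuille_mean_field):
        mean = poiseuille_mean_field
        X, Y = np.meshgrid(mean.x, mean.y)
        ut, _ = poiseuille_truth(X, Y)
        m = mean.valid
        measured = mean.u[m].max() / mean.u[m].mean()
        truth = ut[m].max() / ut[m].mean()
        assert abs(measured / truth - 1.0) < 0.03

    def test_featureless_images_raise(self):
        rng = np.random.default_rng(0)
        pair = ParticleImagePair(
            frame_a=rng.integers(90, 110, PIV_SHAPE).astype(np.uint8),
            frame_b=rng.integers(90, 110, PIV_SHAPE).astype(np.uint8),
            truth=uniform_field(0, 0, PIV_SHAPE),
            params=ParticleImageParams(), seed=0)
        with pytest.raises(RuntimeError, match="invalid"):
            multipass_piv(pair)

    def test_image_smaller_than_window_raises(self):
        pair = make_particle_image_pair(uniform_field(0, 0, (64, 100)), seed=0)
        with pytest.raises(ValueError, match="smaller than window"):
            multipass_piv(pair)

    def test_config_invariants_enforced(self):
        with pytest.raises(ValueError):
            PivConfig(initial_window=(8, 32), final_window=(32, 128))
        with pytest.raises(ValueError):
            PivConfig(overlap=0.9)
        with pytest.raises(ValueError):
            PivConfig(snr_threshold=0.5)
        assert PivConfig().window_schedule() == [(32, 128), (16, 64), (8, 32)]


class TestExtractProfile:
    @staticmethod
    def _analytic_field(u_max=4.0):
        x = np.arange(16.0, 241.0, 16.0)
        y = np.arange(4.0, 61.0, 4.0)
        X, Y = np.meshgrid(x, y)
        u = u_max * 4 * (Y / 64) * (1 - Y / 64)
        return VelocityField(x=x, y=y, u=u, v=np.zeros_like(u),
                             snr=np.full_like(u, 5.0),
                             valid=np.ones(u.shape, bool))

    def test_symmetric_with_centerline_maximum(self):
        prof = extract_profile(self._analytic_field(), 160.0)
        u = prof.u_um_s.to_numpy()
        np.testing.assert_allclose(u, u[::-1], atol=1e-9)
        assert np.argmax(u) == len(u) // 2

    @pytest.mark.parametrize("station", [160.0, 200.0, 240.0])
    def test_default_stations_supported(self, station):
        prof = extract_profile(self._analytic_field(), station,
                               normalization_U0=4.0 * 2 / 3)
        assert {"y_um", "u_um_s", "U_over_U0"} <= set(prof.columns)
        assert prof.U_over_U0.max() == pytest.approx(1.5, rel=0.02)

    def test_profile_flux_matches_station_flux(self, poiseuille_truth,
                                               poiseuille_mean_field):
        mean = poiseuille_mean_field
        prof = extract_profile(mean, 128.0)
        keep = mean.valid[:, np.searchsorted(mean.x, 128.0)]
        y = prof.y_um.to_numpy()[keep]
        u = prof.u_um_s.to_numpy()[keep]
        flux = np.trapezoid(u, y)
        ut, _ = poiseuille_truth(np.full_like(y, 128.0), y)
        flux_true = np.trapezoid(ut, y)
        assert abs(flux / flux_true - 1.0) < 0.02

    def test_station_outside_field_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            extract_profile(self._analytic_field(), 5000.0)
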