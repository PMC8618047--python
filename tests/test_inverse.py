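import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import brentq

from conftest import H0, PIXEL_SIZE, TE, make_noiseless_profile
from thermoparam import HeatSourceTruth, forward_temperature_point
from thermoparam.inverse import (
    DEFAULT_CONSTANTS,
    FitFailureError,
    ModelConstants,
    SingularInversionError,
    dir_depth,
    dir_intensity,
    lorentz_fit,
    lorentz_params,
    pattern_vector,
    r_squared,
    source_radius,
    theta_angle,
)
from thermoparam.segmentation import RoIProfile


def brute_force_depth(t_a, tmax, te, a, h0=H0):
    """Independent 1-D root find: the depth whose forward profile passes
    through both the peak and the sample."""

    def residual(d):
        q = 4 * math.pi * h0 * d**2 * (tmax - te)
        return q / (4 * math.pi * h0 * (d**2 + a**2)) - (t_a - te)

    return brentq(residual, 1e-6, 1.0, xtol=1e-15, rtol=1e-15)


class TestDirClosedForms:
    def test_worked_example_round_trip(self):
        q = 4 * np.pi * H0 * 0.01**2 * 12
        src = HeatSourceTruth((0, 0), 0.01, q)
        t_a = forward_temperature_point(0.0168, src)
        assert dir_depth(t_a, 34.0, TE, 0.0168) == pytest.approx(0.01, rel=1e-9)
        assert dir_intensity(t_a, 34.0, TE, 0.0168, H0) == pytest.approx(q, rel=1e-9)

    def test_midpoint_sample_depth_equals_offset(self):
        # (T(a)-Te)/(Tmax-T(a)) = 1 exactly at the half-contrast point
        assert dir_depth(28.0, 34.0, 22.0, 0.005) == pytest.approx(0.005)

    def test_ambient_sample_returns_zero_with_warning(self):
        with pytest.warns(UserWarning, match="flat profile"):
            assert dir_depth(22.0, 34.0, 22.0, 0.005) == 0.0
        with pytest.warns(UserWarning, match="flat profile"):
            assert dir_intensity(22.0, 34.0, 22.0, 0.005, H0) == 0.0

    def test_sample_at_or_above_peak_singular(self):
        with pytest.raises(SingularInversionError):
            dir_depth(34.0, 34.0, 22.0, 0.005)
        with pytest.raises(SingularInversionError):
            dir_intensity(35.0, 34.0, 22.0, 0.005, H0)

    def test_sample_below_ambient_rejected(self):
        with pytest.raises(SingularInversionError):
            dir_depth(21.0, 34.0, 22.0, 0.005)

    def test_intensity_linear_in_contrast_at_fixed_shape(self):
        q1 = dir_intensity(28.0, 34.0, 22.0, 0.005, H0)
        q2 = dir_intensity(34.0, 46.0, 22.0, 0.005, H0)  # both contrasts doubled
        assert q2 == pytest.approx(2 * q1, rel=1e-12)

    @settings(derandomize=True, max_examples=60)
    @given(
        d=st.floats(0.002, 0.02),
        elev=st.floats(2.0, 12.0),
        k=st.integers(1, 30),
    )
    def test_agrees_with_brute_force_inversion(self, d, elev, k):
        q = elev * 4 * math.pi * H0 * d**2
        src = HeatSourceTruth((0, 0), d, q)
        a = k * PIXEL_SIZE
        t_a = forward_temperature_point(a, src)
        tmax = forward_temperature_point(0.0, src)
        d_hat = dir_depth(t_a, tmax, TE, a)
        assert d_hat == pytest.approx(brute_force_depth(t_a, tmax, TE, a), rel=1e-9)
        assert d_hat == pytest.approx(d, rel=1e-9)


class TestSourceRadius:
    def test_unit_case(self):
        c = ModelConstants(qm=418.6, at=1.0)
        assert source_radius(418.6, c) == pytest.approx(1.0, rel=1e-12)

    def test_zero_intensity(self):
        assert source_radius(0.0) == 0.0

    def test_worked_example(self):
        assert source_radius(0.13224) == pytest.approx(0.0681, abs=5e-5)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            source_radius(-0.1)

    @settings(derandomize=True, max_examples=40)
    @given(q=st.floats(1e-6, 10.0))
    def test_scale_covariance(self, q):
        assert source_radius(8 * q) == pytest.approx(2 * source_radius(q), rel=1e-12)

    def test_sphere_convention(self):
        c = ModelConstants(radius_convention="sphere")
        assert source_radius(1.0, c) == pytest.approx((3 / (4 * math.pi * 418.6)) ** (1 / 3))


class TestThetaAngle:
    @pytest.mark.parametrize(
        "q, a, expected",
        [
            (0.0, 0.01, 0.0),
            (0.01, 0.01, 45.0),
            (0.13224, 0.0168, 82.76),
            (0.5, 0.0, 90.0),
            (0.0, 0.0, 0.0),
        ],
    )
    def test_values(self, q, a, expected):
        assert theta_angle(q, a) == pytest.approx(expected, abs=5e-3)


class TestRSquared:
    def test_perfect_fit(self):
        y = np.array([1.0, 2.0, 5.0])
        assert r_squared(y, y) == 1.0

    def test_mean_predictor_zero(self):
        y = np.array([1.0, 2.0, 3.0])
        assert r_squared(y, np.full(3, 2.0)) == 0.0

    def test_hand_arithmetic(self):
        assert r_squared(np.array([1.0, 2.0, 3.0]), np.array([1.0, 2.0, 4.0])) == pytest.approx(0.5)

    def test_constant_observed_undefined(self):
        with pytest.raises(ValueError):
            r_squared(np.full(3, 2.0), np.array([1.0, 2.0, 3.0]))


class TestLorentzFit:
    def test_recovers_generating_parameters(self):
        offsets = np.arange(31) * PIXEL_SIZE
        A, w, y0 = 0.0012, 0.01, 22.0
        temps = A / (offsets**2 + w**2) + y0
        prof = RoIProfile(offsets, temps, float(temps[0]), (0, 0), TE,
                          np.full(31, 4))
        fit = lorentz_fit(prof)
        assert fit.amplitude == pytest.approx(A, rel=1e-6)
        assert fit.width == pytest.approx(w, rel=1e-6)
        assert fit.offset == pytest.approx(y0, rel=1e-6)
        assert fit.fit_r_squared == pytest.approx(1.0, abs=1e-12)

    def test_flat_profile_fails(self):
        offsets = np.arange(10) * PIXEL_SIZE
        prof = RoIProfile(offsets, np.full(10, 30.0), 30.0, (0, 0), TE, np.full(10, 4))
        with pytest.raises(FitFailureError):
            lorentz_fit(prof)

    def test_width_reported_positive(self, noiseless_profile):
        assert lorentz_fit(noiseless_profile).width > 0

    def test_params_convention(self):
        assert lorentz_params(0.0012, 0.01) == (0.01, 0.0012)
        assert lorentz_params(0.0012, -0.01) == (0.01, 0.0012)
        assert lorentz_params(0.0, 0.01)[1] == 0.0


class TestPatternVector:
    def test_dir_constant_across_offsets_on_noiseless_profile(self, noiseless_profile):
        vectors = [
            pattern_vector(noiseless_profile, "dir", k * PIXEL_SIZE)
            for k in range(1, 31)
        ]
        depths = {round(v.depth, 12) for v in vectors}
        intensities = {round(v.intensity, 10) for v in vectors}
        assert len(depths) == 1 and len(intensities) == 1
        assert vectors[0].depth == pytest.approx(0.01, rel=1e-9)
        assert vectors[0].fit_r_squared == pytest.approx(1.0, abs=1e-12)

    def test_lorentz_matches_dir_up_to_units(self, noiseless_profile):
        a = 28 * PIXEL_SIZE
        v_dir = pattern_vector(noiseless_profile, "dir", a)
        v_lor = pattern_vector(noiseless_profile, "lorentz", a)
        assert v_lor.depth == pytest.approx(v_dir.depth, rel=1e-6)
        # Lorentz intensity uses the 4 pi h0 = 1 convention
        assert v_lor.intensity * 4 * math.pi * H0 == pytest.approx(v_dir.intensity, rel=1e-6)
        assert v_lor.tmax == v_dir.tmax

    def test_off_grid_offset_rejected(self, noiseless_profile):
        with pytest.raises(ValueError, match="not on the profile grid"):
            pattern_vector(noiseless_profile, "dir", 0.00123)

    def test_zero_offset_rejected(self, noiseless_profile):
        with pytest.raises(ValueError):
            pattern_vector(noiseless_profile, "dir", 0.0)

    def test_feature_order(self, noiseless_profile):
        v = pattern_vector(noiseless_profile, "dir", PIXEL_SIZE)
        feats = v.as_features()
        assert feats[0] == v.tmax and feats[4] == v.theta


class TestNoiseRobustness:
    def test_lorentz_depth_median_error_under_sensor_noise(self):
        """With 0.04 degC sensor noise the fitted depth stays within 10%
        median relative error for peaks >= 2 degC above ambient."""
        rng = np.random.default_rng(123)
        offsets = np.arange(31) * PIXEL_SIZE
        d, elev = 0.008, 3.0
        q = elev * 4 * math.pi * H0 * d**2
        src = HeatSourceTruth((0, 0), d, q)
        clean = forward_temperature_point(offsets, src)
        errors = []
        for _ in range(200):
            noisy = clean + rng.normal(0.0, 0.04 / 2, size=31)  # mean of 4 rays
            noisy[0] = max(noisy[0], noisy[1:].max() + 1e-9)  # peak stays the max
            prof = RoIProfile(offsets, noisy, float(noisy[0]), (0, 0), TE, np.full(31, 4))
            fit = lorentz_fit(prof)
            errors.append(abs(fit.width - d) / d)
        assert np.median(errors) < 0.10

    def test_fit_quality_degrades_with_noise(self):
        rng = np.random.default_rng(7)
        offsets = np.arange(31) * PIXEL_SIZE
        src = HeatSourceTruth((0, 0), 0.008, 3.0 * 4 * math.pi * H0 * 0.008**2)
        clean = forward_temperature_point(offsets, src)
        mean_rsq = []
        for sd in (0.0, 0.04, 0.2):
            vals = []
            for _ in range(20):
                noisy = clean + rng.normal(0.0, sd, size=31)
                noisy[0] = max(noisy[0], noisy[1:].max() + 1e-9)
                prof = RoIProfile(offsets, noisy, float(noisy[0]), (0, 0), TE,
                                  np.full(31, 4))
                vals.append(lorentz_fit(prof).fit_r_squared)
            mean_rsq.append(np.mean(vals))
        assert mean_rsq[0] == pytest.approx(1.0, abs=1e-9)
        assert mean_rsq[0] > mean_rsq[1] > mean_rsq[2]
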