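"""Standard-spectrum clean-up: regrid, exclusions, baseline, floor, smooth, normalize."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from nmrmixsim import (
    SimulationParameters,
    StandardSpectrum,
    ValidationError,
    apply_exclusion_regions,
    baseline_correct,
    kernel_smooth,
    normalize_unit_integral,
    preprocess_standard,
    regrid,
    remove_negative_artifacts,
)
from nmrmixsim.preprocess import _kernel_weights
from nmrmixsim.synthetic_standards import (
    LorentzianSpec,
    MultipletShape,
    make_lorentzian_standard,
)

from conftest import constant_spectrum


def brute_force_kernel_smooth(y, kernel, bandwidth, threshold_fraction):
    """Independent point-by-point weighted-mean oracle."""
    half = 3 * bandwidth if kernel == "normal" else bandwidth
    threshold = threshold_fraction * y.max()
    out = y.copy()
    for i in range(y.size):
        if not y[i] < threshold:
            continue
        lo, hi = max(0, i - half), min(y.size - 1, i + half)
        num = den = 0.0
        for j in range(lo, hi + 1):
            u = (j - i) / bandwidth
            if kernel == "normal":
                w = math.exp(-0.5 * u * u)
            elif kernel == "box":
                w = 1.0
            elif kernel == "triangle":
                w = max(0.0, 1.0 - abs(u))
            else:  # epanechnikov
                w = max(0.0, 1.0 - u * u)
            num += w * y[j]
            den += w
        out[i] = num / den
    return out


class TestRegrid:
    def test_identical_grid_is_identity(self, grid4k, singlet_spectrum):
        s, _ = singlet_spectrum
        out = regrid(s, grid4k)
        assert np.array_equal(out.intensity, s.intensity)

    def test_linear_signal_interpolates_exactly(self):
        s = StandardSpectrum("m", "e", [0.0, 1.0, 2.0], [0.0, 2.0, 4.0])
        out = regrid(s, np.array([0.25, 0.5, 1.5]))
        assert np.allclose(out.intensity, [0.5, 1.0, 3.0])

    def test_points_outside_range_are_zero(self):
        s = StandardSpectrum("m", "e", [1.0, 2.0], [5.0, 5.0])
        out = regrid(s, np.array([0.0, 1.5, 3.0]))
        assert out.intensity[0] == 0.0 and out.intensity[2] == 0.0


class TestExclusionRegions:
    def test_default_regions_zero_exactly(self):
        params = SimulationParameters(ppm_min=0.0, ppm_max=10.0, n_points=1001)
        s = constant_spectrum(1.0, params.grid())
        out = apply_exclusion_regions(s, params.exclusion_regions)
        in_excl = ((out.ppm >= 0.0) & (out.ppm <= 0.2)) | (
            (out.ppm >= 4.5) & (out.ppm <= 6.0)
        )
        assert np.all(out.intensity[in_excl] == 0.0)
        assert np.all(out.intensity[~in_excl] == 1.0)

    def test_empty_region_list_is_identity(self, grid4k):
        s = constant_spectrum(2.0, grid4k)
        assert np.array_equal(apply_exclusion_regions(s, []).intensity, s.intensity)

    def test_region_covering_grid_zeroes_all(self, grid4k):
        s = constant_spectrum(2.0, grid4k)
        out = apply_exclusion_regions(s, [(-1.0, 11.0)])
        assert np.all(out.intensity == 0.0)

    def test_idempotent_and_bitwise_zero(self, grid4k):
        s = constant_spectrum(3.0, grid4k)
        once = apply_exclusion_regions(s, [(1.0, 2.0)])
        twice = apply_exclusion_regions(once, [(1.0, 2.0)])
        assert np.array_equal(once.intensity, twice.intensity)
        mask = (s.ppm >= 1.0) & (s.ppm <= 2.0)
        assert np.all(once.intensity[mask] == 0.0)


class TestBaselineCorrect:
    def test_all_zero_unchanged(self, grid4k):
        s = constant_spectrum(0.0, grid4k)
        assert np.array_equal(baseline_correct(s, 0.3125, 10).intensity, s.intensity)

    def test_constant_above_threshold_unchanged(self, grid4k):
        # a constant equals its own maximum, so every point sits at or
        # above max/10 and nothing is corrected
        s = constant_spectrum(7.0, grid4k)
        assert np.array_equal(baseline_correct(s, 0.3125, 10).intensity, s.intensity)

    def test_offset_removed_peak_untouched(self):
        grid = np.linspace(0.0, 10.0, 4001)  # apex lands exactly on a grid point
        spec = LorentzianSpec(
            multiplets=[MultipletShape(centre=5.0, half_width=0.01)], baseline=(5.0,)
        )
        s, _ = make_lorentzian_standard(spec, grid, scale=100.0 * math.pi * 0.01)
        # peak height ~100 on constant offset 5
        assert s.intensity.max() == pytest.approx(105.0, rel=0.01)
        out = baseline_correct(s, 0.3125, 10)
        apex = np.argmax(s.intensity)
        assert out.intensity[apex] == s.intensity[apex]
        off_peak = np.abs(grid - 5.0) > 1.0
        assert np.all(np.abs(out.intensity[off_peak]) < 0.5)

    def test_window_smaller_than_spacing_rejected(self, grid4k):
        s = constant_spectrum(1.0, grid4k)
        with pytest.raises(ValidationError):
            baseline_correct(s, 1e-6, 10)


class TestRemoveNegativeArtifacts:
    def test_constant_spectrum_unchanged(self, grid4k):
        s = constant_spectrum(4.0, grid4k)
        out, M, sigma_med, limit = remove_negative_artifacts(s, 32)
        assert sigma_med == 0.0 and limit == M == 4.0
        assert np.array_equal(out.intensity, s.intensity)

    def test_limit_against_hand_computation_single_bin(self):
        # 6-point vector, one bin: sigma_med is the global sample SD.
        # y = 1..6: M = 3.5, var = 3.5, l = 3.5 - 3*sqrt(3.5)
        y = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        s = StandardSpectrum("m", "e", np.arange(6.0), y)
        out, M, sigma_med, limit = remove_negative_artifacts(s, 1)
        assert M == 3.5
        assert sigma_med == pytest.approx(math.sqrt(3.5), abs=1e-12)
        assert limit == pytest.approx(3.5 - 3 * math.sqrt(3.5), abs=1e-12)

    def test_dip_raised_to_limit(self):
        # zeros except one dip: most bins have zero SD, so sigma_med = 0
        # and the floor sits at the median (0); the dip is clipped to it
        y = np.zeros(256)
        y[100] = -10.0
        s = StandardSpectrum("m", "e", np.arange(256.0), y)
        out, M, sigma_med, limit = remove_negative_artifacts(s, 32)
        # independent recomputation of the rule
        exp_sigma = float(np.median([np.std(b, ddof=1) for b in np.array_split(y, 32)]))
        exp_limit = float(np.median(y)) - 3 * exp_sigma
        assert sigma_med == exp_sigma and limit == exp_limit
        assert out.intensity.min() >= limit
        assert out.intensity[100] == limit

    def test_applying_twice_equals_once(self):
        rng = np.random.default_rng(8)
        y = rng.standard_normal(512)
        s = StandardSpectrum("m", "e", np.arange(512.0), y)
        once, *_ = remove_negative_artifacts(s, 32)
        twice, _, _, l2 = remove_negative_artifacts(once, 32)
        # the recomputed limit can only move up, never uncovering clipped points
        assert np.all(twice.intensity >= once.intensity)


class TestKernelSmooth:
    def test_constant_unchanged(self, grid4k):
        s = constant_spectrum(5.0, grid4k)
        out = kernel_smooth(s, "normal", 3, 0.5)
        assert np.allclose(out.intensity, 5.0, atol=1e-12)

    def test_nothing_below_threshold_is_identity(self):
        rng = np.random.default_rng(0)
        y = 10.0 + rng.uniform(0, 1, 128)
        s = StandardSpectrum("m", "e", np.arange(128.0), y)
        # threshold = 0.5 * max < min(y): nothing is below it
        out = kernel_smooth(s, "normal", 3, 0.5)
        assert np.array_equal(out.intensity, y)

    def test_white_noise_variance_reduced_and_matches_oracle(self):
        rng = np.random.default_rng(1)
        y = rng.standard_normal(1024)
        s = StandardSpectrum("m", "e", np.arange(1024.0), y)
        out = kernel_smooth(s, "normal", 5, 1.0)
        assert out.intensity.var() < y.var()
        oracle = brute_force_kernel_smooth(y, "normal", 5, 1.0)
        assert np.allclose(out.intensity, oracle, atol=1e-12, rtol=0)

    def test_unknown_kernel_rejected(self, grid4k):
        with pytest.raises(ValidationError):
            kernel_smooth(constant_spectrum(1.0, grid4k), "cauchy", 3, 0.5)

    @settings(max_examples=100, derandomize=True, deadline=None)
    @given(
        data=st.lists(
            st.floats(min_value=-100, max_value=100, allow_nan=False), min_size=8, max_size=48
        ),
        kernel=st.sampled_from(["normal", "box", "triangle", "epanechnikov"]),
        bandwidth=st.integers(min_value=1, max_value=5),
        frac=st.floats(min_value=0.05, max_value=1.0),
    )
    def test_equals_brute_force_oracle(self, data, kernel, bandwidth, frac):
        y = np.asarray(data)
        s = StandardSpectrum("m", "e", np.arange(float(y.size)), y)
        out = kernel_smooth(s, kernel, bandwidth, frac)
        oracle = brute_force_kernel_smooth(y, kernel, bandwidth, frac)
        assert np.allclose(out.intensity, oracle, atol=1e-9, rtol=0)

    def test_attenuation_factor_of_weights(self):
        # interior-point variance attenuation of smoothed white noise is
        # sum(w^2)/sum(w)^2; used by the mixture noise checks
        w = _kernel_weights("normal", 5)
        factor = float((w**2).sum() / w.sum() ** 2)
        assert 0 < factor < 1


class TestNormalize:
    @pytest.mark.parametrize(
        "y,expected",
        [([2, 2, 2, 2], [0.25, 0.25, 0.25, 0.25]), ([1, 0, 3], [0.25, 0, 0.75])],
    )
    def test_examples(self, y, expected):
        s = StandardSpectrum("m", "e", np.arange(float(len(y))), np.array(y, dtype=float))
        out = normalize_unit_integral(s)
        assert np.allclose(out.intensity, expected)
        assert out.stage == "normalized"

    def test_idempotent(self):
        s = StandardSpectrum("m", "e", np.arange(4.0), np.array([0.1, 0.2, 0.3, 0.4]))
        once = normalize_unit_integral(s)
        twice = normalize_unit_integral(once)
        assert np.array_equal(once.intensity, twice.intensity)

    def test_scale_invariant(self):
        rng = np.random.default_rng(2)
        y = rng.uniform(0, 1, 64)
        s1 = StandardSpectrum("m", "e", np.arange(64.0), y)
        s2 = StandardSpectrum("m", "e", np.arange(64.0), 17.3 * y)
        assert np.allclose(
            normalize_unit_integral(s1).intensity, normalize_unit_integral(s2).intensity
        )

    def test_all_zero_rejected(self, grid4k):
        with pytest.raises(ValidationError):
            normalize_unit_integral(constant_spectrum(0.0, grid4k))


class TestPreprocessPipeline:
    def test_all_zero_raw_spectrum_errors_at_normalization(self, small_params):
        s = constant_spectrum(0.0, small_params.grid())
        with pytest.raises(ValidationError):
            preprocess_standard(s, small_params)

    def test_clean_standard_has_unit_integral(self, small_params, singlet_spectrum):
        s, _ = singlet_spectrum
        out, report = preprocess_standard(s, small_params)
        assert out.stage == "normalized"
        assert out.intensity.sum() == pytest.approx(1.0, abs=1e-9)
        assert out.intensity.min() >= 0.0
        assert report.clip_limit == report.intensity_median - 3 * report.sigma_med

    @staticmethod
    def _aligned_fixture(noise_sd=0.0, baseline=(), rng=None):
        # area ratio 1:2 carried by line count at equal line heights, all
        # lines exactly on grid points and at the same phase relative to
        # the 0.3125-ppm baseline windows (120 grid steps on 4033
        # points), so the thresholded baseline/smoothing steps treat
        # every line alike and only lineshape tails differ
        params = SimulationParameters(n_points=4033, shift_enabled=False, snr=float("inf"))
        spec = LorentzianSpec(
            multiplets=[
                MultipletShape(centre=2.0, half_width=0.003, area_weight=1.0),
                MultipletShape(centre=7.9375, j_spacing=1.875, weights=(1.0, 1.0),
                               half_width=0.003, area_weight=2.0),
            ],
            baseline=tuple(baseline),
            noise_sd=noise_sd,
        )
        s, truth = make_lorentzian_standard(spec, params.grid(), rng=rng)
        return params, s, truth

    @staticmethod
    def _region_fraction(spectrum):
        a = spectrum.intensity[spectrum.ppm < 4.5].sum()
        b = spectrum.intensity[spectrum.ppm > 6.0].sum()
        return a / (a + b)

    def test_noiseless_fixture_relative_areas_preserved(self):
        params, s, truth = self._aligned_fixture()
        out, _ = preprocess_standard(s, params)
        truth_frac = truth["multiplets"][0]["area_fraction"]
        assert self._region_fraction(out) == pytest.approx(truth_frac, rel=1e-3)

    def test_noisy_fixture_area_fractions_within_2_percent(self):
        params, s, truth = self._aligned_fixture(
            noise_sd=5.0, baseline=(20.0, 1.0), rng=np.random.default_rng(9)
        )
        out, _ = preprocess_standard(s, params)
        truth_frac = truth["multiplets"][0]["area_fraction"]
        assert self._region_fraction(out) == pytest.approx(truth_frac, rel=0.02)
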