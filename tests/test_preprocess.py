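"""Deconvolution, filters, profiles and projections."""

import numpy as np
import pytest
from scipy.ndimage import gaussian_filter

from mitomorph.preprocess import (
    blind_deconvolve,
    brightest_window,
    contrast_stretch,
    fft_filter,
    gaussian_psf,
    project,
    psf_sigma_from_optics,
    section_profile,
    spatial_filter_2d,
)
from mitomorph.stack import ZStack


@pytest.fixture(scope="module")
def blurred_bead():
    """Point source blurred with a known anisotropic Gaussian PSF."""
    vol = np.zeros((24, 48, 48))
    vol[12, 24, 24] = 8000.0
    blurred = gaussian_filter(vol, (2.4, 1.2, 1.2))
    return ZStack(blurred, 1, 1, bit_depth=16)


class TestBlindDeconvolve:
    def test_zero_cycles_is_identity(self, blurred_bead):
        out = blind_deconvolve(blurred_bead, cycles=0)
        assert np.array_equal(out.data, blurred_bead.data)

    def test_peak_strictly_increases_over_cycles(self, blurred_bead):
        peaks = [
            blind_deconvolve(blurred_bead, cycles=c, psf_sigma=(2.4, 1.2)).data.max()
            for c in (2, 4, 6, 8, 10)
        ]
        assert all(a < b for a, b in zip(peaks, peaks[1:]))

    def test_flux_conserved_within_one_percent(self, blurred_bead):
        out = blind_deconvolve(blurred_bead, cycles=10, psf_sigma=(2.4, 1.2))
        assert abs(out.data.sum() / blurred_bead.data.sum() - 1) < 0.01

    def test_output_nonnegative(self, blurred_bead):
        out = blind_deconvolve(blurred_bead, cycles=10, psf_sigma=(2.4, 1.2))
        assert out.data.min() >= 0

    def test_delta_psf_on_sharp_image_is_identity(self):
        img = np.zeros((5, 32, 32))
        img[2, 10:20, 10:20] = 100.0
        stack = ZStack(img, 1, 1, bit_depth=16)
        delta = np.zeros((3, 3, 3))
        delta[1, 1, 1] = 1.0
        out = blind_deconvolve(stack, cycles=5, psf_init=delta)
        assert np.abs(out.data - img).max() < 1.0

    def test_single_section_3d_mode_errors(self):
        stack = ZStack(np.ones((1, 8, 8), np.uint8), 1, 1)
        with pytest.raises(ValueError, match="2d"):
            blind_deconvolve(stack, cycles=2)

    def test_2d_mode_accepts_single_section(self):
        rng = np.random.default_rng(0)
        data = gaussian_filter(rng.random((1, 32, 32)) * 100, (0, 1.2, 1.2))
        stack = ZStack(data, 1, 1, bit_depth=16)
        out = blind_deconvolve(stack, cycles=3, mode="2d", psf_sigma=(0, 1.2))
        assert out.shape == stack.shape

    def test_optics_sigma_has_sane_scale(self):
        sz, sxy = psf_sigma_from_optics(1.4, 510, 0.0845, 0.364)
        # lateral blur ~1 px at Nyquist-ish sampling, axial a bit wider in µm
        assert 0.5 < sxy < 2.0
        assert 0.5 < sz < 2.0

    def test_gaussian_psf_normalized(self):
        psf = gaussian_psf((2.0, 1.0, 1.0))
        assert psf.sum() == pytest.approx(1.0)
        assert psf.min() >= 0


class TestSpatialFilter:
    def test_constant_image_maps_to_zero(self):
        out = spatial_filter_2d(np.full((32, 32), 57.0))
        assert np.abs(out).max() == pytest.approx(0.0, abs=1e-9)

    def test_concordant_with_deconvolution_path(self):
        """The spatial-filtering path and the deconvolution path give
        per-section 2D descriptors that agree within 20% on a synthetic
        stack — the two processing routes are interchangeable for 2D
        analysis."""
        from mitomorph.report import analyze_2d
        from mitomorph.synthetic import simulate_cell_stack

        stack, _ = simulate_cell_stack("filamentous", seed=1)
        k = section_profile(stack).argmax
        spatial = analyze_2d(
            spatial_filter_2d(stack.data[k].astype(float)), fraction=0.2
        )
        dec = blind_deconvolve(stack, cycles=10, psf_sigma=(2.0, 1.0))
        deconv = analyze_2d(dec.data[k], fraction=0.2)
        a_sp = spatial.summary.totals["A_m_ROI"]
        a_dc = deconv.summary.totals["A_m_ROI"]
        assert abs(a_sp / a_dc - 1) < 0.20
        assert abs(spatial.summary.n_roi - deconv.summary.n_roi) <= 1

    def test_haze_suppressed_under_rod(self):
        img = np.full((48, 48), 40.0)  # uniform haze
        img[22:26, 8:40] += 160.0  # bright rod
        out = spatial_filter_2d(img)
        background = np.ones_like(img, bool)
        background[18:30, 4:44] = False
        assert out[background].mean() < 0.5 * 40.0
        # rod still dominant
        assert out[23, 24] > 100


class TestFFTFilter:
    def test_allpass_lowpass_is_identity(self):
        rng = np.random.default_rng(0)
        img = rng.random((32, 32)) * 100
        out = fft_filter(img, aoi_radius=100, hipass=False, rolloff=0.5)
        assert np.abs(out - img).max() < 1.0

    def test_hipass_removes_constant_background(self):
        img = np.full((64, 64), 50.0)
        img[30:34, 10:54] += 150.0
        out = fft_filter(img, aoi_radius=3, hipass=True)
        background = np.ones_like(img, bool)
        background[26:38, 6:58] = False
        assert out[background].mean() < 0.5 * 50.0

    def test_contrast_increases_as_radius_shrinks(self):
        # peak/background contrast on a line profile across synthetic rods
        img = np.full((64, 64), 30.0)
        for y in (16, 32, 48):
            img[y - 1 : y + 2, 8:56] += 170.0
        contrasts = []
        for r in (10, 5, 2):
            out = fft_filter(img, aoi_radius=r, hipass=True)
            profile = out[:, 32]
            peak = max(profile[y] for y in (16, 32, 48))
            valley = np.median(profile)
            contrasts.append(peak - valley)
        assert contrasts[0] < contrasts[1] < contrasts[2]

    def test_bad_radius_rejected(self):
        with pytest.raises(ValueError):
            fft_filter(np.ones((8, 8)), aoi_radius=0)


class TestContrastStretch:
    def test_identity_on_full_range(self):
        data = np.arange(256, dtype=np.uint8).reshape(1, 16, 16)
        out = contrast_stretch(ZStack(data, 1, 1), 0, 255)
        assert np.array_equal(out.data, data)

    def test_midpoint_maps_to_128(self):
        # documented rounding: numpy round-half-even at the midpoint
        arr = np.array([[[50.0]]])
        out = contrast_stretch(arr, 0, 100)
        assert out[0, 0, 0] == 128

    def test_below_min_all_zero_above_max_saturates(self):
        arr = np.array([[[10.0, 20.0, 250.0]]])
        out = contrast_stretch(arr, 30, 200)
        assert out[0, 0, 0] == 0 and out[0, 0, 1] == 0 and out[0, 0, 2] == 255

    def test_constant_input_with_auto_limits_errors(self):
        with pytest.raises(ValueError, match="undefined"):
            contrast_stretch(np.full((1, 4, 4), 7.0))


class TestProfilesAndProjections:
    def test_all_zero_stack_profile(self):
        prof = section_profile(ZStack(np.zeros((4, 8, 8), np.uint8), 1, 1))
        assert prof.sums.tolist() == [0, 0, 0, 0]
        assert prof.argmax == 0

    def test_test_stack_profile_shape(self, test_stack):
        stack, _ = test_stack
        prof = section_profile(stack)
        assert prof.sums[0] == prof.sums[4] == 0
        assert prof.sums[1] == prof.sums[2] == prof.sums[3] > 0
        assert prof.argmax == 1  # ties break to the lowest index

    def test_brightest_window_centers_on_peak(self):
        data = np.zeros((9, 4, 4), np.uint8)
        data[6] = 100
        stack = ZStack(data, 1, 1)
        assert brightest_window(stack, 3) == [5, 6, 7]

    def test_single_section_projection_is_that_section(self, test_stack):
        stack, _ = test_stack
        for method in ("average", "mic"):
            out = project(stack, method, sections=[2])
            assert np.array_equal(out, stack.data[2].astype(float))

    def test_mic_dominates_average_and_sections(self):
        rng = np.random.default_rng(3)
        stack = ZStack(rng.integers(0, 255, (5, 16, 16), dtype=np.uint8), 1, 1)
        avg = project(stack, "average")
        mic = project(stack, "mic")
        assert (mic >= avg - 1e-9).all()
        assert (mic >= stack.data.max(axis=0) - 1e-9).all()

    def test_average_and_mic_values(self):
        data = np.zeros((3, 1, 1))
        data[:, 0, 0] = [0, 3, 6]
        stack = ZStack(data, 1, 1, bit_depth=16)
        assert project(stack, "average")[0, 0] == pytest.approx(3.0)
        assert project(stack, "mic")[0, 0] == pytest.approx(6.0)

    def test_empty_selection_errors(self, test_stack):
        with pytest.raises(ValueError, match="empty"):
            project(test_stack[0], "mic", sections=[])
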