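"""Conditioning-chain contracts: each of the nine steps and the chain."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from ramanbrain.axis import N_TRUNCATED_BINS, SPACING, WavenumberAxis, factory_axis
from ramanbrain.preprocess import (
    PreprocessingError,
    Spectrum,
    average_repeats,
    correct_instrument_response,
    fit_axis_calibration,
    preprocess_acquisition,
    preprocess_cohort,
    remove_cosmic_rays,
    savgol_smooth,
    snv,
    subtract_dark,
    truncate_spectrum,
)
from ramanbrain.synthetic import (
    CalibrationReferences,
    GeneratorConfig,
    generate_cohort,
)


class TestSubtractDark:
    def test_frame_equal_to_dark_gives_zero(self):
        dark = np.arange(10.0)
        out = subtract_dark(dark[None, :], dark)
        np.testing.assert_array_equal(out, np.zeros((1, 10)))

    def test_constant_offset_preserved_without_clipping(self):
        dark = np.full(8, 100.0)
        out = subtract_dark((dark - 5.0)[None, :], dark)
        np.testing.assert_array_equal(out, np.full((1, 8), -5.0))

    def test_length_mismatch_raises(self):
        with pytest.raises(PreprocessingError, match="dark"):
            subtract_dark(np.zeros((2, 5)), np.zeros(4))

    def test_noiseless_frame_minus_dark_is_response_times_truth(
            self, noiseless_cohort):
        acq = noiseless_cohort.acquisitions[0]
        truth = noiseless_cohort.truth[acq.location_id]
        out = subtract_dark(acq.frames, acq.dark_frame)
        np.testing.assert_allclose(out[0], truth.baseline + truth.signal,
                                   atol=1e-9)


class TestCosmicRayRemoval:
    def test_constant_frames_pass_through(self):
        frames = np.tile(np.linspace(1, 5, 20), (6, 1))
        np.testing.assert_array_equal(remove_cosmic_rays(frames), frames)

    def test_planted_spike_removed(self, rng):
        frames = rng.poisson(1000.0, size=(20, 50)).astype(float)
        spiked = frames.copy()
        spiked[3, 25] += 50.0 * 1000.0
        cleaned = remove_cosmic_rays(spiked)
        median = np.median(frames[:, 25])
        mad = 1.4826 * np.median(np.abs(frames[:, 25] - median))
        assert abs(cleaned[3, 25] - median) < 3 * mad
        untouched = np.ones_like(frames, dtype=bool)
        untouched[3, 25] = False
        np.testing.assert_array_equal(cleaned[untouched], spiked[untouched])

    def test_false_positive_rate_below_a_thousandth(self, rng):
        frames = rng.poisson(2000.0, size=(20, 800)).astype(float)
        cleaned = remove_cosmic_rays(frames, k=8.0)
        changed = np.mean(cleaned != frames)
        assert changed < 1e-3

    def test_too_few_repeats_warns_and_passes_through(self):
        frames = np.ones((2, 10))
        with pytest.warns(UserWarning, match="fewer than 3"):
            out = remove_cosmic_rays(frames)
        np.testing.assert_array_equal(out, frames)


class TestTruncation:
    def test_factory_axis_truncates_to_521_bins(self):
        axis = factory_axis()
        spec = Spectrum(axis, np.ones(axis.n_bins), "raw_mean")
        out = truncate_spectrum(spec)
        assert out.n_bins == N_TRUNCATED_BINS

    def test_boundary_bins_retained(self):
        axis = factory_axis().truncate()
        assert axis.values[0] == pytest.approx(800.0, abs=1e-9)
        assert axis.values[-1] == pytest.approx(1750.0, abs=1e-9)

    def test_axis_inside_window_is_identity(self):
        axis = WavenumberAxis(np.linspace(900, 1500, 40), np.arange(40),
                              (900.0, 600.0 / 39.0))
        spec = Spectrum(axis, np.arange(40.0), "raw_mean")
        out = truncate_spectrum(spec)
        np.testing.assert_array_equal(out.intensities, spec.intensities)

    def test_empty_result_raises(self):
        axis = WavenumberAxis(np.linspace(100, 300, 20), np.arange(20),
                              (100.0, 200.0 / 19.0))
        spec = Spectrum(axis, np.ones(20), "raw_mean")
        with pytest.raises(PreprocessingError, match="truncate"):
            truncate_spectrum(spec)


class TestAxisCalibration:
    def _references(self, coeffs, noise=False, seed=0, known=None):
        """Reference spectrum with peaks at known positions under a map."""
        axis = factory_axis()
        pixels = axis.pixels.astype(float)
        values = coeffs[0] + coeffs[1] * pixels
        if known is None:
            known = (703.0, 887.0, 1114.0, 1235.0, 1602.0, 1775.0)
        y = np.full(pixels.size, 200.0)
        for pos in known:
            y += 5000.0 * np.exp(-0.5 * ((values - pos) / 4.0) ** 2)
        if noise:
            y = np.random.default_rng(seed).poisson(y).astype(float)
        return CalibrationReferences(
            wavenumber_reference=y, known_peak_positions=known,
            response_reference={}, response_known_curve=np.ones_like(y),
            axis=axis)

    def test_linear_map_recovered_exactly_noiseless(self):
        refs = self._references((400.0, 1.8269))
        fit = fit_axis_calibration(refs)
        assert fit.coefficients[0] == pytest.approx(400.0, abs=1e-6)
        assert fit.coefficients[1] == pytest.approx(1.8269, abs=1e-8)
        assert fit.rms_residual < 1e-6

    def test_identity_map_recovered(self):
        """Identity pixel map: declared positions equal apparent pixels."""
        known = (100.0, 250.0, 420.0, 600.0, 800.0)
        refs = self._references((0.0, 1.0), known=known)
        fit = fit_axis_calibration(refs)
        assert fit.coefficients[0] == pytest.approx(0.0, abs=1e-6)
        assert fit.coefficients[1] == pytest.approx(1.0, abs=1e-8)

    def test_noisy_reference_recovers_map_below_point1_rms(self):
        errors = []
        for seed in range(5):
            refs = self._references((401.75, SPACING), noise=True, seed=seed)
            fit = fit_axis_calibration(refs)
            true_values = 401.75 + SPACING * refs.axis.pixels
            errors.append(np.sqrt(np.mean(
                (fit.axis.values - true_values) ** 2)))
        assert np.median(errors) < 0.1

    def test_too_few_peaks_fails_with_diagnostic(self):
        axis = factory_axis()
        refs = CalibrationReferences(
            wavenumber_reference=np.full(axis.n_bins, 7.0),
            known_peak_positions=(703.0, 887.0, 1114.0),
            response_reference={}, response_known_curve=np.ones(axis.n_bins),
            axis=axis)
        with pytest.raises(PreprocessingError, match="calibrate"):
            fit_axis_calibration(refs)


class TestResponseCorrection:
    def test_flat_response_is_identity_up_to_scale(self):
        x = np.linspace(1.0, 2.0, 30)
        out = correct_instrument_response(x, np.full(30, 3.0), np.ones(30))
        np.testing.assert_allclose(out, x, rtol=1e-12)

    def test_halved_counts_double_after_correction(self):
        x = np.linspace(1.0, 2.0, 30)
        known = np.ones(30)
        measured = 0.5 * known
        half = correct_instrument_response(x, measured, known)
        np.testing.assert_allclose(half, x, rtol=1e-12)  # unit-mean: scale out
        varying = np.where(np.arange(30) < 15, 0.5, 1.0)
        out = correct_instrument_response(x, varying, known)
        assert out[0] / out[-1] == pytest.approx(2.0 * x[0] / x[-1], rel=1e-9)

    def test_nonpositive_response_fails(self):
        with pytest.raises(PreprocessingError, match="response"):
            correct_instrument_response(np.ones(5), np.zeros(5), np.ones(5))

    def test_two_sites_agree_after_correction(self):
        """Site-distorted responses are removed: corrected tumor-mean
        spectra from the two sites agree within a small fraction of the
        spectral dynamic range."""
        config = GeneratorConfig(n_patients_per_site=4,
                                 n_locations_per_patient=13,
                                 pathologies=("glioblastoma",),
                                 patient_effect_sd=0.0,
                                 location_effect_sd={"brain": 0.0,
                                                     "tumor": 0.0},
                                 lowq_fraction=0.0, seed=41)
        cohort = generate_cohort(config)
        spectra = preprocess_cohort(cohort)
        means = {}
        for site in config.sites:
            stack = [spectra[a.location_id].intensities
                     for a in cohort.acquisitions
                     if a.site == site and a.label == "tumor"]
            means[site] = np.mean(stack, axis=0)
        a, b = means[config.sites[0]], means[config.sites[1]]
        gap = np.max(np.abs(a - b)) / np.ptp(a)
        assert gap < 0.02


class TestAveraging:
    def test_identical_frames_average_to_themselves(self):
        frame = np.linspace(0, 9, 10)
        np.testing.assert_array_equal(average_repeats(np.tile(frame, (20, 1))),
                                      frame)

    def test_single_frame_is_itself(self):
        frame = np.arange(5.0)
        np.testing.assert_array_equal(average_repeats(frame[None, :]), frame)

    def test_variance_reduction_twenty_fold(self, rng):
        frames = rng.normal(0.0, 1.0, size=(20, 500))
        mean = average_repeats(frames)
        ratio = frames.var() / mean.var()
        assert ratio == pytest.approx(20.0, rel=0.2)


class TestSavgol:
    def test_cubic_polynomial_reproduced_exactly(self):
        x = np.linspace(-1, 1, 101)
        y = 2.0 + 0.5 * x - 3.0 * x ** 2 + 0.7 * x ** 3
        out = savgol_smooth(y)
        np.testing.assert_allclose(out[5:-5], y[5:-5], atol=1e-8)

    def test_constant_unchanged(self):
        np.testing.assert_allclose(savgol_smooth(np.full(50, 4.2)),
                                   np.full(50, 4.2), atol=1e-12)

    def test_white_noise_variance_reduced(self, rng):
        y = rng.normal(size=1000)
        assert savgol_smooth(y).var() < y.var()

    def test_window_longer_than_input_fails(self):
        with pytest.raises(PreprocessingError, match="smooth"):
            savgol_smooth(np.ones(5))


class TestSNV:
    def test_symmetric_pair_fixed_point(self):
        np.testing.assert_allclose(snv([1.0, -1.0]), [1.0, -1.0])

    def test_hand_computed_three_values(self):
        np.testing.assert_allclose(snv([1.0, 2.0, 3.0]),
                                   [-1.2247448, 0.0, 1.2247448], atol=1e-6)

    def test_zero_dispersion_fails(self):
        with pytest.raises(PreprocessingError, match="snv"):
            snv(np.full(10, 3.3))

    @given(st.lists(st.floats(-1e4, 1e4), min_size=3, max_size=200))
    def test_output_mean_zero_population_sd_one(self, values):
        arr = np.asarray(values)
        if arr.std() < 1e-9:
            return
        out = snv(arr)
        assert abs(out.mean()) < 1e-9
        assert abs(out.std() - 1.0) < 1e-9


class TestFullChain:
    def test_final_spectrum_is_snv_stage_with_521_bins(self, tiny_cohort):
        spectra = preprocess_cohort(tiny_cohort)
        for spec in spectra.values():
            assert spec.stage == "snv"
            assert spec.n_bins == N_TRUNCATED_BINS
            assert abs(spec.intensities.mean()) < 1e-9
            assert abs(spec.intensities.std() - 1.0) < 1e-9

    def test_noiseless_chain_recovers_planted_mixture(self, noiseless_cohort):
        """With no noise, no baseline error sources beyond BubbleFill and
        flat response, the final spectrum equals the SNV of the
        (smoothed) planted Gaussian mixture."""
        acq = noiseless_cohort.acquisitions[0]
        truth = noiseless_cohort.truth[acq.location_id]
        mask = noiseless_cohort.axis.truncation_mask()
        final = preprocess_acquisition(acq, noiseless_cohort.references)
        expected = snv(savgol_smooth(truth.signal[mask]))
        # BubbleFill removes a small share of the broad-band mass, so the
        # agreement is to a few percent of the SNV dynamic range
        err = np.max(np.abs(final.intensities - expected)) / np.ptp(expected)
        assert err < 0.05
        # peak positions and relative heights survive to high accuracy
        assert np.corrcoef(final.intensities, expected)[0, 1] > 0.999

    def test_reprocessing_is_deterministic(self, tiny_cohort):
        a = preprocess_cohort(tiny_cohort)
        b = preprocess_cohort(tiny_cohort)
        for loc in a:
            np.testing.assert_array_equal(a[loc].intensities,
                                          b[loc].intensities)
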