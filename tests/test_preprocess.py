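"""Preprocessing chain: calibrations, spike removal, EMSC, normalization."""

import numpy as np
import pandas as pd
import pytest

from pollenraman.errors import (
    CalibrationError,
    DegenerateFitError,
    NormalizationError,
    RegionError,
)
from pollenraman.preprocess import (
    EMSCModel,
    PipelineConfig,
    STAGE_ORDER,
    apply_response,
    area_normalize,
    calibrate_intensity,
    calibrate_wavenumber,
    crop_region,
    emsc_correct,
    emsc_fit,
    preprocess_pipeline,
    remove_cosmic_spikes,
)
from pollenraman.simulate import (
    ClassProfile,
    SpectrumDesign,
    generate_dataset,
    make_calibration_fixtures,
    water_reference,
)
from pollenraman.spectrum import Spectrum, SpectralDataset


def _spectrum(axis, intensities, **meta):
    return Spectrum(np.asarray(axis, float), np.asarray(intensities, float), meta)


class TestWavenumberCalibration:
    def test_identity_mapping_recovered(self):
        fx = make_calibration_fixtures([0.0, 1.0], n_pixels=512)
        cal = calibrate_wavenumber(fx.standard_intensities, fx.peak_table, degree=1)
        assert cal.residual_rms < 0.5
        recovered = cal.wavenumbers(fx.pixel_axis)
        assert np.max(np.abs(recovered - fx.pixel_axis)) < 0.5

    def test_known_cubic_recovered_within_half_wavenumber(self):
        coeffs = [500.0, 2.5, -3e-4, 2e-7]
        fx = make_calibration_fixtures(coeffs, n_pixels=1024, peak_wavenumbers=np.linspace(650, 2800, 10))
        cal = calibrate_wavenumber(fx.standard_intensities, fx.peak_table, degree=3)
        assert np.max(np.abs(cal.wavenumbers(fx.pixel_axis) - fx.true_wavenumbers)) < 0.5

    def test_too_few_peaks_for_degree(self):
        fx = make_calibration_fixtures([600.0, 2.0], n_pixels=256, peak_wavenumbers=[700.0, 1000.0])
        with pytest.raises(CalibrationError):
            calibrate_wavenumber(fx.standard_intensities, fx.peak_table, degree=3)


class TestIntensityCalibration:
    def test_equal_lamps_give_unit_factors(self):
        lamp = np.linspace(1, 2, 100)
        response = calibrate_intensity(lamp, lamp)
        np.testing.assert_allclose(response.factors, 1.0)
        spec = _spectrum(np.arange(100), np.sin(np.arange(100)) + 2)
        np.testing.assert_array_equal(apply_response(spec, response).intensities, spec.intensities)

    def test_known_smooth_ratio_recovered(self):
        axis = np.linspace(600, 3100, 400)
        certified = 1.0 + np.exp(-0.5 * ((axis - 1800) / 900) ** 2)
        curve = 0.5 + 0.4 * np.sin(axis / 700.0) ** 2
        measured = certified * curve
        response = calibrate_intensity(measured, certified)
        np.testing.assert_allclose(response.factors, 1.0 / curve, rtol=1e-9)
        corrected = measured * response.factors
        np.testing.assert_allclose(corrected, certified, rtol=1e-6)

    def test_mostly_nonpositive_measured_rejected(self):
        with pytest.raises(CalibrationError):
            calibrate_intensity(np.zeros(50), np.ones(50))


class TestSpikeRemoval:
    @pytest.fixture
    def band_spectrum(self):
        axis = np.linspace(600, 3100, 1200)
        clean = (
            1.0 * np.exp(-0.5 * ((axis - 1004) / 8) ** 2)
            + 0.8 * np.exp(-0.5 * ((axis - 1441) / 13) ** 2)
            + 0.02 * np.random.default_rng(0).standard_normal(axis.size)
        )
        return _spectrum(axis, clean)

    def test_spike_free_input_untouched(self, band_spectrum):
        out, spikes = remove_cosmic_spikes(band_spectrum)
        assert spikes.size == 0
        np.testing.assert_array_equal(out.intensities, band_spectrum.intensities)

    def test_single_channel_spike_removed_surgically(self, band_spectrum):
        y = band_spectrum.intensities.copy()
        y[700] += 50.0
        out, spikes = remove_cosmic_spikes(band_spectrum.with_intensities(y))
        assert list(spikes) == [700]
        untouched = np.ones(y.size, dtype=bool)
        untouched[700] = False
        np.testing.assert_array_equal(out.intensities[untouched], y[untouched])
        assert abs(out.intensities[700] - band_spectrum.intensities[700]) < 0.5

    def test_generator_spikes_identified_exactly(self):
        # on ground-truthed synthetic spectra every inserted cosmic hit is
        # flagged and nothing else is
        from pollenraman.simulate import SpectrumDesign, generate_dataset, separable_profiles

        profiles = separable_profiles(3, amplitude_delta=0.4)
        design = SpectrumDesign(n_per_class=10, noise_sd=0.02, spike_rate=0.5, seed=21)
        _, truth = generate_dataset(profiles, design, return_truth=True)
        assert sum(g.spike_channels.size for g in truth) > 0
        for gen in truth:
            _, spikes = remove_cosmic_spikes(gen.spectrum)
            assert set(spikes.tolist()) == set(gen.spike_channels.tolist())

    def test_wide_genuine_band_preserved(self, band_spectrum):
        out, spikes = remove_cosmic_spikes(band_spectrum, width_threshold=3)
        peak_channel = int(np.argmax(band_spectrum.intensities))
        assert peak_channel not in set(spikes.tolist())
        assert out.intensities[peak_channel] == band_spectrum.intensities[peak_channel]


class TestEMSC:
    @pytest.fixture
    def model(self):
        axis = np.linspace(600, 3100, 800)
        reference = (
            np.exp(-0.5 * ((axis - 1004) / 8) ** 2)
            + 0.7 * np.exp(-0.5 * ((axis - 1660) / 14) ** 2)
            + 0.5 * np.exp(-0.5 * ((axis - 2851) / 16) ** 2)
        )
        return EMSCModel(reference=reference, water=water_reference(axis), axis=axis)

    def test_reference_itself_gives_unit_coefficients(self, model):
        spec = _spectrum(model.axis, model.reference)
        c = emsc_fit(spec, model)
        np.testing.assert_allclose(c.as_array(), [1, 0, 0, 0, 0], atol=1e-9)
        np.testing.assert_allclose(emsc_correct(spec, model, c).intensities, model.reference, atol=1e-9)

    def test_exact_mixture_coefficients_recovered(self, model):
        nu = 2 * (model.axis - model.axis[0]) / (model.axis[-1] - model.axis[0]) - 1
        y = 2.0 * model.reference + 0.5 * model.water + 1.0 + 0.01 * nu
        c = emsc_fit(_spectrum(model.axis, y), model)
        np.testing.assert_allclose(c.as_array(), [2.0, 0.5, 1.0, 0.01, 0.0], atol=1e-6)
        corrected = emsc_correct(_spectrum(model.axis, y), model, c)
        np.testing.assert_allclose(corrected.intensities, model.reference, atol=1e-6)

    def test_noisy_fit_matches_normal_equations_oracle(self, model):
        rng = np.random.default_rng(4)
        y = 1.5 * model.reference + 0.3 * model.water + 0.5 + 0.05 * rng.standard_normal(model.axis.size)
        c = emsc_fit(_spectrum(model.axis, y), model)
        # independent solution of the normal equations
        D = model.design_matrix()
        expected = np.linalg.solve(D.T @ D, D.T @ y)
        np.testing.assert_allclose(c.as_array(), expected, atol=1e-8)

    @pytest.mark.parametrize("b", [2.0, -1.5, 0.2])
    def test_exact_recovery_property(self, model, b):
        nu = 2 * (model.axis - model.axis[0]) / (model.axis[-1] - model.axis[0]) - 1
        y = b * model.reference + 0.8 * model.water + 2.0 - 0.3 * nu + 0.1 * nu**2
        corrected = emsc_correct(_spectrum(model.axis, y), model)
        np.testing.assert_allclose(corrected.intensities, model.reference, atol=1e-6)

    def test_degenerate_b_rejected(self, model):
        y = 0.5 * model.water + 1.0
        with pytest.raises(DegenerateFitError):
            emsc_correct(_spectrum(model.axis, y), model, b_floor=1e-3)

    def test_noise_shrinks_correction_error(self, model):
        # mean deviation from the reference decreases as noise vanishes
        errs = []
        for noise_sd in (0.1, 0.01, 0.001):
            devs = []
            for seed in range(30):
                rng = np.random.default_rng(seed)
                y = 1.2 * model.reference + 0.4 * model.water + 1.0 + noise_sd * rng.standard_normal(model.axis.size)
                corrected = emsc_correct(_spectrum(model.axis, y), model)
                devs.append(np.mean(np.abs(corrected.intensities - model.reference)))
            errs.append(np.mean(devs))
        assert errs[0] > errs[1] > errs[2]


class TestNormalizeAndCrop:
    def test_simple_arithmetic(self):
        out = area_normalize(_spectrum([1, 2, 3], [2, 3, 5]))
        np.testing.assert_allclose(out.intensities, [0.2, 0.3, 0.5])

    def test_idempotent_and_unit_sum(self):
        rng = np.random.default_rng(0)
        spec = _spectrum(np.arange(50), rng.random(50) + 0.1)
        once = area_normalize(spec)
        assert abs(once.intensities.sum() - 1.0) < 1e-12
        twice = area_normalize(once)
        np.testing.assert_allclose(twice.intensities, once.intensities, rtol=1e-12)

    def test_nonpositive_area_rejected(self):
        with pytest.raises(NormalizationError):
            area_normalize(_spectrum([1, 2], [1.0, -1.0]))

    def test_crop_full_range_is_identity(self):
        spec = _spectrum(np.linspace(600, 3100, 100), np.arange(100))
        out = crop_region(spec, (600, 3100))
        np.testing.assert_array_equal(out.intensities, spec.intensities)

    def test_crop_fingerprint_boundaries_inclusive(self):
        axis = np.arange(600.0, 3100.0, 2.0)
        spec = _spectrum(axis, np.ones_like(axis))
        out = crop_region(spec, (758.0, 1800.0))
        # direct index computation of the inclusive window
        expected = axis[(axis >= 758.0) & (axis <= 1800.0)]
        np.testing.assert_array_equal(out.axis, expected)
        assert out.axis[0] >= 758.0 and out.axis[-1] <= 1800.0

    def test_disjoint_bounds_rejected(self):
        with pytest.raises(RegionError):
            crop_region(_spectrum(np.linspace(600, 3100, 10), np.ones(10)), (5000, 6000))


class TestPipeline:
    def _mixture_dataset(self, reference, axis, n=12, noise_sd=0.0, seed=0):
        rng = np.random.default_rng(seed)
        nu = 2 * (axis - axis[0]) / (axis[-1] - axis[0]) - 1
        water = water_reference(axis)
        rows, manifest = [], []
        for i in range(n):
            b = rng.uniform(0.5, 2.0)
            y = (
                b * reference
                + rng.uniform(0.2, 0.8) * water
                + rng.uniform(0.5, 2.0)
                + rng.uniform(-0.3, 0.3) * nu
                + rng.uniform(-0.2, 0.2) * nu**2
                + noise_sd * rng.standard_normal(axis.size)
            )
            rows.append(y)
            manifest.append({"id": f"s{i}", "species": "x", "genus": "x", "family": "x", "growth_habit": "herb"})
        return SpectralDataset(axis, np.vstack(rows), pd.DataFrame(manifest))

    def test_noise_free_mixtures_recover_normalized_reference(self):
        axis = np.linspace(600, 3100, 600)
        reference = np.exp(-0.5 * ((axis - 1004) / 8) ** 2) + 0.6 * np.exp(-0.5 * ((axis - 1441) / 13) ** 2)
        ds = self._mixture_dataset(reference, axis)
        model = EMSCModel(reference=reference, water=water_reference(axis), axis=axis)
        processed, log = preprocess_pipeline(ds, emsc_model=model)
        expected = reference / reference.sum()
        assert len(processed) == len(ds) and not log.dropped
        for row in processed.intensities:
            np.testing.assert_allclose(row, expected, atol=1e-6)

    def test_stage_order_is_canonical(self):
        axis = np.linspace(600, 3100, 300)
        reference = np.exp(-0.5 * ((axis - 1004) / 8) ** 2)
        ds = self._mixture_dataset(reference, axis, n=3)
        _, log = preprocess_pipeline(ds)
        assert tuple(log.stages) == STAGE_ORDER

    def test_empty_dataset_passes_through(self):
        axis = np.linspace(600, 3100, 50)
        empty = SpectralDataset(axis, np.empty((0, 50)), pd.DataFrame(columns=["id"]))
        processed, log = preprocess_pipeline(empty)
        assert len(processed) == 0 and log.n_in == log.n_out == 0

    def test_degenerate_spectrum_dropped_others_survive(self):
        axis = np.linspace(600, 3100, 400)
        reference = np.exp(-0.5 * ((axis - 1004) / 8) ** 2) + 0.5 * np.exp(-0.5 * ((axis - 2851) / 16) ** 2)
        ds = self._mixture_dataset(reference, axis, n=5)
        # one spectrum with no reference contribution at all -> degenerate b
        ds.intensities[2] = 0.3 * water_reference(axis) + 1.0
        model = EMSCModel(reference=reference, water=water_reference(axis), axis=axis)
        processed, log = preprocess_pipeline(ds, emsc_model=model, config=PipelineConfig(emsc_b_floor=1e-3))
        assert len(processed) == 4
        assert len(log.dropped) == 1 and log.dropped[0]["id"] == "s2"

    def test_full_synthetic_dataset_survives(self, four_class_dataset):
        ds, _ = four_class_dataset
        processed, log = preprocess_pipeline(ds)
        assert log.n_in == log.n_out + len(log.dropped)
        assert len(processed) >= 0.95 * len(ds)
        # every surviving spectrum is area normalized
        np.testing.assert_allclose(processed.intensities.sum(axis=1), 1.0, atol=1e-9)
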