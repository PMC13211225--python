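"""HTS spectral operators: scatter correction, turbidity, AUC, BCM."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from accelstab.simulate import generate_absorbance_series, generate_emission_series
from accelstab.spectra import (
    ScatterBaseline,
    Spectrum,
    SpectrumError,
    barycentric_mean,
    correct_scattering,
    fit_scatter_baseline,
    spectrum_auc,
    turbidity_at,
)


def gaussian_band(center, amplitude=1.0, width=10.0, grid=None):
    grid = np.arange(250.0, 500.5, 1.0) if grid is None else grid
    return Spectrum(grid, amplitude * np.exp(-0.5 * ((grid - center) / width) ** 2))


class TestScatterBaseline:
    def test_exponent_recovered_from_rayleigh_like_background(self, rng):
        grid = np.arange(250.0, 500.5, 1.0)
        truth = ScatterBaseline(a=0.01, b=7.5e8, c=-4.0)
        noisy = Spectrum(grid, truth.evaluate(grid) + rng.normal(0, 1e-4, grid.size))
        fit = fit_scatter_baseline(noisy)
        assert fit.c == pytest.approx(-4.0, rel=0.05)

    def test_spec_magnitude_background(self):
        # much weaker scattering term, near-noiseless
        grid = np.arange(250.0, 500.5, 1.0)
        truth = ScatterBaseline(a=0.01, b=1e6, c=-4.0)
        spec = Spectrum(grid, truth.evaluate(grid) + np.random.default_rng(0).normal(0, 1e-8, grid.size))
        fit = fit_scatter_baseline(spec)
        assert fit.c == pytest.approx(-4.0, rel=0.05)

    def test_flat_spectrum_gives_zero_scale(self):
        grid = np.arange(250.0, 500.5, 1.0)
        fit = fit_scatter_baseline(Spectrum(grid, np.full(grid.size, 0.3)))
        assert abs(fit.b * 400.0**fit.c) < 1e-8
        assert fit.a == pytest.approx(0.3, abs=1e-6)

    def test_residual_rms_tracks_noise(self, rng):
        grid = np.arange(250.0, 500.5, 1.0)
        truth = ScatterBaseline(a=0.02, b=7.5e8, c=-4.0)
        noise = 5e-4
        spec = Spectrum(grid, truth.evaluate(grid) + rng.normal(0, noise, grid.size))
        fit = fit_scatter_baseline(spec)
        window = (grid >= 350) & (grid <= 500)
        resid = spec.intensities[window] - fit.evaluate(grid[window])
        assert np.sqrt(np.mean(resid**2)) <= noise * 1.5

    def test_too_few_points_raises(self):
        grid = np.array([360.0, 370.0, 380.0])
        with pytest.raises(SpectrumError):
            fit_scatter_baseline(Spectrum(grid, np.ones(3)))


class TestCorrection:
    def test_pure_baseline_corrects_to_zero(self):
        grid = np.arange(250.0, 500.5, 1.0)
        truth = ScatterBaseline(a=0.01, b=7.5e8, c=-4.0)
        spec = Spectrum(grid, truth.evaluate(grid))
        fit = fit_scatter_baseline(spec)
        corrected = correct_scattering(spec, fit)
        assert np.max(np.abs(corrected.intensities)) < 1e-6

    def test_recovers_analyte_band_under_scatter(self):
        grid = np.arange(250.0, 500.5, 1.0)
        band = gaussian_band(280.0, amplitude=0.5, width=12.0, grid=grid)
        baseline = ScatterBaseline(a=0.01, b=7.5e8, c=-4.0)
        mixed = Spectrum(grid, band.intensities + baseline.evaluate(grid))
        corrected = correct_scattering(mixed, fit_scatter_baseline(mixed))
        assert np.max(np.abs(corrected.intensities - band.intensities)) < 0.02 * 0.5

    def test_idempotent_within_fit_residual(self, rng):
        grid = np.arange(250.0, 500.5, 1.0)
        noise = 2e-4
        spec = Spectrum(
            grid,
            ScatterBaseline(0.01, 7.5e8, -4.0).evaluate(grid) + rng.normal(0, noise, grid.size),
        )
        once = correct_scattering(spec, fit_scatter_baseline(spec))
        twice = correct_scattering(once, fit_scatter_baseline(once))
        window = (grid >= 350) & (grid <= 500)
        assert np.max(np.abs(twice.intensities[window] - once.intensities[window])) < 3 * noise


class TestTurbidity:
    def test_exact_grid_point_and_midpoint(self):
        spec = Spectrum(np.array([349.0, 350.0, 352.0]), np.array([1.0, 2.0, 4.0]))
        assert turbidity_at(spec) == pytest.approx(2.0)
        assert turbidity_at(spec, 351.0) == pytest.approx(3.0)

    def test_monotone_series_with_growing_scatter(self):
        series = generate_absorbance_series(b_schedule=[0.0, 2e8, 6e8, 1.2e9])
        turb = [turbidity_at(s) for s in series]
        assert turb[0] == pytest.approx(0.01, abs=1e-6)  # offset only
        assert np.all(np.diff(turb) > 0)

    def test_out_of_range_raises(self):
        spec = Spectrum(np.array([300.0, 310.0]), np.array([1.0, 1.0]))
        with pytest.raises(SpectrumError):
            turbidity_at(spec, 350.0)


class TestAUC:
    def test_constant_one_over_range(self):
        grid = np.arange(300.0, 450.5, 1.0)
        assert spectrum_auc(Spectrum(grid, np.ones(grid.size))) == pytest.approx(150.0)

    def test_linearity(self):
        s = gaussian_band(330.0, grid=np.arange(300.0, 450.5, 1.0))
        doubled = Spectrum(s.wavelengths, 2 * s.intensities)
        assert spectrum_auc(doubled) == pytest.approx(2 * spectrum_auc(s), rel=1e-12)

    def test_gaussian_band_analytic_area(self):
        amp, sigma = 2.0, 8.0
        grid = np.arange(300.0, 450.25, 0.25)
        s = gaussian_band(375.0, amplitude=amp, width=sigma, grid=grid)
        assert spectrum_auc(s) == pytest.approx(amp * sigma * np.sqrt(2 * np.pi), rel=0.01)

    @given(split=st.floats(310.0, 440.0))
    def test_additive_over_adjacent_subranges(self, split):
        grid = np.arange(300.0, 450.5, 1.0)
        s = gaussian_band(360.0, grid=grid)
        total = spectrum_auc(s, (300.0, 450.0))
        assert spectrum_auc(s, (300.0, split)) + spectrum_auc(s, (split, 450.0)) == pytest.approx(
            total, rel=1e-9
        )


class TestBarycentricMean:
    def test_symmetric_band_centroid_is_center(self):
        # width chosen so both tails vanish inside the integration range
        s = gaussian_band(330.0, width=4.0, grid=np.arange(300.0, 450.5, 1.0))
        assert barycentric_mean(s) == pytest.approx(330.0, abs=1e-6)

    def test_translation_equivariance(self):
        grid = np.arange(300.0, 450.5, 1.0)
        a = barycentric_mean(gaussian_band(330.0, width=4.0, grid=grid))
        b = barycentric_mean(gaussian_band(340.0, width=4.0, grid=grid))
        assert b - a == pytest.approx(10.0, abs=1e-6)

    def test_intensity_scaling_invariance(self):
        s = gaussian_band(345.0, grid=np.arange(300.0, 450.5, 1.0))
        scaled = Spectrum(s.wavelengths, 7.3 * s.intensities)
        assert barycentric_mean(scaled) == pytest.approx(barycentric_mean(s), rel=1e-12)

    def test_red_shifting_series_strictly_increases(self):
        series = generate_emission_series(
            centers=np.linspace(330, 345, 6), amplitudes=np.linspace(1.0, 0.6, 6)
        )
        bcm = [barycentric_mean(s) for s in series]
        assert np.all(np.diff(bcm) > 0)

    def test_bounded_by_range(self):
        s = gaussian_band(310.0, grid=np.arange(300.0, 450.5, 1.0))
        assert 300.0 <= barycentric_mean(s) <= 450.0

    def test_all_zero_raises(self):
        grid = np.arange(300.0, 450.5, 1.0)
        with pytest.raises(SpectrumError):
            barycentric_mean(Spectrum(grid, np.zeros(grid.size)))
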