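"""TRES reconstruction and log-normal band fitting."""

import numpy as np
import pytest

from tdfspec import units
from tdfspec.decayfit import MultiExponentialModel, fit_decay
from tdfspec.errors import DegenerateInputError
from tdfspec.synthdata import build_surface, simulate_decays, steady_state_from_surface
from tdfspec.tres import (
    SteadyStateSpectrum,
    band_trajectory,
    fit_band,
    lognormal_profile,
    reconstruct,
)

WAVELENGTHS = np.arange(400.0, 551.0, 10.0)


def _gaussian_spectrum(peak_nm=460.0, fwhm_nm=60.0):
    grid = np.arange(380.0, 601.0, 1.0)
    sigma = fwhm_nm / 2.355
    return SteadyStateSpectrum(
        axis="wavelength",
        grid=grid,
        intensities=np.exp(-0.5 * ((grid - peak_nm) / sigma) ** 2),
    )


class TestFitBand:
    nu = np.linspace(18000.0, 25000.0, 40)

    def test_exact_lognormal_recovered(self):
        y = lognormal_profile(self.nu, 10.0, 21500.0, 3000.0, -0.3)
        band = fit_band(self.nu, y)
        assert band.amplitude == pytest.approx(10.0, rel=1e-6)
        assert band.peak == pytest.approx(21500.0, rel=1e-6)
        assert band.fwhm == pytest.approx(3000.0, rel=1e-6)
        assert band.asymmetry == pytest.approx(-0.3, abs=1e-6)

    def test_symmetric_gaussian_limit(self):
        sigma = 2500.0 / 2.3548200450309493
        y = 5.0 * np.exp(-0.5 * ((self.nu - 21000.0) / sigma) ** 2)
        band = fit_band(self.nu, y)
        assert abs(band.asymmetry) <= 0.02
        assert band.fwhm == pytest.approx(2500.0, rel=0.005)

    def test_fwhm_matches_numeric_half_height(self, fwhm_oracle):
        dense = np.linspace(15000.0, 27000.0, 5000)
        for b in (-0.4, 0.0, 0.25):
            band = fit_band(
                self.nu, lognormal_profile(self.nu, 3.0, 21000.0, 2800.0, b)
            )
            numeric = fwhm_oracle(dense, band.profile(dense))
            assert band.fwhm == pytest.approx(numeric, rel=0.01)

    def test_monotone_slice_rejected(self):
        y = np.linspace(0.1, 5.0, self.nu.size)
        with pytest.raises(DegenerateInputError):
            fit_band(self.nu, y)

    def test_unbracketed_peak_rejected(self):
        # maximum interior by a noise wiggle but edge intensity ~ max
        y = np.linspace(0.1, 5.0, self.nu.size)
        y[-2] = 5.05
        with pytest.raises(DegenerateInputError):
            fit_band(self.nu, y)

    def test_too_few_points_rejected(self):
        from tdfspec.errors import InvalidParameterError

        with pytest.raises(InvalidParameterError):
            fit_band(np.array([1.0, 2.0, 3.0, 4.0]), np.array([1.0, 2.0, 1.5, 1.0]))


class TestReconstruct:
    def test_shared_lifetime_gives_scaled_copies_of_spectrum(self):
        spectrum = _gaussian_spectrum()
        fits = [
            (w, MultiExponentialModel(amplitudes=[1000.0], lifetimes=[3.0]))
            for w in WAVELENGTHS
        ]
        time_grid = np.geomspace(0.05, 10.0, 20)
        surface = reconstruct(fits, spectrum, time_grid)
        ratios = surface.intensity / surface.intensity[0]
        # every time slice is the first slice scaled by a constant
        assert np.allclose(ratios, ratios[:, :1], rtol=1e-9)
        peaks = surface.wavenumber_grid[np.argmax(surface.intensity, axis=1)]
        assert np.all(peaks == peaks[0])

    def test_normalization_invariant_on_random_fits(self):
        """The time integral of each reconstructed decay equals the
        steady-state intensity at that wavenumber."""
        rng = np.random.default_rng(42)
        spectrum = _gaussian_spectrum()
        for _ in range(20):
            wavelengths = rng.choice(WAVELENGTHS, size=6, replace=False)
            fits = []
            for w in wavelengths:
                n = rng.integers(1, 4)
                fits.append(
                    (
                        float(w),
                        MultiExponentialModel(
                            amplitudes=rng.uniform(100.0, 5000.0, n),
                            lifetimes=rng.uniform(0.2, 6.0, n),
                        ),
                    )
                )
            time_grid = np.geomspace(0.05, 10.0, 15)
            surface = reconstruct(fits, spectrum, time_grid)
            for (w, model) in fits:
                nu = float(units.nm_to_wavenumber(w))
                k = int(np.argmin(np.abs(surface.wavenumber_grid - nu)))
                target = (
                    float(spectrum.intensity_at(w)[0])
                    * w**2
                    / units.WAVENUMBER_PER_NM
                )
                analytic = (
                    model.integral()
                    * surface.intensity[0, k]
                    / float(model.decay(np.array([time_grid[0]]))[0])
                )
                assert analytic == pytest.approx(target, rel=1e-6)

    def test_zero_integral_fit_rejected(self):
        spectrum = _gaussian_spectrum()
        fits = [
            (450.0, MultiExponentialModel(amplitudes=[0.0], lifetimes=[1.0])),
            (460.0, MultiExponentialModel(amplitudes=[10.0], lifetimes=[1.0])),
        ]
        with pytest.raises(DegenerateInputError, match="450"):
            reconstruct(fits, spectrum, np.geomspace(0.1, 5.0, 10))

    def test_end_to_end_noiseless_slice_recovery(self, fast_irf):
        """Fit near-noiseless decays, reconstruct, compare a slice with the
        generator surface (3% RMS)."""
        from tdfspec.synthdata import RelaxationTruth

        truth = RelaxationTruth(
            nu_infinity=21000.0,
            delta_nu=2000.0,
            relaxation_components=((1.0, 1.0),),
            fluorescence_lifetimes=((0.4, 1.8), (0.6, 3.2)),
            width_baseline=3300.0,
        )
        nu_grid = np.arange(16000.0, 27500.0, 20.0)
        surface = build_surface(truth, nu_grid, fast_irf.time_grid)
        wavelengths = np.arange(400.0, 551.0, 15.0)
        decays = simulate_decays(
            surface, fast_irf, wavelengths, peak_counts=200000, seed=0
        )
        spectrum = steady_state_from_surface(surface, as_wavelength=True)
        fits = [(d.wavelength, fit_decay(d, fast_irf).model) for d in decays]
        t_slice = 0.1
        rec = reconstruct(fits, spectrum, np.array([t_slice, 1.0, 3.0]))
        measured_nu = rec.wavenumber_grid
        # generator slice at the reconstruction time via interpolation in t
        expected = np.array(
            [
                np.interp(t_slice, surface.time_grid, surface.slice_at_wavenumber(float(nu)))
                for nu in measured_nu
            ]
        )
        rms = np.sqrt(np.mean((rec.intensity[0] - expected) ** 2)) / expected.max()
        assert rms < 0.03

    def test_band_maximum_strictly_decreasing_for_relaxing_truth(self, fast_irf):
        from tdfspec.synthdata import RelaxationTruth

        truth = RelaxationTruth(
            nu_infinity=21000.0,
            delta_nu=2500.0,
            relaxation_components=((1.0, 1.0),),
            fluorescence_lifetimes=((0.4, 1.8), (0.6, 3.2)),
            width_baseline=3300.0,
        )
        nu_grid = np.arange(16000.0, 27500.0, 20.0)
        surface = build_surface(truth, nu_grid, fast_irf.time_grid)
        decays = simulate_decays(
            surface, fast_irf, np.arange(400.0, 551.0, 15.0), peak_counts=100000, seed=2
        )
        spectrum = steady_state_from_surface(surface, as_wavelength=True)
        fits = [(d.wavelength, fit_decay(d, fast_irf).model) for d in decays]
        rec = reconstruct(fits, spectrum, np.geomspace(0.15, 8.0, 30))
        trajectory = band_trajectory(rec, on_error="skip").valid()
        # strictly decreasing while relaxation is in progress (t < 4 tau);
        # once relaxed the trajectory is flat to within a few cm^-1
        relaxing = trajectory.times < 4.0
        assert np.all(np.diff(trajectory.nu_max[relaxing]) < 0)
        assert trajectory.nu_max[-1] == pytest.approx(21000.0, abs=30.0)


class TestBandTrajectory:
    def _surface_from_truth(self, truth, t_start=0.05, t_end=20.0, n=80):
        nu_grid = np.arange(
            truth.nu_infinity - 6000.0, truth.nu_peak_zero + 6000.0, 25.0
        )
        times = np.geomspace(t_start, t_end, n)
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            surface = build_surface(truth, nu_grid, times)
        from tdfspec.tres import TresSurface

        return TresSurface(
            wavenumber_grid=surface.wavenumber_grid,
            time_grid=surface.time_grid,
            intensity=surface.intensity,
        )

    def test_constant_surface_gives_flat_trajectories(self):
        from tdfspec.synthdata import RelaxationTruth

        truth = RelaxationTruth(
            nu_infinity=21000.0,
            delta_nu=0.0,
            relaxation_components=((1.0, 1.0),),
            fluorescence_lifetimes=((1.0, 100.0),),
            width_baseline=3000.0,
        )
        surface = self._surface_from_truth(truth)
        trajectory = band_trajectory(surface).valid()
        assert np.ptp(trajectory.nu_max) < 1.0
        assert np.ptp(trajectory.fwhm) < 1.0

    def test_single_bump_yields_one_interior_width_maximum(self, laurdan_like_truth):
        surface = self._surface_from_truth(laurdan_like_truth)
        trajectory = band_trajectory(surface).valid()
        w = trajectory.fwhm
        interior = (w[1:-1] > w[:-2]) & (w[1:-1] > w[2:])
        assert interior.sum() == 1

    def test_two_slow_bumps_yield_two_maxima(self, di4_like_truth):
        from tdfspec.tdfs import fwhm_maxima

        surface = self._surface_from_truth(di4_like_truth)
        trajectory = band_trajectory(surface).valid()
        maxima = fwhm_maxima(trajectory.times, trajectory.fwhm)
        assert len(maxima) >= 2

    def test_warm_start_matches_cold_start_on_noiseless_surface(self, laurdan_like_truth):
        surface = self._surface_from_truth(laurdan_like_truth)
        warm = band_trajectory(surface).valid()
        cold_nu = []
        for i in range(surface.time_grid.size):
            band = fit_band(surface.wavenumber_grid, surface.intensity[i])
            cold_nu.append(band.peak)
        assert np.allclose(warm.nu_max, cold_nu, rtol=1e-3)


class TestSpectrumConversions:
    def test_round_trip_preserves_signal(self):
        spectrum = _gaussian_spectrum()
        back = spectrum.to_wavenumber().to_wavelength()
        total_a = np.trapezoid(spectrum.intensities, spectrum.grid)
        total_b = np.trapezoid(back.intensities, back.grid)
        assert total_b == pytest.approx(total_a, rel=1e-6)
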