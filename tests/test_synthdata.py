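"""Generator tests: IRF discretization, the relaxing-band surface, detector
simulation, steady-state integration, vesicle stacks and solvent spectra."""

import numpy as np
import pytest
from scipy.signal import fftconvolve

from tdfspec import make_irf, units
from tdfspec.errors import CoverageWarning, InvalidParameterError
from tdfspec.synthdata import (
    DEFAULT_SOLVENT_PEAKS_NM,
    RelaxationTruth,
    RingGeometry,
    WidthBump,
    build_surface,
    gaussian_band_spectrum,
    simulate_decays,
    simulate_solvent_spectrum,
    simulate_vesicle_stack,
    steady_state_from_surface,
    time_zero_references,
)
from tdfspec.tdfs import estimate_time_zero


class TestMakeIrf:
    @pytest.mark.parametrize("fwhm_ps", [78.0, 84.0])
    def test_unit_sum_and_numeric_fwhm(self, fwhm_ps, fwhm_oracle):
        irf = make_irf(fwhm_ps, 7.0, 50.0, 1.0)
        assert irf.amplitudes.sum() == pytest.approx(1.0, abs=1e-12)
        measured_ps = 1000.0 * fwhm_oracle(irf.time_grid, irf.amplitudes)
        assert 71.0 <= measured_ps <= 85.0
        assert abs(measured_ps - fwhm_ps) <= 7.0  # within one channel width

    def test_near_delta_limit(self):
        irf = make_irf(7.0, 7.0, 10.0, 0.5)
        top3 = np.sort(irf.amplitudes)[-3:].sum()
        assert top3 > 0.9
        assert irf.amplitudes.sum() == pytest.approx(1.0, abs=1e-12)

    def test_second_moment_matches_gaussian_sigma(self):
        irf = make_irf(84.0, 7.0, 50.0, 1.0)
        mean = np.sum(irf.time_grid * irf.amplitudes)
        sigma = np.sqrt(np.sum((irf.time_grid - mean) ** 2 * irf.amplitudes))
        expected = 0.084 / (2.0 * np.sqrt(2.0 * np.log(2.0)))
        assert sigma == pytest.approx(expected, rel=0.05)

    @pytest.mark.parametrize("bad", [{"fwhm_ps": -1.0}, {"channel_width_ps": 0.0}])
    def test_non_positive_widths_rejected(self, bad):
        kwargs = {"fwhm_ps": 78.0, "channel_width_ps": 7.0, "window_ns": 50.0}
        kwargs.update(bad)
        with pytest.raises(InvalidParameterError):
            make_irf(**kwargs)


class TestBuildSurface:
    nu_grid = np.arange(16000.0, 27000.0, 10.0)

    def test_no_relaxation_keeps_band_position_constant(self):
        truth = RelaxationTruth(
            nu_infinity=21000.0,
            delta_nu=0.0,
            relaxation_components=((1.0, 1.0),),
            fluorescence_lifetimes=((1.0, 4.0),),
            width_baseline=3000.0,
        )
        surface = build_surface(truth, self.nu_grid, np.linspace(0.0, 10.0, 50))
        peaks = self.nu_grid[np.argmax(surface.intensity, axis=1)]
        assert np.all(peaks == peaks[0])
        assert abs(peaks[0] - 21000.0) <= 10.0

    def test_single_component_exponential_identity(self):
        truth = RelaxationTruth(
            nu_infinity=21000.0,
            delta_nu=2000.0,
            relaxation_components=((1.0, 1.0),),
            fluorescence_lifetimes=((1.0, 4.0),),
            width_baseline=3000.0,
        )
        expected = 21000.0 + 2000.0 / np.e
        assert truth.nu_peak(1.0) == pytest.approx(expected, rel=1e-9)
        # and the generated slice peaks there
        surface = build_surface(truth, self.nu_grid, np.array([0.0, 1.0, 10.0]))
        peak = self.nu_grid[np.argmax(surface.intensity[1])]
        assert abs(peak - expected) <= 10.0

    def test_width_bumps_appear_as_fwhm_maxima_of_slices(self, fwhm_oracle):
        truth = RelaxationTruth(
            nu_infinity=21000.0,
            delta_nu=0.0,
            relaxation_components=((1.0, 1.0),),
            fluorescence_lifetimes=((1.0, 4.0),),
            width_baseline=3000.0,
            width_bumps=(WidthBump(1.1, 600.0, 0.25), WidthBump(5.2, 600.0, 0.25)),
        )
        times = np.geomspace(0.05, 20.0, 120)
        surface = build_surface(truth, self.nu_grid, times)
        widths = np.array(
            [fwhm_oracle(self.nu_grid, surface.intensity[i]) for i in range(times.size)]
        )
        interior = (widths[1:-1] > widths[:-2]) & (widths[1:-1] > widths[2:])
        peak_times = times[1:-1][interior]
        assert peak_times.size == 2
        spacing = np.diff(np.log(times)).max()
        assert abs(np.log(peak_times[0] / 1.1)) <= 2 * spacing
        assert abs(np.log(peak_times[1] / 5.2)) <= 2 * spacing

    def test_short_window_warns(self, laurdan_like_truth):
        with pytest.warns(CoverageWarning):
            build_surface(laurdan_like_truth, self.nu_grid, np.linspace(0.0, 1.0, 10))


class TestSimulateDecays:
    def _surface(self, truth, irf):
        nu_grid = np.arange(16000.0, 27000.0, 20.0)
        return build_surface(truth, nu_grid, irf.time_grid)

    def test_peak_counts_respected(self, fast_irf, laurdan_like_truth):
        surface = self._surface(laurdan_like_truth, fast_irf)
        curves = simulate_decays(
            surface, fast_irf, [420.0, 460.0, 500.0], peak_counts=5000, seed=3
        )
        for curve in curves:
            assert abs(curve.counts.max() - 5000) <= 4 * np.sqrt(5000)

    def test_zero_surface_gives_zero_counts(self, fast_irf):
        nu_grid = np.arange(16000.0, 27000.0, 20.0)
        truth = RelaxationTruth(
            nu_infinity=21000.0,
            delta_nu=0.0,
            relaxation_components=((1.0, 1.0),),
            fluorescence_lifetimes=((1.0, 4.0),),
            width_baseline=3000.0,
        )
        surface = build_surface(truth, nu_grid, fast_irf.time_grid)
        zero = type(surface)(
            wavenumber_grid=surface.wavenumber_grid,
            time_grid=surface.time_grid,
            intensity=np.zeros_like(surface.intensity),
        )
        curves = simulate_decays(zero, fast_irf, [460.0], peak_counts=5000, seed=1)
        assert np.all(curves[0].counts == 0)

    def test_seed_determinism(self, fast_irf, laurdan_like_truth):
        surface = self._surface(laurdan_like_truth, fast_irf)
        a = simulate_decays(surface, fast_irf, [440.0, 480.0], peak_counts=1000, seed=9)
        b = simulate_decays(surface, fast_irf, [440.0, 480.0], peak_counts=1000, seed=9)
        c = simulate_decays(surface, fast_irf, [440.0, 480.0], peak_counts=1000, seed=10)
        for x, y in zip(a, b):
            assert np.array_equal(x.counts, y.counts)
        assert not np.array_equal(a[0].counts, c[0].counts)

    def test_wavelength_outside_surface_named_in_error(self, fast_irf, laurdan_like_truth):
        surface = self._surface(laurdan_like_truth, fast_irf)
        with pytest.raises(InvalidParameterError, match="999"):
            simulate_decays(surface, fast_irf, [999.0], peak_counts=5000, seed=1)

    def test_photon_bookkeeping(self, fast_irf, laurdan_like_truth):
        """Total counts match the scaled IRF-convolved slice integral."""
        surface = self._surface(laurdan_like_truth, fast_irf)
        wavelength = 460.0
        curves = simulate_decays(
            surface, fast_irf, [wavelength], peak_counts=5000, seed=4
        )
        trace = surface.slice_at_wavenumber(float(units.nm_to_wavenumber(wavelength)))
        expected = np.clip(
            fftconvolve(fast_irf.amplitudes, trace)[: fast_irf.time_grid.size], 0, None
        )
        expected = expected * (5000.0 / expected.max())
        total = expected.sum()
        assert abs(curves[0].counts.sum() - total) <= 5 * np.sqrt(total)


class TestSteadyState:
    def test_constant_surface_integrates_to_duration_times_slice(self):
        nu_grid = np.arange(18000.0, 24000.0, 20.0)
        slice_shape = np.exp(-0.5 * ((nu_grid - 21000.0) / 1000.0) ** 2)
        times = np.linspace(0.0, 7.0, 71)
        from tdfspec.synthdata import EmissionSurface

        surface = EmissionSurface(
            wavenumber_grid=nu_grid,
            time_grid=times,
            intensity=np.tile(slice_shape, (times.size, 1)),
        )
        spectrum = steady_state_from_surface(surface)
        assert np.allclose(spectrum.intensities, 7.0 * slice_shape, rtol=1e-9)

    def test_jacobian_preserves_total_signal(self, fast_irf, laurdan_like_truth):
        nu_grid = np.arange(16000.0, 27000.0, 20.0)
        surface = build_surface(laurdan_like_truth, nu_grid, fast_irf.time_grid)
        in_nu = steady_state_from_surface(surface, as_wavelength=False)
        in_wl = steady_state_from_surface(surface, as_wavelength=True)
        total_nu = np.trapezoid(in_nu.intensities, in_nu.grid)
        total_wl = np.trapezoid(in_wl.intensities, in_wl.grid)
        assert total_wl == pytest.approx(total_nu, rel=1e-6)

    def test_single_lifetime_amplitude_is_tau_times_slice(self):
        nu_grid = np.arange(18000.0, 24000.0, 20.0)
        truth = RelaxationTruth(
            nu_infinity=21000.0,
            delta_nu=0.0,
            relaxation_components=((1.0, 0.1),),
            fluorescence_lifetimes=((1.0, 4.0),),
            width_baseline=3000.0,
        )
        times = np.linspace(0.0, 80.0, 4001)  # 20 lifetimes, fine sampling
        surface = build_surface(truth, nu_grid, times)
        spectrum = steady_state_from_surface(surface)
        assert np.allclose(spectrum.intensities, 4.0 * surface.intensity[0], rtol=1e-3)


class TestTimeZeroReferences:
    def test_reference_arithmetic_recovers_truth(self, laurdan_like_truth):
        refs = time_zero_references(laurdan_like_truth)
        estimate = estimate_time_zero(*refs)
        assert estimate == pytest.approx(laurdan_like_truth.nu_peak_zero, abs=1.0)


class TestVesicleStack:
    channels = np.arange(420.0, 541.0, 10.0)
    ring = RingGeometry(center_row=32.0, center_col=32.0, radius=20.0, thickness=3.0)

    def _phase(self, peak):
        return gaussian_band_spectrum(peak, 50.0, axis="wavelength")

    def test_phase_spectra_recover_input_peaks(self):
        stack, mask = simulate_vesicle_stack(
            (64, 64),
            self.ring,
            self._phase(440.0),
            self._phase(490.0),
            self.channels,
            10.0,
            counts_scale=5000.0,
            seed=5,
        )
        mean_a = stack.counts[mask == 1].mean(axis=0)
        mean_b = stack.counts[mask == 2].mean(axis=0)
        assert self.channels[np.argmax(mean_a)] == 440.0
        assert self.channels[np.argmax(mean_b)] == 490.0

    def test_counts_scale_convergence_to_noiseless_bands(self):
        results = {}
        for scale in (1e3, 1e6):
            stack, mask = simulate_vesicle_stack(
                (48, 48),
                RingGeometry(24.0, 24.0, 15.0, 3.0),
                self._phase(440.0),
                self._phase(490.0),
                self.channels,
                10.0,
                counts_scale=scale,
                seed=6,
            )
            mean_a = stack.counts[mask == 1].mean(axis=0)
            results[scale] = mean_a / mean_a.max()
        ideal, _ = simulate_vesicle_stack(
            (48, 48),
            RingGeometry(24.0, 24.0, 15.0, 3.0),
            self._phase(440.0),
            self._phase(490.0),
            self.channels,
            10.0,
            counts_scale=1e8,
            seed=7,
        )
        reference = ideal.counts[_ == 1].mean(axis=0)
        reference = reference / reference.max()
        err_low = np.abs(results[1e3] - reference).max()
        err_high = np.abs(results[1e6] - reference).max()
        assert err_high < err_low

    def test_determinism_and_mask_labels(self):
        a, mask_a = simulate_vesicle_stack(
            (48, 48), RingGeometry(24, 24, 15), self._phase(440), self._phase(490),
            self.channels, 10.0, counts_scale=500, seed=11,
        )
        b, mask_b = simulate_vesicle_stack(
            (48, 48), RingGeometry(24, 24, 15), self._phase(440), self._phase(490),
            self.channels, 10.0, counts_scale=500, seed=11,
        )
        assert np.array_equal(a.counts, b.counts)
        assert np.array_equal(mask_a, mask_b)
        assert set(np.unique(mask_a)) == {0, 1, 2}

    def test_uncovered_channel_rejected(self):
        with pytest.raises(InvalidParameterError):
            simulate_vesicle_stack(
                (32, 32), RingGeometry(16, 16, 10),
                self._phase(440.0), self._phase(490.0),
                np.array([300.0, 420.0]), 10.0, counts_scale=500, seed=1,
            )


class TestSolventSpectra:
    def _peak(self, dye, solvent, table=None):
        spectrum = simulate_solvent_spectrum(dye, solvent, peak_table=table)
        return spectrum.grid[np.argmax(spectrum.intensities)]

    def test_laurdan_ordering(self):
        peaks = {s: self._peak("laurdan", s) for s in ("ethanol", "dmso", "chloroform")}
        assert peaks["ethanol"] > peaks["dmso"] > peaks["chloroform"]

    def test_di4_ordering(self):
        peaks = {s: self._peak("di4", s) for s in ("ethanol", "dmso", "chloroform")}
        assert peaks["dmso"] > peaks["ethanol"] > peaks["chloroform"]

    def test_custom_table_with_ties(self):
        table = {"laurdan": {"ethanol": 480.0, "dmso": 480.0, "chloroform": 440.0}}
        assert self._peak("laurdan", "ethanol", table) == self._peak(
            "laurdan", "dmso", table
        )

    def test_unknown_solvent_rejected(self):
        with pytest.raises(InvalidParameterError):
            simulate_solvent_spectrum("laurdan", "toluene")

    def test_default_table_solvents(self):
        assert set(DEFAULT_SOLVENT_PEAKS_NM) == {"laurdan", "di4"}


class TestTruthValidation:
    def test_weights_must_sum_to_one(self):
        with pytest.raises(InvalidParameterError):
            RelaxationTruth(
                nu_infinity=21000.0,
                delta_nu=1000.0,
                relaxation_components=((0.5, 1.0), (0.2, 2.0)),
                fluorescence_lifetimes=((1.0, 4.0),),
                width_baseline=3000.0,
            )

    def test_negative_shift_rejected(self):
        with pytest.raises(InvalidParameterError):
            RelaxationTruth(
                nu_infinity=21000.0,
                delta_nu=-10.0,
                relaxation_components=((1.0, 1.0),),
                fluorescence_lifetimes=((1.0, 4.0),),
                width_baseline=3000.0,
            )

    def test_single_width_bump_gives_single_interior_maximum(self, laurdan_like_truth):
        times = np.geomspace(0.02, 20.0, 200)
        widths = laurdan_like_truth.width(times)
        interior = (widths[1:-1] > widths[:-2]) & (widths[1:-1] > widths[2:])
        assert interior.sum() == 1
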