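"""Synthetic-data generator with known ground truth.

Generative model for a continuously relaxing emission band: the band maximum
shifts multi-exponentially from nu(0) = nu_inf + delta_nu (+ an optional
constant electrochromic offset) toward nu_inf,

    nu_p(t) = nu_inf + offset + delta_nu * sum_j w_j exp(-t / tau_rel_j),

the total amplitude decays multi-exponentially with the fluorescence
lifetimes, and each time slice is a skewed log-normal band whose width
Gamma(t) follows a baseline plus Gaussian-in-log-time "bumps" — the transient
broadening that accompanies heterogeneous dipolar relaxation (one bump for
laurdan-like probes, several for di-4-like probes).  Projections of this
surface onto single emission wavelengths are well approximated by
three-exponential decays, which is what the fitting stage assumes.

Everything downstream of the generator is exercised against the stored
ground truth: detector simulation convolves slices with a Gaussian IRF and
draws Poisson counts scaled to a target peak count (the stop criterion of a
TCSPC acquisition), steady-state spectra are exact time integrals of the
surface, and two-phase vesicle image stacks come with their phase mask.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.signal import fftconvolve

from . import units
from .decayfit import DecayCurve, InstrumentResponse
from .errors import CoverageWarning, InvalidParameterError
from .gp import SpectralImageStack
from .tres import SteadyStateSpectrum, lognormal_profile

__all__ = [
    "WidthBump",
    "RelaxationTruth",
    "EmissionSurface",
    "RingGeometry",
    "make_irf",
    "build_surface",
    "simulate_decays",
    "steady_state_from_surface",
    "time_zero_references",
    "simulate_vesicle_stack",
    "simulate_solvent_spectrum",
    "DEFAULT_SOLVENT_PEAKS_NM",
    "gaussian_band_spectrum",
]


@dataclass(frozen=True)
class WidthBump:
    """One transient broadening event: Gaussian in ln(t).

    ``peak_time`` is where the bump culminates (ns), ``height`` its amplitude
    (cm^-1) and ``log_width`` the dimensionless standard deviation in ln(t).
    """

    peak_time: float  # ns
    height: float  # cm^-1
    log_width: float = 0.3

    def __post_init__(self):
        if self.peak_time <= 0 or self.height < 0 or self.log_width <= 0:
            raise InvalidParameterError("width bump parameters must be positive")

    def __call__(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        out = np.zeros_like(t)
        pos = t > 0
        z = np.log(t[pos] / self.peak_time) / self.log_width
        out[pos] = self.height * np.exp(-0.5 * z**2)
        return out


@dataclass(frozen=True)
class RelaxationTruth:
    """Ground-truth parameters of a relaxing emission band."""

    nu_infinity: float  # cm^-1
    delta_nu: float  # cm^-1
    relaxation_components: tuple  # of (weight, tau_rel ns)
    fluorescence_lifetimes: tuple  # of (amplitude fraction, tau_fl ns)
    width_baseline: float  # cm^-1
    width_bumps: tuple = ()  # of WidthBump
    asymmetry: float = -0.25
    electrochromic_offset: float = 0.0  # cm^-1
    seed: int = 0

    def __post_init__(self):
        object.__setattr__(
            self, "relaxation_components", tuple(tuple(c) for c in self.relaxation_components)
        )
        object.__setattr__(
            self, "fluorescence_lifetimes", tuple(tuple(c) for c in self.fluorescence_lifetimes)
        )
        object.__setattr__(self, "width_bumps", tuple(self.width_bumps))
        weights = np.array([w for w, _ in self.relaxation_components], dtype=float)
        taus = np.array([tau for _, tau in self.relaxation_components], dtype=float)
        if weights.size == 0 or abs(weights.sum() - 1.0) > 1e-9:
            raise InvalidParameterError("relaxation weights must sum to 1")
        if np.any(taus <= 0):
            raise InvalidParameterError("relaxation times must be positive")
        amps = np.array([a for a, _ in self.fluorescence_lifetimes], dtype=float)
        fl_taus = np.array([tau for _, tau in self.fluorescence_lifetimes], dtype=float)
        if amps.size == 0 or np.any(amps < 0) or np.any(fl_taus <= 0):
            raise InvalidParameterError("fluorescence lifetimes must be positive")
        if self.delta_nu < 0:
            raise InvalidParameterError("delta_nu must be >= 0")
        if self.nu_infinity <= 0:
            raise InvalidParameterError("nu_infinity must be positive")
        if self.width_baseline <= 0:
            raise InvalidParameterError("width baseline must be positive")
        nu0 = self.nu_peak_zero
        if not np.isfinite(nu0) or nu0 < self.nu_infinity:
            raise InvalidParameterError("implied nu_p(0) must be finite, >= nu_infinity")

    @property
    def nu_peak_zero(self) -> float:
        """Implied band position at t = 0 (cm^-1)."""
        return self.nu_infinity + self.delta_nu + self.electrochromic_offset

    @property
    def max_relaxation_time(self) -> float:
        return max(tau for _, tau in self.relaxation_components)

    def nu_peak(self, t) -> np.ndarray:
        """Band maximum nu_p(t) (cm^-1)."""
        t = np.asarray(t, dtype=float)
        decay = sum(
            w * np.exp(-np.maximum(t, 0.0) / tau)
            for w, tau in self.relaxation_components
        )
        return self.nu_infinity + self.electrochromic_offset + self.delta_nu * decay

    def amplitude(self, t) -> np.ndarray:
        """Total band amplitude A(t) (arbitrary scale)."""
        t = np.asarray(t, dtype=float)
        with np.errstate(under="ignore"):
            a = sum(
                alpha * np.exp(-np.maximum(t, 0.0) / tau)
                for alpha, tau in self.fluorescence_lifetimes
            )
        return np.where(t < 0, 0.0, a)

    def width(self, t) -> np.ndarray:
        """Band FWHM Gamma(t) (cm^-1)."""
        t = np.asarray(t, dtype=float)
        total = np.full_like(t, self.width_baseline, dtype=float)
        for bump in self.width_bumps:
            total = total + bump(t)
        return total


@dataclass(frozen=True)
class EmissionSurface:
    """Noise-free I(nu, t) on a (time, wavenumber) grid."""

    wavenumber_grid: np.ndarray  # cm^-1, strictly monotone
    time_grid: np.ndarray  # ns, strictly increasing, >= 0
    intensity: np.ndarray  # (time, wavenumber), >= 0
    truth: RelaxationTruth | None = None

    def __post_init__(self):
        nu = np.asarray(self.wavenumber_grid, dtype=float)
        t = np.asarray(self.time_grid, dtype=float)
        I = np.asarray(self.intensity, dtype=float)
        object.__setattr__(self, "wavenumber_grid", nu)
        object.__setattr__(self, "time_grid", t)
        object.__setattr__(self, "intensity", I)
        steps = np.diff(nu)
        if not (np.all(steps > 0) or np.all(steps < 0)):
            raise InvalidParameterError("wavenumber grid must be strictly monotone")
        if np.any(np.diff(t) <= 0) or t[0] < 0:
            raise InvalidParameterError("time grid must be strictly increasing, >= 0")
        if I.shape != (t.size, nu.size):
            raise InvalidParameterError("intensity shape must be (time, wavenumber)")
        if not np.all(np.isfinite(I)) or np.any(I < 0):
            raise InvalidParameterError("intensity must be finite and >= 0")

    def slice_at_wavenumber(self, nu: float) -> np.ndarray:
        """Time course at one wavenumber, linearly interpolated along nu."""
        grid = self.wavenumber_grid
        intensity = self.intensity
        if grid[0] > grid[-1]:
            grid, intensity = grid[::-1], intensity[:, ::-1]
        if not (grid[0] <= nu <= grid[-1]):
            raise InvalidParameterError(
                f"wavenumber {nu:.1f} cm^-1 outside surface range "
                f"[{grid[0]:.1f}, {grid[-1]:.1f}]"
            )
        return np.array(
            [np.interp(nu, grid, intensity[i]) for i in range(self.time_grid.size)]
        )


def make_irf(
    fwhm_ps: float,
    channel_width_ps: float,
    window_ns: float,
    t0_ns: float = 1.0,
) -> InstrumentResponse:
    """Discretized Gaussian IRF, normalized to unit sum.

    ``fwhm_ps`` and ``channel_width_ps`` are in picoseconds; the window and
    pulse position ``t0_ns`` in nanoseconds.  The window must cover t0 plus
    at least five FWHM.
    """
    if fwhm_ps <= 0 or channel_width_ps <= 0:
        raise InvalidParameterError("IRF FWHM and channel width must be positive")
    fwhm = fwhm_ps / 1000.0
    dt = channel_width_ps / 1000.0
    if window_ns < t0_ns + 5.0 * fwhm:
        raise InvalidParameterError("window must cover t0 plus >= 5 x FWHM")
    time_grid = np.arange(0.0, window_ns, dt)
    sigma = fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    profile = np.exp(-0.5 * ((time_grid - t0_ns) / sigma) ** 2)
    amplitudes = profile / profile.sum()
    return InstrumentResponse(time_grid=time_grid, amplitudes=amplitudes, fwhm=fwhm)


def build_surface(
    truth: RelaxationTruth,
    wavenumber_grid: np.ndarray,
    time_grid: np.ndarray,
) -> EmissionSurface:
    """Evaluate the generative model on a (wavenumber, time) grid.

    Warns when the time grid does not reach 3x the slowest relaxation time,
    in which case nu(inf) is ill-constrained downstream.
    """
    wavenumber_grid = np.asarray(wavenumber_grid, dtype=float)
    time_grid = np.asarray(time_grid, dtype=float)
    if time_grid[-1] < 3.0 * truth.max_relaxation_time:
        warnings.warn(
            "time grid covers less than 3x the slowest relaxation component; "
            "the asymptote nu(inf) will be ill-constrained",
            CoverageWarning,
            stacklevel=2,
        )
    peaks = truth.nu_peak(time_grid)
    amps = truth.amplitude(time_grid)
    widths = truth.width(time_grid)
    intensity = np.stack(
        [
            lognormal_profile(wavenumber_grid, a, p, w, truth.asymmetry)
            for a, p, w in zip(amps, peaks, widths)
        ]
    )
    return EmissionSurface(
        wavenumber_grid=wavenumber_grid,
        time_grid=time_grid,
        intensity=intensity,
        truth=truth,
    )


def simulate_decays(
    surface: EmissionSurface,
    irf: InstrumentResponse,
    wavelengths,
    peak_counts: int = 5000,
    seed=0,
) -> list[DecayCurve]:
    """Simulate TCSPC histograms at the given emission wavelengths (nm).

    Each wavelength's time course is extracted from the surface, convolved
    with the IRF on the detector grid, scaled so the maximum expected count
    equals ``peak_counts`` (the acquisition stop criterion) and Poisson
    noise is drawn.  Each wavelength uses an independent child stream of
    ``seed``, so identical seeds reproduce counts bitwise.
    """
    if peak_counts < 100:
        raise InvalidParameterError("peak_counts must be >= 100")
    wavelengths = [float(w) for w in wavelengths]
    tg = irf.time_grid
    if surface.time_grid.size != tg.size or not np.allclose(
        surface.time_grid, tg, atol=1e-9
    ):
        raise InvalidParameterError(
            "surface must be sampled on the detector (IRF) time grid"
        )
    seed_seq = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    children = seed_seq.spawn(len(wavelengths))
    curves = []
    for wavelength, child in zip(wavelengths, children):
        nu = units.nm_to_wavenumber(wavelength)
        lo = surface.wavenumber_grid.min()
        hi = surface.wavenumber_grid.max()
        if not (lo <= nu <= hi):
            raise InvalidParameterError(
                f"wavelength {wavelength} nm (nu = {nu:.1f} cm^-1) outside the "
                f"surface range [{lo:.1f}, {hi:.1f}] cm^-1"
            )
        trace = surface.slice_at_wavenumber(float(nu))
        expected = fftconvolve(irf.amplitudes, trace)[: tg.size]
        expected = np.clip(expected, 0.0, None)
        peak = expected.max()
        if peak > 0:
            expected = expected * (peak_counts / peak)
        rng = np.random.default_rng(child)
        counts = rng.poisson(expected)
        curves.append(
            DecayCurve(
                wavelength=wavelength,
                time_grid=tg,
                counts=counts,
                metadata={"peak_counts": int(peak_counts)},
            )
        )
    return curves


def steady_state_from_surface(
    surface: EmissionSurface, as_wavelength: bool = False
) -> SteadyStateSpectrum:
    """Time-integrate the surface into a steady-state spectrum.

    The wavelength form applies the Jacobian so the total integrated signal
    is preserved between the two axes.
    """
    integral = np.trapezoid(surface.intensity, surface.time_grid, axis=0)
    nu = surface.wavenumber_grid
    if nu[0] > nu[-1]:
        nu, integral = nu[::-1], integral[::-1]
    spectrum = SteadyStateSpectrum(axis="wavenumber", grid=nu, intensities=integral)
    return spectrum.to_wavelength() if as_wavelength else spectrum


def gaussian_band_spectrum(
    peak: float,
    fwhm: float,
    axis: str = "wavenumber",
    span_factor: float = 3.0,
    n_points: int = 301,
) -> SteadyStateSpectrum:
    """Smooth synthetic single-band (Gaussian) spectrum around ``peak``."""
    half = span_factor * fwhm
    grid = np.linspace(peak - half, peak + half, n_points)
    sigma = fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    intens = np.exp(-0.5 * ((grid - peak) / sigma) ** 2)
    return SteadyStateSpectrum(axis=axis, grid=grid, intensities=intens)


def time_zero_references(
    truth: RelaxationTruth,
    nonpolar_stokes_shift: float = 2000.0,
    absorption_solvent_shift: float = 800.0,
    band_fwhm: float = 2500.0,
) -> tuple[SteadyStateSpectrum, SteadyStateSpectrum, SteadyStateSpectrum]:
    """Synthetic reference spectra for the Fee-Maroncelli time-zero estimate.

    Returns ``(abs_polar, abs_nonpolar, em_nonpolar)`` Gaussian bands whose
    peak arithmetic reproduces the truth's nu_p(0) exactly:
    abs_polar peaks at nu_p(0) + S, abs_nonpolar at nu_p(0) + S + d and
    em_nonpolar at nu_p(0) + d, with S the non-polar Stokes shift and d the
    absorption solvent shift.
    """
    nu0 = truth.nu_peak_zero
    abs_polar = gaussian_band_spectrum(nu0 + nonpolar_stokes_shift, band_fwhm)
    abs_nonpolar = gaussian_band_spectrum(
        nu0 + nonpolar_stokes_shift + absorption_solvent_shift, band_fwhm
    )
    em_nonpolar = gaussian_band_spectrum(nu0 + absorption_solvent_shift, band_fwhm)
    return abs_polar, abs_nonpolar, em_nonpolar


@dataclass(frozen=True)
class RingGeometry:
    """Equatorial vesicle ring split into two arcs by angle."""

    center_row: float
    center_col: float
    radius: float
    thickness: float = 3.0
    split_angles: tuple = (0.0, np.pi)  # arc A spans [a0, a1), arc B the rest

    def masks(self, shape) -> np.ndarray:
        """Label image: 0 background, 1 arc A, 2 arc B."""
        rows, cols = np.indices(shape)
        dr = rows - self.center_row
        dc = cols - self.center_col
        r = np.hypot(dr, dc)
        on_ring = np.abs(r - self.radius) <= self.thickness / 2.0
        angle = np.mod(np.arctan2(dr, dc), 2.0 * np.pi)
        a0, a1 = np.mod(self.split_angles[0], 2 * np.pi), np.mod(
            self.split_angles[1], 2 * np.pi
        )
        if a0 <= a1:
            in_a = (angle >= a0) & (angle < a1)
        else:
            in_a = (angle >= a0) | (angle < a1)
        labels = np.zeros(shape, dtype=int)
        labels[on_ring & in_a] = 1
        labels[on_ring & ~in_a] = 2
        return labels


def simulate_vesicle_stack(
    image_size: tuple,
    ring: RingGeometry,
    phase_a_spectrum: SteadyStateSpectrum,
    phase_b_spectrum: SteadyStateSpectrum,
    channel_centers,
    channel_width: float,
    counts_scale: float = 1000.0,
    seed=0,
    background_fraction: float = 1e-3,
) -> tuple[SpectralImageStack, np.ndarray]:
    """Two-phase vesicle spectral image stack with its ground-truth mask.

    Ring pixels on arc A draw Poisson counts from ``phase_a_spectrum``
    band-integrated per channel (arc B likewise), jointly scaled so the
    brightest phase/channel expectation equals ``counts_scale``; background
    pixels have near-zero expectation.  Returns ``(stack, mask)`` with mask
    labels 0 = background, 1 = arc A, 2 = arc B.
    """
    channel_centers = np.asarray(channel_centers, dtype=float)

    def _band_means(spectrum):
        spec = spectrum.to_wavelength()
        lo, hi = spec.grid[0], spec.grid[-1]
        means = []
        for center in channel_centers:
            if center - channel_width / 2 < lo or center + channel_width / 2 > hi:
                raise InvalidParameterError(
                    f"channel at {center} nm not covered by the phase spectrum"
                )
            pts = np.linspace(center - channel_width / 2, center + channel_width / 2, 11)
            means.append(float(spec.intensity_at(pts).mean()))
        return np.array(means)

    expect_a = _band_means(phase_a_spectrum)
    expect_b = _band_means(phase_b_spectrum)
    scale = counts_scale / max(expect_a.max(), expect_b.max())
    expect_a, expect_b = expect_a * scale, expect_b * scale
    background = background_fraction * counts_scale

    labels = ring.masks(tuple(image_size))
    expected = np.full(tuple(image_size) + (channel_centers.size,), background)
    expected[labels == 1] = expect_a
    expected[labels == 2] = expect_b
    rng = np.random.default_rng(
        seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    )
    counts = rng.poisson(expected).astype(float)
    stack = SpectralImageStack(
        counts=counts, channel_centers=channel_centers, channel_width=channel_width
    )
    return stack, labels


#: Emission-maximum wavelengths (nm) per dye and solvent; the defaults
#: realize the solvatochromic orderings ethanol > DMSO > chloroform for
#: laurdan (hydrogen-bond-sensitive) and DMSO > ethanol > chloroform for
#: di-4-like probes (dielectric-constant-driven).
DEFAULT_SOLVENT_PEAKS_NM = {
    "laurdan": {"ethanol": 490.0, "dmso": 475.0, "chloroform": 440.0},
    "di4": {"dmso": 625.0, "ethanol": 610.0, "chloroform": 580.0},
}

_SOLVENTS = ("ethanol", "dmso", "chloroform")


def simulate_solvent_spectrum(
    dye: str,
    solvent: str,
    peak_table: dict | None = None,
    band_fwhm_nm: float = 70.0,
) -> SteadyStateSpectrum:
    """Smooth single-band emission spectrum of a dye in one solvent."""
    solvent = solvent.lower()
    if solvent not in _SOLVENTS:
        raise InvalidParameterError(
            f"unknown solvent {solvent!r}; expected one of {_SOLVENTS}"
        )
    table = peak_table if peak_table is not None else DEFAULT_SOLVENT_PEAKS_NM
    try:
        peak = float(table[dye][solvent])
    except KeyError:
        raise InvalidParameterError(
            f"peak table has no entry for ({dye!r}, {solvent!r})"
        ) from None
    return gaussian_band_spectrum(peak, band_fwhm_nm, axis="wavelength")
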