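"""Time-resolved emission spectra (TRES) reconstruction and band-shape fitting.

The spectral reconstruction method combines per-wavelength deconvolved decay
fits D_k(t) with the steady-state emission spectrum S:

    I(lambda_k, t) = D_k(t) * S(lambda_k) / integral_0^inf D_k(t') dt'

so that, by construction, the time integral of every reconstructed decay
equals the steady-state intensity at that wavelength.  The surface is then
converted to the wavenumber axis (with the Jacobian) and each time slice is
fitted with a skewed log-normal band (Siano-Metzler form) to give the band
maximum nu_max(t) and spectral width FWHM(t).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from . import units
from .decayfit import MultiExponentialModel, numeric_fwhm
from .errors import DegenerateInputError, InvalidParameterError, TdfspecWarning

__all__ = [
    "SteadyStateSpectrum",
    "TresSurface",
    "LognormalBand",
    "BandTrajectory",
    "lognormal_profile",
    "fit_band",
    "fit_spectrum_band",
    "reconstruct",
    "band_trajectory",
]


@dataclass(frozen=True)
class SteadyStateSpectrum:
    """Steady-state emission (or absorption) spectrum on either spectral axis."""

    axis: str  # "wavelength" (nm) or "wavenumber" (cm^-1)
    grid: np.ndarray  # strictly monotone
    intensities: np.ndarray  # >= 0
    excitation_nm: float | None = None

    def __post_init__(self):
        if self.axis not in ("wavelength", "wavenumber"):
            raise InvalidParameterError(f"unknown spectral axis {self.axis!r}")
        grid = np.asarray(self.grid, dtype=float)
        intens = np.asarray(self.intensities, dtype=float)
        object.__setattr__(self, "grid", grid)
        object.__setattr__(self, "intensities", intens)
        if grid.size < 5:
            raise InvalidParameterError("spectrum needs at least 5 grid points")
        steps = np.diff(grid)
        if not (np.all(steps > 0) or np.all(steps < 0)):
            raise InvalidParameterError("spectrum grid must be strictly monotone")
        if np.any(intens < 0) or not np.all(np.isfinite(intens)):
            raise InvalidParameterError("intensities must be finite and >= 0")

    def _ascending(self):
        if self.grid[0] > self.grid[-1]:
            return self.grid[::-1], self.intensities[::-1]
        return self.grid, self.intensities

    def intensity_at(self, points) -> np.ndarray:
        """Linear interpolation; points outside the grid raise."""
        points = np.atleast_1d(np.asarray(points, dtype=float))
        grid, intens = self._ascending()
        if np.any(points < grid[0]) or np.any(points > grid[-1]):
            raise InvalidParameterError(
                f"points outside spectrum grid [{grid[0]}, {grid[-1]}]"
            )
        return np.interp(points, grid, intens)

    def to_wavenumber(self) -> "SteadyStateSpectrum":
        """Jacobian-converted copy on the wavenumber axis (ascending)."""
        if self.axis == "wavenumber":
            return self
        grid, intens = self._ascending()
        nu = units.nm_to_wavenumber(grid)[::-1]
        inu = units.intensity_to_wavenumber_form(grid, intens)[::-1]
        return SteadyStateSpectrum(
            axis="wavenumber", grid=nu, intensities=inu, excitation_nm=self.excitation_nm
        )

    def to_wavelength(self) -> "SteadyStateSpectrum":
        """Jacobian-converted copy on the wavelength axis (ascending)."""
        if self.axis == "wavelength":
            return self
        grid, intens = self._ascending()
        lam = units.wavenumber_to_nm(grid)[::-1]
        ilam = units.intensity_to_wavelength_form(grid, intens)[::-1]
        return SteadyStateSpectrum(
            axis="wavelength", grid=lam, intensities=ilam, excitation_nm=self.excitation_nm
        )


@dataclass(frozen=True)
class TresSurface:
    """Reconstructed I(nu, t): rows are time slices, columns wavenumber points."""

    wavenumber_grid: np.ndarray  # cm^-1, ascending
    time_grid: np.ndarray  # ns, increasing
    intensity: np.ndarray  # shape (time, wavenumber), >= 0
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        nu = np.asarray(self.wavenumber_grid, dtype=float)
        t = np.asarray(self.time_grid, dtype=float)
        I = np.asarray(self.intensity, dtype=float)
        object.__setattr__(self, "wavenumber_grid", nu)
        object.__setattr__(self, "time_grid", t)
        object.__setattr__(self, "intensity", I)
        if np.any(np.diff(nu) <= 0):
            raise InvalidParameterError("wavenumber grid must be ascending")
        if np.any(np.diff(t) <= 0) or t[0] < 0:
            raise InvalidParameterError("time grid must be increasing and >= 0")
        if I.shape != (t.size, nu.size):
            raise InvalidParameterError("intensity shape must be (time, wavenumber)")
        if not np.all(np.isfinite(I)) or np.any(I < -1e-12):
            raise InvalidParameterError("intensity must be finite and >= 0")

    def slice_at(self, index: int) -> np.ndarray:
        return self.intensity[index]


@dataclass
class LognormalBand:
    """Skewed log-normal emission band.

    The profile (Siano-Metzler form, parameterized directly by the FWHM
    ``fwhm`` and asymmetry ``asymmetry``) is

        I(nu) = A exp(-ln2 * [ln(1 + 2 b (nu - nu_max) / Delta) / b]^2)

    with Delta = fwhm * b / sinh(b); the expression inside the logarithm must
    stay positive, intensities are zero beyond the cutoff.  b -> 0 recovers a
    Gaussian of FWHM ``fwhm``.
    """

    amplitude: float
    peak: float  # nu_max, cm^-1
    fwhm: float  # cm^-1
    asymmetry: float
    residual_norm: float = 0.0

    def __post_init__(self):
        if self.fwhm <= 0:
            raise InvalidParameterError("band FWHM must be positive")
        if self.amplitude < 0:
            raise InvalidParameterError("band amplitude must be >= 0")

    def profile(self, nu) -> np.ndarray:
        return lognormal_profile(nu, self.amplitude, self.peak, self.fwhm, self.asymmetry)


_LN2 = np.log(2.0)


def lognormal_profile(nu, amplitude, peak, fwhm, asymmetry) -> np.ndarray:
    """Evaluate the skewed log-normal band; Gaussian in the b -> 0 limit.

    Implemented with ``log1p`` so the profile (and its derivative with
    respect to the asymmetry) is smooth through b = 0; only b == 0 exactly
    takes the closed-form Gaussian branch.
    """
    nu = np.asarray(nu, dtype=float)
    if fwhm <= 0:
        raise InvalidParameterError("band FWHM must be positive")
    b = float(asymmetry)
    x = nu - peak
    if b == 0.0 or abs(b) < 1e-12:
        return amplitude * np.exp(-4.0 * _LN2 * (x / fwhm) ** 2)
    delta = fwhm * b / np.sinh(b)
    z = 2.0 * b * x / delta
    out = np.zeros_like(nu, dtype=float)
    pos = z > -1.0
    out[pos] = amplitude * np.exp(-_LN2 * (np.log1p(z[pos]) / b) ** 2)
    return out


def fit_band(
    wavenumber: np.ndarray,
    intensity: np.ndarray,
    initial: LognormalBand | None = None,
) -> LognormalBand:
    """Least-squares skewed log-normal fit of a single spectral slice.

    Requires at least 5 points and an interior maximum (the band peak must be
    bracketed by the grid).  The FWHM follows in closed form from the fitted
    parameters; the symmetric limit is handled smoothly.
    """
    nu = np.asarray(wavenumber, dtype=float)
    y = np.asarray(intensity, dtype=float)
    if nu.size != y.size:
        raise InvalidParameterError("grid and intensity differ in length")
    if nu.size < 5:
        raise InvalidParameterError("slice needs at least 5 points")
    if nu[0] > nu[-1]:
        nu, y = nu[::-1], y[::-1]
    k = int(np.argmax(y))
    if k == 0 or k == nu.size - 1 or y[k] <= 0:
        raise DegenerateInputError("slice has no interior maximum")
    # a noise-induced interior argmax on a monotone slice is not a band
    # maximum: require the peak to be genuinely bracketed
    if y[0] >= 0.95 * y[k] or y[-1] >= 0.95 * y[k]:
        raise DegenerateInputError(
            "band maximum not bracketed within the spectral window"
        )

    span = float(nu[-1] - nu[0])
    if initial is not None:
        x0 = np.array(
            [initial.amplitude, initial.peak, initial.fwhm, initial.asymmetry]
        )
    else:
        try:
            w0 = numeric_fwhm(nu, y)
        except DegenerateInputError:
            w0 = span / 3.0
        x0 = np.array([y[k], nu[k], w0, 0.0])

    lower = np.array([0.0, nu[0], span * 1e-3, -1.5])
    upper = np.array([np.inf, nu[-1], span * 10.0, 1.5])
    x0 = np.clip(x0, lower, upper + 0.0)
    x0[0] = max(x0[0], y[k] * 1e-3)

    def residual(x):
        return lognormal_profile(nu, x[0], x[1], x[2], x[3]) - y

    result = least_squares(
        residual,
        x0,
        bounds=(lower, upper),
        method="trf",
        x_scale=np.array([max(y[k], 1e-12), span, span, 1.0]),
        max_nfev=500,
    )
    amp, peak, fwhm, asym = result.x
    return LognormalBand(
        amplitude=float(amp),
        peak=float(peak),
        fwhm=float(fwhm),
        asymmetry=float(asym),
        residual_norm=float(np.linalg.norm(result.fun)),
    )


def fit_spectrum_band(spectrum: SteadyStateSpectrum) -> LognormalBand:
    """Band-fit a steady-state spectrum on the wavenumber axis."""
    s = spectrum.to_wavenumber()
    return fit_band(s.grid, s.intensities)


def reconstruct(
    fits,
    spectrum: SteadyStateSpectrum,
    time_grid: np.ndarray,
) -> TresSurface:
    """Reconstruct TRES from per-wavelength decay fits and the steady-state
    spectrum.

    Parameters
    ----------
    fits
        Sequence of ``(wavelength_nm, MultiExponentialModel)`` pairs, one per
        recorded decay.  Backgrounds are excluded (detector artifact, not
        emission); the shift plays no role once the decay is deconvolved.
    spectrum
        Steady-state emission spectrum covering every fit wavelength.
    time_grid
        Times (ns) at which slices are evaluated.

    Returns
    -------
    TresSurface on the ascending wavenumber grid, normalized so that the
    analytic time integral of each reconstructed decay equals the
    steady-state intensity at that wavenumber.
    """
    time_grid = np.asarray(time_grid, dtype=float)
    pairs = [(float(w), m) for w, m in fits]
    if not pairs:
        raise InvalidParameterError("no fits supplied")
    wavelengths = np.array([w for w, _ in pairs])
    spec_wl = spectrum.to_wavelength()
    s_values = spec_wl.intensity_at(wavelengths)

    rows = []
    for (wavelength, model), s_val in zip(pairs, s_values):
        if not isinstance(model, MultiExponentialModel):
            raise InvalidParameterError("fits must carry MultiExponentialModel entries")
        norm = model.integral()
        if norm <= 0:
            raise DegenerateInputError(
                f"fit at {wavelength} nm has zero analytic integral"
            )
        rows.append(model.decay(time_grid) * (s_val / norm))
    intensity_wl = np.stack(rows, axis=1)  # (time, wavelength)

    # Rise components (negative amplitudes) can push sampled values slightly
    # below zero near t = 0; emission is non-negative, so clip.  The
    # normalization invariant uses the analytic integral and is unaffected.
    intensity_wl = np.clip(intensity_wl, 0.0, None)

    # Jacobian-convert per-wavelength densities to the wavenumber axis.
    nu = units.nm_to_wavenumber(wavelengths)
    intensity_nu = intensity_wl * (wavelengths**2 / units.WAVENUMBER_PER_NM)[None, :]
    order = np.argsort(nu)
    return TresSurface(
        wavenumber_grid=nu[order],
        time_grid=time_grid,
        intensity=intensity_nu[:, order],
        provenance={
            "wavelengths_nm": [w for w, _ in pairs],
            "spectrum_axis": spectrum.axis,
        },
    )


@dataclass
class BandTrajectory:
    """Per-time-slice log-normal band parameters on a common time grid.

    Slices that could not be fitted (``on_error="skip"``) carry NaN entries
    and are listed in ``skipped``; ``valid()`` filters them out.
    """

    times: np.ndarray  # ns
    nu_max: np.ndarray  # cm^-1
    fwhm: np.ndarray  # cm^-1
    asymmetry: np.ndarray
    amplitude: np.ndarray
    skipped: list = field(default_factory=list)

    def valid(self) -> "BandTrajectory":
        ok = np.isfinite(self.nu_max)
        return BandTrajectory(
            times=self.times[ok],
            nu_max=self.nu_max[ok],
            fwhm=self.fwhm[ok],
            asymmetry=self.asymmetry[ok],
            amplitude=self.amplitude[ok],
            skipped=list(self.skipped),
        )


def band_trajectory(surface: TresSurface, on_error: str = "raise") -> BandTrajectory:
    """Fit every time slice of a TRES surface, warm-starting from the
    previous slice.

    ``on_error="skip"`` records unfittable slices (e.g. the band maximum
    still outside the measured spectral window at the earliest times) as NaN
    instead of raising.
    """
    if on_error not in ("raise", "skip"):
        raise InvalidParameterError("on_error must be 'raise' or 'skip'")
    n_t = surface.time_grid.size
    nu_max = np.full(n_t, np.nan)
    fwhm = np.full(n_t, np.nan)
    asym = np.full(n_t, np.nan)
    amp = np.full(n_t, np.nan)
    skipped = []
    previous = None
    for i in range(n_t):
        try:
            band = fit_band(
                surface.wavenumber_grid, surface.intensity[i], initial=previous
            )
        except DegenerateInputError as exc:
            if on_error == "raise":
                raise DegenerateInputError(
                    f"slice at t = {surface.time_grid[i]:.4g} ns: {exc}"
                ) from exc
            skipped.append((float(surface.time_grid[i]), str(exc)))
            continue
        previous = band
        nu_max[i] = band.peak
        fwhm[i] = band.fwhm
        asym[i] = band.asymmetry
        amp[i] = band.amplitude
    if skipped:
        warnings.warn(
            f"{len(skipped)} TRES slice(s) skipped during band fitting",
            TdfspecWarning,
            stacklevel=2,
        )
    return BandTrajectory(
        times=surface.time_grid,
        nu_max=nu_max,
        fwhm=fwhm,
        asymmetry=asym,
        amplitude=amp,
        skipped=skipped,
    )
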