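"""Time-dependent fluorescence shift (TDFS) observables.

From the band-maximum trajectory nu(t) and width trajectory FWHM(t) of a
reconstructed TRES surface this module derives

* nu(0)   -- the time-zero (Franck-Condon) emission maximum, estimated from
  steady-state reference spectra by the Fee-Maroncelli construction
  nu(0) = peak(abs, polar) - [peak(abs, nonpolar) - peak(em, nonpolar)];
* nu(inf) -- the fully relaxed emission maximum, read off the terminal
  plateau of nu(t);
* the total shift  Delta nu = nu(0) - nu(inf), proportional to the polarity
  (hydration) probed by the dye;
* the shift correlation function  C(t) = (nu(t) - nu(inf)) / Delta nu  and
  the integrated relaxation time  tau_r = int_0^inf C(t) dt;
* the interior maxima of FWHM(t).  The spectral width transiently broadens
  while sub-populations relax at different rates, so the time of the width
  maximum proxies the average relaxation time even when nu(0) is not
  measurable (dyes insoluble in non-polar solvents); heterogeneous probes
  can show several maxima.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks, savgol_filter

from .errors import (
    InconsistentEstimatesError,
    InvalidParameterError,
    RelaxationIncompleteWarning,
    TimeZeroUnavailable,
)
from .tres import BandTrajectory, SteadyStateSpectrum, fit_spectrum_band

__all__ = [
    "RelaxationResult",
    "TauRResult",
    "estimate_time_zero",
    "estimate_nu_infinity",
    "total_shift",
    "correlation_function",
    "integrated_relaxation_time",
    "fwhm_maxima",
    "principal_fwhm_maximum",
    "analyze_trajectory",
]


def estimate_time_zero(
    abs_polar: SteadyStateSpectrum | None,
    abs_nonpolar: SteadyStateSpectrum | None,
    em_nonpolar: SteadyStateSpectrum | None,
) -> float:
    """Fee-Maroncelli time-zero estimate of the emission maximum (cm^-1).

    The absorption spectrum in the polar environment of interest is shifted
    by the intrinsic (non-polar solvent) absorption-emission gap:

        nu(0) = peak(abs_polar) - [peak(abs_nonpolar) - peak(em_nonpolar)]

    Raises
    ------
    TimeZeroUnavailable
        If any reference spectrum is missing (e.g. the dye is insoluble in
        non-polar solvents), carrying the reason.
    """
    missing = [
        name
        for name, spec in (
            ("polar absorption", abs_polar),
            ("nonpolar absorption", abs_nonpolar),
            ("nonpolar emission", em_nonpolar),
        )
        if spec is None
    ]
    if missing:
        raise TimeZeroUnavailable(
            "time-zero estimate unavailable: missing " + ", ".join(missing)
        )
    peak_abs_polar = fit_spectrum_band(abs_polar).peak
    peak_abs_np = fit_spectrum_band(abs_nonpolar).peak
    peak_em_np = fit_spectrum_band(em_nonpolar).peak
    return float(peak_abs_polar - (peak_abs_np - peak_em_np))


def estimate_nu_infinity(
    times: np.ndarray,
    nu: np.ndarray,
    slope_threshold: float = 25.0,
    window_decades: float = 0.5,
) -> float:
    """Asymptote of the band-maximum trajectory (cm^-1).

    Returns the mean of nu(t) over the points of the terminal
    ``window_decades`` of the time axis whose local slope |d nu / d log10 t|
    is below ``slope_threshold`` (cm^-1 per decade).  If no point qualifies
    the final value is returned with a :class:`RelaxationIncompleteWarning`.
    """
    times = np.asarray(times, dtype=float)
    nu = np.asarray(nu, dtype=float)
    if times.size != nu.size or times.size < 3:
        raise InvalidParameterError("trajectory needs >= 3 aligned points")
    if np.any(times <= 0):
        raise InvalidParameterError("trajectory times must be positive")
    span = np.log10(times[-1] / times[0])
    if span < 1.5:
        raise InvalidParameterError(
            f"trajectory spans {span:.2f} decades; >= 1.5 required"
        )
    logt = np.log10(times)
    slope = np.gradient(nu, logt)
    terminal = logt >= logt[-1] - window_decades
    flat = terminal & (np.abs(slope) < slope_threshold)
    if not np.any(flat):
        warnings.warn(
            "no terminal plateau below the slope threshold; relaxation not "
            "complete within the window, falling back to the final point",
            RelaxationIncompleteWarning,
            stacklevel=2,
        )
        return float(nu[-1])
    return float(np.mean(nu[flat]))


def total_shift(nu_zero: float, nu_infinity: float) -> float:
    """Total fluorescence shift Delta nu = nu(0) - nu(inf) (cm^-1)."""
    delta = float(nu_zero) - float(nu_infinity)
    if delta < 0:
        raise InconsistentEstimatesError(
            f"nu(0) = {nu_zero} below nu(inf) = {nu_infinity}: inconsistent estimates"
        )
    return delta


def correlation_function(
    times: np.ndarray, nu: np.ndarray, nu_zero: float, nu_infinity: float
) -> np.ndarray:
    """Normalized shift correlation C(t) = (nu(t) - nu(inf)) / Delta nu.

    Values are reported as-is (no clipping) so out-of-range points remain
    visible as diagnostics.
    """
    delta = float(nu_zero) - float(nu_infinity)
    if delta <= 0:
        raise InvalidParameterError("Delta nu must be positive for C(t)")
    nu = np.asarray(nu, dtype=float)
    times = np.asarray(times, dtype=float)
    if times.size != nu.size:
        raise InvalidParameterError("times and nu differ in length")
    return (nu - nu_infinity) / delta


@dataclass
class TauRResult:
    """Integrated relaxation time split into observed and extrapolated parts."""

    total: float  # ns
    windowed: float  # trapezoidal integral over the observed window
    tail: float  # exponential-tail extrapolation beyond the window
    tail_lifetime: float | None = None  # ns, None when no tail was fitted


def integrated_relaxation_time(times: np.ndarray, c: np.ndarray) -> TauRResult:
    """tau_r = int_0^inf C(t) dt (ns).

    Trapezoidal integration over the observed window plus a single-exponential
    tail fitted to the last decade of positive C(t); the leading [0, t_0]
    segment is closed assuming C(0) = 1.  Both contributions are reported
    separately so the extrapolation can be audited.
    """
    times = np.asarray(times, dtype=float)
    c = np.asarray(c, dtype=float)
    if times.size != c.size or times.size < 3:
        raise InvalidParameterError("C(t) needs >= 3 aligned points")
    if not np.all(np.isfinite(c)):
        raise InvalidParameterError("C(t) contains non-finite values")
    if c[-1] >= 0.05:
        warnings.warn(
            f"C(t) ends at {c[-1]:.3f} >= 0.05; tau_r is tail-dominated",
            RelaxationIncompleteWarning,
            stacklevel=2,
        )
    windowed = float(np.trapezoid(c, times))
    if times[0] > 0:
        # close the unobserved leading segment with C(0) = 1
        windowed += float(0.5 * (1.0 + c[0]) * times[0])

    tail = 0.0
    tail_lifetime = None
    last_decade = times >= times[-1] / 10.0
    usable = last_decade & (c > 0)
    if c[-1] > 0 and usable.sum() >= 3:
        # linear regression of ln C on t over the last decade
        coeffs = np.polyfit(times[usable], np.log(c[usable]), 1)
        if coeffs[0] < 0:
            tail_lifetime = float(-1.0 / coeffs[0])
            tail = float(c[-1] * tail_lifetime)
    return TauRResult(
        total=windowed + tail, windowed=windowed, tail=tail, tail_lifetime=tail_lifetime
    )


def _parabolic_vertex(x: np.ndarray, y: np.ndarray, i: int) -> tuple[float, float]:
    """Vertex of the parabola through points (i-1, i, i+1); falls back to i."""
    x0, x1, x2 = x[i - 1], x[i], x[i + 1]
    y0, y1, y2 = y[i - 1], y[i], y[i + 1]
    denom = (x0 - x1) * (x0 - x2) * (x1 - x2)
    if denom == 0:
        return float(x1), float(y1)
    a = (x2 * (y1 - y0) + x1 * (y0 - y2) + x0 * (y2 - y1)) / denom
    b = (x2**2 * (y0 - y1) + x1**2 * (y2 - y0) + x0**2 * (y1 - y2)) / denom
    if a >= 0:
        return float(x1), float(y1)
    xv = -b / (2.0 * a)
    if not (min(x0, x2) <= xv <= max(x0, x2)):
        return float(x1), float(y1)
    c = y1 - a * x1**2 - b * x1
    return float(xv), float(a * xv**2 + b * xv + c)


def fwhm_maxima(
    times: np.ndarray,
    widths: np.ndarray,
    smoothing_window: int = 5,
    min_prominence: float = 0.02,
    return_prominences: bool = False,
) -> list:
    """Interior local maxima of the spectral-width trajectory FWHM(t).

    The trajectory is resampled onto a uniform log-time grid, smoothed with a
    Savitzky-Golay filter (local quadratic, ``smoothing_window`` points) and
    searched for interior maxima with prominence above ``min_prominence``
    times the trajectory range.  Peak times are refined by parabolic
    interpolation in log-time.  Endpoint extrema are excluded; results are
    sorted by time (earlier first on ties).

    Returns a list of ``(time_ns, width_cm1)`` pairs (triples including the
    absolute prominence in cm^-1 when ``return_prominences`` is set);
    monotone trajectories yield an empty list.
    """
    times = np.asarray(times, dtype=float)
    widths = np.asarray(widths, dtype=float)
    ok = np.isfinite(widths) & np.isfinite(times)
    times, widths = times[ok], widths[ok]
    if times.size < 7:
        raise InvalidParameterError("width trajectory needs >= 7 points")
    if smoothing_window > times.size:
        raise InvalidParameterError("fewer points than the smoothing window")
    if np.any(times <= 0) or np.any(np.diff(times) <= 0):
        raise InvalidParameterError("times must be positive and increasing")
    if smoothing_window % 2 == 0:
        smoothing_window += 1

    logt = np.log10(times)
    uniform_logt = np.linspace(logt[0], logt[-1], times.size)
    resampled = np.interp(uniform_logt, logt, widths)
    if smoothing_window >= 5:
        smooth = savgol_filter(resampled, smoothing_window, polyorder=2)
    else:
        smooth = resampled

    span = float(np.ptp(smooth))
    if span <= 0:
        return []
    peaks, props = find_peaks(smooth, prominence=min_prominence * span)
    results = []
    for idx, prom in zip(peaks, props["prominences"]):
        if idx == 0 or idx == smooth.size - 1:
            continue
        lv, wv = _parabolic_vertex(uniform_logt, smooth, idx)
        results.append((float(10.0**lv), float(wv), float(prom)))
    results.sort(key=lambda triple: triple[0])
    if return_prominences:
        return results
    return [(t, w) for t, w, _ in results]


def principal_fwhm_maximum(
    times: np.ndarray,
    widths: np.ndarray,
    mode: str = "prominent",
    prominence_floor: float = 0.25,
    **kwargs,
) -> tuple[float, float] | None:
    """One representative width-maximum time from a trajectory.

    ``mode="prominent"`` returns the most prominent interior maximum — the
    robust choice when a single relaxation process is expected, since
    low-amplitude fit-noise wiggles can masquerade as extra maxima.
    ``mode="latest"`` returns the latest maximum whose prominence is at
    least ``prominence_floor`` times the largest — the slow
    dipolar-relaxation signature of multi-process probes.  Returns
    ``(time_ns, width_cm1)`` or None when no maximum exists.
    """
    maxima = fwhm_maxima(times, widths, return_prominences=True, **kwargs)
    if not maxima:
        return None
    if mode == "prominent":
        t, w, _ = max(maxima, key=lambda triple: triple[2])
        return (t, w)
    if mode == "latest":
        best = max(triple[2] for triple in maxima)
        kept = [triple for triple in maxima if triple[2] >= prominence_floor * best]
        t, w, _ = kept[-1]
        return (t, w)
    raise InvalidParameterError(f"unknown selection mode {mode!r}")


@dataclass
class RelaxationResult:
    """TDFS observables derived from one band trajectory.

    ``nu_zero`` (and hence ``delta_nu``, ``tau_r`` and the correlation
    function) may be unavailable when the time-zero reference spectra cannot
    be measured; ``nu_zero_unavailable_reason`` then records why.
    """

    nu_infinity: float
    nu_zero: float | None = None
    nu_zero_unavailable_reason: str | None = None
    delta_nu: float | None = None
    tau_r: TauRResult | None = None
    correlation_times: np.ndarray | None = None
    correlation: np.ndarray | None = None
    fwhm_maxima: list = field(default_factory=list)
    trajectory: BandTrajectory | None = None
    warnings: list = field(default_factory=list)

    @property
    def nu_zero_available(self) -> bool:
        return self.nu_zero is not None

    def to_dict(self) -> dict:
        return {
            "nu_infinity_cm1": self.nu_infinity,
            "nu_zero_cm1": self.nu_zero,
            "nu_zero_available": self.nu_zero_available,
            "nu_zero_unavailable_reason": self.nu_zero_unavailable_reason,
            "delta_nu_cm1": self.delta_nu,
            "tau_r_ns": None if self.tau_r is None else self.tau_r.total,
            "tau_r_windowed_ns": None if self.tau_r is None else self.tau_r.windowed,
            "tau_r_tail_ns": None if self.tau_r is None else self.tau_r.tail,
            "fwhm_maxima": [
                {"time_ns": t, "width_cm1": w} for t, w in self.fwhm_maxima
            ],
            "warnings": list(self.warnings),
        }


def analyze_trajectory(
    trajectory: BandTrajectory,
    time_zero_references: tuple | None = None,
    slope_threshold: float = 25.0,
    smoothing_window: int = 5,
    min_prominence: float = 0.02,
) -> RelaxationResult:
    """Derive the full set of TDFS observables from a band trajectory.

    ``time_zero_references`` is the ``(abs_polar, abs_nonpolar, em_nonpolar)``
    spectrum triple for the Fee-Maroncelli estimate, or None when it cannot
    be measured; in the latter case the total shift and relaxation time are
    flagged not-computable rather than failing the analysis.
    """
    traj = trajectory.valid()
    captured: list[str] = []
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        nu_inf = estimate_nu_infinity(
            traj.times, traj.nu_max, slope_threshold=slope_threshold
        )
        maxima = fwhm_maxima(
            traj.times,
            traj.fwhm,
            smoothing_window=smoothing_window,
            min_prominence=min_prominence,
        )
        result = RelaxationResult(
            nu_infinity=nu_inf, fwhm_maxima=maxima, trajectory=trajectory
        )
        if time_zero_references is None:
            result.nu_zero_unavailable_reason = (
                "time-zero reference spectra not available"
            )
        else:
            try:
                result.nu_zero = estimate_time_zero(*time_zero_references)
            except TimeZeroUnavailable as exc:
                result.nu_zero_unavailable_reason = exc.reason
        if result.nu_zero is not None:
            result.delta_nu = total_shift(result.nu_zero, nu_inf)
            if result.delta_nu > 0:
                c = correlation_function(traj.times, traj.nu_max, result.nu_zero, nu_inf)
                result.correlation_times = traj.times
                result.correlation = c
                result.tau_r = integrated_relaxation_time(traj.times, c)
        captured.extend(str(w.message) for w in caught)
    result.warnings = captured
    return result
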