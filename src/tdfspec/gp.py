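"""Generalized polarization (GP) of polarity-sensitive membrane probes.

GP = (I_blue - I_red) / (I_blue + I_red) is a normalized two-band intensity
ratio in [-1, 1] reporting lipid packing: blue-shifted emission (ordered,
tightly packed bilayers) gives high GP, red-shifted emission (disordered,
hydrated bilayers) gives low GP.  Laurdan uses the 440/490 nm bands, the
red-shifted probe di-4-ANEPPDHQ uses 560/650 nm.  The module computes GP
from spectrofluorometer spectra (point or ~10 nm band mode), builds
per-pixel GP maps from spectral image stacks, extracts per-phase spectra of
phase-separated vesicles, and ranks solvent polarity on the dielectric and
Dimroth-Reichardt scales.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import (
    DegenerateInputError,
    InvalidParameterError,
    TdfspecWarning,
    UndefinedGPError,
)
from .tres import SteadyStateSpectrum

__all__ = [
    "GpConvention",
    "SpectralImageStack",
    "GpMap",
    "PolarityTable",
    "gp_value",
    "gp_from_spectrum",
    "delta_gp",
    "gp_map",
    "phase_spectra",
    "rank_polarity",
]


@dataclass(frozen=True)
class GpConvention:
    """Blue/red emission-band positions used to form the GP ratio."""

    name: str
    blue_nm: float
    red_nm: float
    half_width_nm: float = 5.0

    def __post_init__(self):
        if not self.blue_nm < self.red_nm:
            raise InvalidParameterError("blue channel must lie below red channel")
        if self.half_width_nm <= 0:
            raise InvalidParameterError("band half-width must be positive")

    @classmethod
    def laurdan(cls) -> "GpConvention":
        return cls(name="laurdan", blue_nm=440.0, red_nm=490.0)

    @classmethod
    def di4(cls) -> "GpConvention":
        return cls(name="di4", blue_nm=560.0, red_nm=650.0)

    @classmethod
    def for_dye(cls, dye: str) -> "GpConvention":
        try:
            return {"laurdan": cls.laurdan, "di4": cls.di4}[dye]()
        except KeyError:
            raise InvalidParameterError(f"unknown dye convention {dye!r}") from None


@dataclass(frozen=True)
class SpectralImageStack:
    """Multi-channel image: an emission spectrum for every pixel."""

    counts: np.ndarray  # (rows, cols, channels), >= 0
    channel_centers: np.ndarray  # nm, strictly increasing
    channel_width: float  # nm

    def __post_init__(self):
        counts = np.asarray(self.counts, dtype=float)
        centers = np.asarray(self.channel_centers, dtype=float)
        object.__setattr__(self, "counts", counts)
        object.__setattr__(self, "channel_centers", centers)
        if counts.ndim != 3:
            raise InvalidParameterError("stack must be (rows, cols, channels)")
        if centers.size != counts.shape[2] or centers.size < 2:
            raise InvalidParameterError("need >= 2 channel centers matching the stack")
        if np.any(np.diff(centers) <= 0):
            raise InvalidParameterError("channel centers must be strictly increasing")
        if np.any(counts < 0):
            raise InvalidParameterError("counts must be non-negative")
        if self.channel_width <= 0:
            raise InvalidParameterError("channel width must be positive")

    def band_counts(self, center_nm: float, half_width_nm: float) -> np.ndarray:
        """Mean counts over the channels overlapping [center +- half-width]."""
        reach = half_width_nm + self.channel_width / 2.0
        selected = np.abs(self.channel_centers - center_nm) <= reach
        if not np.any(selected):
            raise InvalidParameterError(
                f"stack channels do not cover the {center_nm} nm band"
            )
        return self.counts[:, :, selected].mean(axis=2)


@dataclass(frozen=True)
class GpMap:
    """Per-pixel GP values; invalid pixels are NaN and masked out."""

    values: np.ndarray  # NaN where invalid
    valid: np.ndarray  # boolean mask
    convention: GpConvention

    def __post_init__(self):
        vals = np.asarray(self.values, dtype=float)
        valid = np.asarray(self.valid, dtype=bool)
        object.__setattr__(self, "values", vals)
        object.__setattr__(self, "valid", valid)
        if vals.shape != valid.shape:
            raise InvalidParameterError("values and mask shapes differ")
        finite = vals[valid]
        if finite.size and (np.any(finite < -1) or np.any(finite > 1)):
            raise InvalidParameterError("valid GP values must lie in [-1, 1]")


def gp_value(i_blue, i_red):
    """GP = (I_blue - I_red) / (I_blue + I_red); antisymmetric, in [-1, 1]."""
    i_blue = np.asarray(i_blue, dtype=float)
    i_red = np.asarray(i_red, dtype=float)
    total = i_blue + i_red
    if np.ndim(total) == 0:
        if total == 0:
            raise UndefinedGPError("GP undefined: zero total intensity")
        return float((i_blue - i_red) / total)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(total > 0, (i_blue - i_red) / np.where(total > 0, total, 1.0), np.nan)
    return out


def gp_from_spectrum(
    spectrum: SteadyStateSpectrum,
    convention: GpConvention,
    mode: str = "point",
) -> float:
    """GP of a steady-state emission spectrum.

    ``point`` mode interpolates the intensity at the band centers (suits
    1 nm-sampled spectrofluorometer data); ``band`` mode averages over
    [center +- half-width] (suits ~10 nm imaging channels).
    """
    spec = spectrum.to_wavelength()
    if mode == "point":
        i_blue = float(spec.intensity_at(convention.blue_nm)[0])
        i_red = float(spec.intensity_at(convention.red_nm)[0])
    elif mode == "band":
        def _band(center):
            lo = center - convention.half_width_nm
            hi = center + convention.half_width_nm
            pts = np.linspace(lo, hi, 21)
            return float(spec.intensity_at(pts).mean())

        i_blue = _band(convention.blue_nm)
        i_red = _band(convention.red_nm)
    else:
        raise InvalidParameterError(f"unknown GP mode {mode!r}")
    return gp_value(i_blue, i_red)


def delta_gp(gp_a: float, gp_b: float) -> float:
    """Difference of two GP values, gp_a - gp_b."""
    return float(gp_a) - float(gp_b)


def gp_map(
    stack: SpectralImageStack,
    convention: GpConvention,
    count_threshold: float | None = None,
) -> GpMap:
    """Per-pixel band-mode GP map.

    Pixels whose total counts fall below ``count_threshold`` (default: 5% of
    the maximum per-pixel total, which excludes background without tuning)
    are marked invalid, as are pixels with a zero GP denominator.
    """
    i_blue = stack.band_counts(convention.blue_nm, convention.half_width_nm)
    i_red = stack.band_counts(convention.red_nm, convention.half_width_nm)
    totals = stack.counts.sum(axis=2)
    if count_threshold is None:
        count_threshold = 0.05 * float(totals.max())
    valid = (totals >= count_threshold) & ((i_blue + i_red) > 0)
    values = gp_value(i_blue, i_red)
    values = np.where(valid, values, np.nan)
    return GpMap(values=values, valid=valid, convention=convention)


def phase_spectra(
    stack: SpectralImageStack,
    segmentation: np.ndarray | GpMap,
) -> tuple[SteadyStateSpectrum, SteadyStateSpectrum]:
    """Mean per-phase emission spectra of a two-phase stack.

    ``segmentation`` is either an integer label mask (0 = background, two
    positive labels = phases) or a :class:`GpMap`, in which case valid pixels
    are split at their median GP.  Returns ``(ordered, disordered)`` spectra,
    ordered phase (higher GP / bluer emission) first.
    """
    if isinstance(segmentation, GpMap):
        gp_vals = segmentation.values
        valid = segmentation.valid
        if not np.any(valid):
            raise DegenerateInputError("no valid pixels to segment")
        median = np.nanmedian(gp_vals[valid])
        labels = np.zeros(gp_vals.shape, dtype=int)
        labels[valid & (gp_vals >= median)] = 1
        labels[valid & (gp_vals < median)] = 2
    else:
        labels = np.asarray(segmentation)
        if labels.shape != stack.counts.shape[:2]:
            raise InvalidParameterError("segmentation shape does not match stack")

    phase_ids = sorted(int(v) for v in np.unique(labels) if v > 0)
    if len(phase_ids) < 2:
        raise DegenerateInputError("segmentation labels fewer than two phases")
    spectra = {}
    for pid in phase_ids[:2]:
        sel = labels == pid
        if not np.any(sel):
            raise DegenerateInputError(f"phase label {pid} has no pixels")
        spectra[pid] = stack.counts[sel].mean(axis=0)

    # ordered phase first: lower intensity-weighted mean wavelength = bluer
    def _mean_wavelength(vals):
        return float(np.sum(stack.channel_centers * vals) / np.sum(vals))

    first, second = sorted(spectra, key=lambda pid: _mean_wavelength(spectra[pid]))
    mean_a, mean_b = spectra[first], spectra[second]
    rel = np.linalg.norm(mean_a - mean_b) / max(np.linalg.norm(mean_a), 1e-12)
    if rel < 0.05:
        warnings.warn(
            "phase spectra are nearly identical; the stack may be single-phase",
            TdfspecWarning,
            stacklevel=2,
        )
    make = lambda vals: SteadyStateSpectrum(
        axis="wavelength", grid=stack.channel_centers, intensities=vals
    )
    return make(mean_a), make(mean_b)


#: Dielectric constant and Dimroth-Reichardt E_T(30) index per solvent.
_DEFAULT_POLARITY = {
    "water": (78.54, 63.1),
    "dmso": (47.0, 45.1),
    "ethanol": (24.6, 51.9),
    "chloroform": (4.81, 39.1),
}


@dataclass(frozen=True)
class PolarityTable:
    """Per-solvent polarity indices on two scales.

    The two scales rank solvents differently: the dielectric constant
    measures polarizability only, while the Dimroth-Reichardt index also
    rewards hydrogen-bonding (ionizing) power — DMSO outranks ethanol on the
    former, ethanol outranks DMSO on the latter.
    """

    entries: dict = field(
        default_factory=lambda: {k: v for k, v in _DEFAULT_POLARITY.items()}
    )

    def __post_init__(self):
        for solvent, (eps, et) in self.entries.items():
            if eps <= 0 or et <= 0:
                raise InvalidParameterError(
                    f"polarity indices for {solvent!r} must be positive"
                )

    def value(self, solvent: str, scale: str) -> float:
        key = solvent.lower()
        if key not in self.entries:
            raise InvalidParameterError(f"unknown solvent {solvent!r}")
        eps, et = self.entries[key]
        if scale == "dielectric":
            return float(eps)
        if scale == "dimroth_reichardt":
            return float(et)
        raise InvalidParameterError(f"unknown polarity scale {scale!r}")


def rank_polarity(
    table: PolarityTable,
    scale: str,
    solvents,
) -> list[list[str]]:
    """Solvents in descending polarity on the chosen scale.

    Returns a list of tie-groups: each inner list holds solvents sharing one
    index value, so ``[["dmso"], ["ethanol"], ["chloroform"]]`` is a strict
    ordering and ties surface as multi-element groups.
    """
    solvents = [s.lower() for s in solvents]
    values = {s: table.value(s, scale) for s in solvents}
    groups: list[list[str]] = []
    for solvent in sorted(solvents, key=lambda s: -values[s]):
        if groups and values[groups[-1][0]] == values[solvent]:
            groups[-1].append(solvent)
        else:
            groups.append([solvent])
    return groups
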