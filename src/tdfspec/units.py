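"""Wavelength/wavenumber conversions.

Convention used everywhere in the package: nu(cm^-1) = 1e7 / lambda(nm).
Spectral intensity densities transform with the Jacobian |d nu / d lambda|
so that the integrated signal is conserved:

    I_nu(nu) = lambda^2 * I_lambda(lambda) / 1e7
    I_lambda(lambda) = nu^2 * I_nu(nu) / 1e7
"""

from __future__ import annotations

import numpy as np

#: cm^-1 * nm
WAVENUMBER_PER_NM = 1.0e7


def nm_to_wavenumber(wavelength_nm):
    """Convert wavelength in nm to wavenumber in cm^-1."""
    wavelength_nm = np.asarray(wavelength_nm, dtype=float)
    return WAVENUMBER_PER_NM / wavelength_nm


def wavenumber_to_nm(wavenumber_cm1):
    """Convert wavenumber in cm^-1 to wavelength in nm."""
    wavenumber_cm1 = np.asarray(wavenumber_cm1, dtype=float)
    return WAVENUMBER_PER_NM / wavenumber_cm1


def intensity_to_wavenumber_form(wavelength_nm, intensity_per_nm):
    """Jacobian-convert a per-wavelength density to a per-wavenumber density."""
    lam = np.asarray(wavelength_nm, dtype=float)
    return np.asarray(intensity_per_nm, dtype=float) * lam**2 / WAVENUMBER_PER_NM


def intensity_to_wavelength_form(wavenumber_cm1, intensity_per_cm1):
    """Jacobian-convert a per-wavenumber density to a per-wavelength density."""
    nu = np.asarray(wavenumber_cm1, dtype=float)
    return np.asarray(intensity_per_cm1, dtype=float) * nu**2 / WAVENUMBER_PER_NM
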