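"""Shared fixtures and independent numeric oracles for the test suite."""

import numpy as np
import pytest

from tdfspec import make_irf
from tdfspec.synthdata import RelaxationTruth, WidthBump


def brute_force_fwhm(x, y):
    """Independent FWHM oracle: half-maximum crossings by linear
    interpolation on each side of the global maximum of a sampled profile.

    Deliberately re-implemented here (not imported from the package) so
    band-fit FWHM values are checked against an independent computation.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    k = int(np.argmax(y))
    half = y[k] / 2.0
    left = right = None
    for i in range(k, 0, -1):
        if y[i - 1] <= half <= y[i]:
            frac = (half - y[i - 1]) / (y[i] - y[i - 1])
            left = x[i - 1] + frac * (x[i] - x[i - 1])
            break
    for i in range(k, x.size - 1):
        if y[i + 1] <= half <= y[i]:
            frac = (y[i] - half) / (y[i] - y[i + 1])
            right = x[i] + frac * (x[i + 1] - x[i])
            break
    if left is None or right is None:
        raise ValueError("half maximum not bracketed")
    return abs(right - left)


@pytest.fixture
def fwhm_oracle():
    return brute_force_fwhm


@pytest.fixture
def fast_irf():
    """78 ps Gaussian IRF on a short 12 ns window (quick fits)."""
    return make_irf(78.0, 7.0, 12.0, 0.5)


@pytest.fixture
def laurdan_like_truth():
    """Single relaxation component, single width bump: laurdan-like."""
    return RelaxationTruth(
        nu_infinity=21000.0,
        delta_nu=3000.0,
        relaxation_components=((1.0, 1.0),),
        fluorescence_lifetimes=((0.4, 1.8), (0.6, 4.6)),
        width_baseline=3300.0,
        width_bumps=(WidthBump(1.0, 600.0, 0.3),),
    )


@pytest.fixture
def di4_like_truth():
    """Two slow width bumps: di-4-like heterogeneous relaxation."""
    return RelaxationTruth(
        nu_infinity=15500.0,
        delta_nu=1500.0,
        relaxation_components=((1.0, 0.8),),
        fluorescence_lifetimes=((0.5, 0.9), (0.5, 2.8)),
        width_baseline=2800.0,
        width_bumps=(WidthBump(0.7, 600.0, 0.3), WidthBump(4.1, 600.0, 0.3)),
    )
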