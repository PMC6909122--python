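"""Analytic beam-profile shapes shared by the kernel generator and the
plan generator's dwell-time flattening step."""

from __future__ import annotations

import math

import numpy as np
from scipy.special import erf

__all__ = ["erf_tophat", "NOMINAL_FWHM", "NOMINAL_SIGMA"]

#: Nominal full widths at half maximum (mm) per collimator.
NOMINAL_FWHM = {15: 22.0, 25: 35.0}
#: Nominal penumbra SD (mm).
NOMINAL_SIGMA = 3.0
#: Nominal exponential depth-attenuation coefficient (per mm).
NOMINAL_MU = 0.008
#: Nominal apex dose rate (Gy/min).
NOMINAL_RATE = 3.0


def erf_tophat(delta, fwhm: float, sigma: float):
    """Error-function-smoothed top-hat profile, unnormalized.

    ``0.5 * [erf((w/2 - d)/(sigma*sqrt(2))) + erf((w/2 + d)/(sigma*sqrt(2)))]``
    — a rectangle of width ``w`` convolved with a Gaussian penumbra of
    standard deviation ``sigma``. For ``w >> sigma`` the half-maximum width
    equals ``w``.
    """
    d = np.asarray(delta, dtype=float)
    s = sigma * math.sqrt(2.0)
    return 0.5 * (erf((fwhm / 2.0 - d) / s) + erf((fwhm / 2.0 + d) / s))
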