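"""Synthetic surrogates for the two calibration inputs.

Real runs calibrate the wavenumber axis against a solid Raman-shift standard
(4-acetaminophenol) and the intensity axis against a certified white lamp.
Neither raw measurement is distributable, so these fixtures construct both
from a known ground truth: a pixel-to-wavenumber polynomial and a smooth
instrument response curve.  Round-tripping the calibration operations on
these fixtures must recover the generating truth.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from ..errors import CalibrationError


@dataclass
class CalibrationFixtures:
    """Everything a calibration round-trip test needs."""

    pixel_axis: np.ndarray            # 0..n_pixels-1
    standard_intensities: np.ndarray  # Raman standard measured on the pixel axis
    peak_table: np.ndarray            # literature wavenumbers of the standard's bands
    true_wavenumbers: np.ndarray      # ground truth: polynomial evaluated on pixels
    wavenumber_axis: np.ndarray       # axis both lamp spectra live on
    measured_lamp: np.ndarray
    certified_lamp: np.ndarray
    response: np.ndarray              # measured = certified * response


def make_calibration_fixtures(
    pixel_to_wavenumber: Sequence[float],
    response_curve: Callable[[np.ndarray], np.ndarray] | None = None,
    n_pixels: int = 1024,
    peak_wavenumbers: Sequence[float] | None = None,
    peak_width_px: float = 2.0,
    rng: np.random.Generator | None = None,
) -> CalibrationFixtures:
    """Build surrogate standard + lamp spectra from known ground truth.

    ``pixel_to_wavenumber`` is a polynomial (constant coefficient first)
    that must be strictly increasing over ``0..n_pixels-1``.  The standard's
    bands are placed at the pixel positions mapping to ``peak_wavenumbers``
    under that polynomial; the measured lamp is the certified lamp times the
    response curve evaluated on the wavenumber axis.
    """
    rng = rng or np.random.default_rng(0)
    pixel_axis = np.arange(n_pixels, dtype=float)
    coeffs = np.asarray(pixel_to_wavenumber, dtype=float)
    true_wavenumbers = np.polynomial.polynomial.polyval(pixel_axis, coeffs)
    if not np.all(np.diff(true_wavenumbers) > 0):
        raise CalibrationError("pixel-to-wavenumber mapping must be strictly increasing")

    lo, hi = true_wavenumbers[0], true_wavenumbers[-1]
    if peak_wavenumbers is None:
        # spread 8 bands over the middle 90% of the covered range
        peak_wavenumbers = np.linspace(lo + 0.05 * (hi - lo), hi - 0.05 * (hi - lo), 8)
    peak_table = np.asarray(peak_wavenumbers, dtype=float)
    if peak_table.min() < lo or peak_table.max() > hi:
        raise CalibrationError("peak table extends beyond the mapped wavenumber range")

    # invert the monotone mapping numerically to place bands in pixel space
    peak_pixels = np.interp(peak_table, true_wavenumbers, pixel_axis)
    standard = np.zeros(n_pixels)
    for p in peak_pixels:
        amp = 0.6 + 0.8 * rng.random()
        standard += amp * np.exp(-0.5 * ((pixel_axis - p) / peak_width_px) ** 2)

    wavenumber_axis = true_wavenumbers.copy()
    # broad thermal-lamp-like certified emission
    mid = 0.5 * (lo + hi)
    certified = 0.3 + np.exp(-0.5 * ((wavenumber_axis - mid) / (0.45 * (hi - lo))) ** 2)
    if response_curve is None:
        response = np.ones_like(wavenumber_axis)
    else:
        response = np.asarray(response_curve(wavenumber_axis), dtype=float)
    measured = certified * response

    return CalibrationFixtures(
        pixel_axis=pixel_axis,
        standard_intensities=standard,
        peak_table=peak_table,
        true_wavenumbers=true_wavenumbers,
        wavenumber_axis=wavenumber_axis,
        measured_lamp=measured,
        certified_lamp=certified,
        response=response,
    )
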