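"""Wavenumber axis for fiber-probe Raman spectra.

The spectrometer records photon counts on CCD pixels; a polynomial
calibration maps pixel index to Raman shift (cm^-1).  The analysis keeps
only the biologically informative fingerprint window [800, 1750] cm^-1,
which on the instrument's grid (spacing 950/520 cm^-1, anchored so that
800 and 1750 cm^-1 fall exactly on pixels) is 521 spectral bins.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: Raman-shift spacing between adjacent pixels (cm^-1), ~1.83 cm^-1.
SPACING = 950.0 / 520.0

#: Full instrument range (cm^-1).
AXIS_MIN, AXIS_MAX = 400.0, 2000.0

#: Closed fingerprint window retained by truncation (cm^-1).
TRUNCATION_LOW, TRUNCATION_HIGH = 800.0, 1750.0

#: Number of bins in the closed interval [800, 1750] at SPACING.
N_TRUNCATED_BINS = 521

#: Numerical tolerance used when testing the closed truncation interval.
EDGE_TOL = 1e-6


@dataclass(frozen=True)
class WavenumberAxis:
    """A strictly increasing Raman-shift axis with pixel provenance.

    Parameters
    ----------
    values : ndarray
        Raman shift of each retained pixel (cm^-1), strictly increasing.
    pixels : ndarray
        CCD pixel index of each entry of ``values`` on the original frame.
    calibration : tuple of float
        Polynomial coefficients ``(c0, c1, ...)`` such that
        ``shift = c0 + c1 * pixel + c2 * pixel**2 + ...``.
    """

    values: np.ndarray
    pixels: np.ndarray
    calibration: tuple

    def __post_init__(self):
        values = np.asarray(self.values, dtype=float)
        pixels = np.asarray(self.pixels, dtype=int)
        if values.ndim != 1 or pixels.shape != values.shape:
            raise ValueError("axis values and pixels must be matching 1-D arrays")
        if values.size >= 2 and not np.all(np.diff(values) > 0):
            raise ValueError("wavenumber axis must be strictly increasing")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "pixels", pixels)
        object.__setattr__(self, "calibration", tuple(float(c) for c in self.calibration))

    @property
    def n_bins(self) -> int:
        return int(self.values.size)

    def truncation_mask(self, low: float = TRUNCATION_LOW, high: float = TRUNCATION_HIGH,
                        tol: float = EDGE_TOL) -> np.ndarray:
        """Boolean mask for the closed interval [low, high] (tol absorbs float error)."""
        return (self.values >= low - tol) & (self.values <= high + tol)

    def truncate(self, low: float = TRUNCATION_LOW, high: float = TRUNCATION_HIGH,
                 tol: float = EDGE_TOL) -> "WavenumberAxis":
        mask = self.truncation_mask(low, high, tol)
        if not mask.any():
            raise ValueError("truncation produced an empty axis")
        return WavenumberAxis(self.values[mask], self.pixels[mask], self.calibration)

    def with_calibration(self, coeffs) -> "WavenumberAxis":
        """Recompute shifts for the current pixels under new polynomial coefficients."""
        values = evaluate_calibration(coeffs, self.pixels)
        return WavenumberAxis(values, self.pixels, tuple(coeffs))


def evaluate_calibration(coeffs, pixels) -> np.ndarray:
    """Evaluate shift = c0 + c1*p + c2*p^2 + ... at the given pixel indices."""
    pixels = np.asarray(pixels, dtype=float)
    out = np.zeros_like(pixels)
    for power, c in enumerate(coeffs):
        out += c * pixels ** power
    return out


def factory_axis() -> WavenumberAxis:
    """The instrument's nominal (factory-calibrated) axis.

    Uniform spacing of 950/520 cm^-1, anchored so that 800 cm^-1 and
    1750 cm^-1 are exact grid points, spanning [400, 2000] cm^-1.  With
    this grid the closed-interval truncation to [800, 1750] retains
    exactly ``N_TRUNCATED_BINS`` bins.
    """
    k_low = int(np.floor((TRUNCATION_LOW - AXIS_MIN) / SPACING))   # pixels below 800
    k_high = int(np.floor((AXIS_MAX - TRUNCATION_LOW) / SPACING))  # pixels at/above 800
    pixels = np.arange(k_low + k_high + 1)
    c0 = TRUNCATION_LOW - k_low * SPACING
    values = c0 + SPACING * pixels
    return WavenumberAxis(values, pixels, (c0, SPACING))
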