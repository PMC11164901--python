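"""Nine-step conditioning of raw Raman acquisitions.

A raw acquisition (repeat CCD frames + dark frame) is converted into a
single normalized spectrum on the truncated, calibrated fingerprint
axis by, in order: (1) dark-count subtraction, (2) cosmic-ray removal
across repeat frames, (3) truncation to [800, 1750] cm^-1 (521 bins),
(4) pixel -> cm^-1 axis calibration from a reference standard,
(5) instrument-response correction, (6) averaging of the repeat
frames, (7) BubbleFill baseline removal (minimum bubble diameter
60 cm^-1), (8) Savitzky-Golay smoothing (order 3, window 11) and
(9) standard normal variate (SNV) normalization.

Truncation precedes calibration in the enumeration, so it is applied
on the instrument's nominal (factory) axis; after the calibration fit
the retained bins are re-checked against the window (with a half-bin
tolerance, since sub-0.1 cm^-1 calibration shifts must not evict the
exact boundary bins) and the 521-bin contract is asserted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import uniform_filter1d
from scipy.signal import find_peaks, savgol_filter

from .axis import (
    N_TRUNCATED_BINS,
    SPACING,
    TRUNCATION_HIGH,
    TRUNCATION_LOW,
    WavenumberAxis,
)
from .synthetic import CalibrationReferences, RawAcquisition

__all__ = [
    "Spectrum",
    "BaselineResult",
    "CalibrationFit",
    "subtract_dark",
    "remove_cosmic_rays",
    "truncate_spectrum",
    "fit_axis_calibration",
    "correct_instrument_response",
    "average_repeats",
    "bubblefill",
    "savgol_smooth",
    "snv",
    "snv_normalize",
    "preprocess_acquisition",
    "preprocess_cohort",
    "PreprocessingError",
]

STAGES = ("raw_mean", "calibrated", "baseline_removed", "smoothed", "snv")


class PreprocessingError(ValueError):
    """Raised when a conditioning stage's contract is violated."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")


@dataclass
class Spectrum:
    """A wavenumber-indexed intensity vector with a processing-stage tag."""

    axis: WavenumberAxis
    intensities: np.ndarray
    stage: str

    def __post_init__(self):
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.intensities.shape != self.axis.values.shape:
            raise ValueError("intensities and axis lengths differ")
        if self.stage not in STAGES:
            raise ValueError(f"unknown stage {self.stage!r}")

    @property
    def n_bins(self) -> int:
        return int(self.intensities.size)


@dataclass
class BaselineResult:
    """BubbleFill output: the smooth baseline and the Raman residual."""

    baseline: np.ndarray
    raman: np.ndarray
    min_bubble_width: float


@dataclass
class CalibrationFit:
    """Pixel -> cm^-1 polynomial fit through detected reference peaks."""

    axis: WavenumberAxis
    coefficients: tuple
    rms_residual: float
    matched: list          # (apparent pixel, known cm^-1) pairs


# ---------------------------------------------------------------------------
# steps 1, 2, 6: frame-level operations


def subtract_dark(frames: np.ndarray, dark_frame: np.ndarray) -> np.ndarray:
    """Step 1: subtract the laser-off background from every frame (no clipping)."""
    frames = np.atleast_2d(np.asarray(frames, dtype=float))
    dark_frame = np.asarray(dark_frame, dtype=float)
    if frames.shape[1] != dark_frame.size:
        raise PreprocessingError("dark", "frame and dark-frame lengths differ")
    return frames - dark_frame[None, :]


def remove_cosmic_rays(frames: np.ndarray, k: float = 8.0) -> np.ndarray:
    """Step 2: replace single-frame spikes with the across-repeat median.

    Cosmic-ray events are uncorrelated between the repeat frames, so a
    value deviating from the per-bin median of the repeats by more than
    ``k`` robust scales (1.4826 x MAD) is replaced by that median.  All
    other values pass through unchanged.
    """
    frames = np.atleast_2d(np.asarray(frames, dtype=float))
    if frames.shape[0] < 3:
        warnings.warn("fewer than 3 repeat frames; cosmic-ray removal skipped")
        return frames.copy()
    median = np.median(frames, axis=0)
    mad = np.median(np.abs(frames - median[None, :]), axis=0)
    scale = 1.4826 * mad
    spikes = np.abs(frames - median[None, :]) > k * scale[None, :]
    cleaned = frames.copy()
    cleaned[spikes] = np.broadcast_to(median[None, :], frames.shape)[spikes]
    return cleaned


def average_repeats(frames: np.ndarray) -> np.ndarray:
    """Step 6: arithmetic per-bin mean of the repeat frames."""
    frames = np.atleast_2d(np.asarray(frames, dtype=float))
    if frames.shape[0] < 1:
        raise PreprocessingError("average", "no frames to average")
    return frames.mean(axis=0)


# ---------------------------------------------------------------------------
# steps 3, 4, 5: axis and response


def truncate_spectrum(spectrum: Spectrum) -> Spectrum:
    """Step 3: keep bins in the closed interval [800, 1750] cm^-1."""
    mask = spectrum.axis.truncation_mask()
    if not mask.any():
        raise PreprocessingError("truncate", "no bins inside [800, 1750] cm^-1")
    return Spectrum(spectrum.axis.truncate(), spectrum.intensities[mask],
                    spectrum.stage)


def _refine_peak_position(y: np.ndarray, idx: int) -> float:
    """Sub-pixel apex via parabolic interpolation of the local maximum.

    Uses log intensities (exact for a Gaussian line shape on a uniform
    grid); falls back to a plain parabola when a neighbour is <= 0.
    """
    if idx <= 0 or idx >= y.size - 1:
        return float(idx)
    ym, y0, yp = y[idx - 1], y[idx], y[idx + 1]
    if min(ym, y0, yp) > 0:
        ym, y0, yp = np.log(ym), np.log(y0), np.log(yp)
    denom = ym - 2.0 * y0 + yp
    if denom >= 0:
        return float(idx)
    return float(idx + 0.5 * (ym - yp) / denom)


def fit_axis_calibration(references: CalibrationReferences,
                         degree: int = 1) -> CalibrationFit:
    """Step 4: least-squares pixel -> cm^-1 fit through reference peaks.

    Detects the strongest peaks of the wavenumber-standard spectrum,
    refines their apparent pixel positions by parabolic interpolation,
    pairs them in axis order with the declared known positions, and fits
    a degree-``degree`` polynomial (default linear).
    """
    y = np.asarray(references.wavenumber_reference, dtype=float)
    known = np.asarray(references.known_peak_positions, dtype=float)
    floor = y - np.median(y)
    idx, props = find_peaks(floor, prominence=0.1 * float(floor.max()))
    if idx.size < known.size:
        raise PreprocessingError(
            "calibrate", f"detected only {idx.size} reference peaks, "
            f"expected {known.size}")
    # keep the strongest len(known) peaks, then pair in axis order
    order = np.argsort(props["prominences"])[::-1][: known.size]
    idx = np.sort(idx[order])
    apparent = np.array([_refine_peak_position(floor, i) for i in idx])
    if apparent.size < 3:
        raise PreprocessingError("calibrate", "fewer than 3 matched peaks")
    coeffs = np.polynomial.polynomial.polyfit(apparent, np.sort(known), degree)
    fitted = np.polynomial.polynomial.polyval(apparent, coeffs)
    rms = float(np.sqrt(np.mean((fitted - np.sort(known)) ** 2)))
    axis = references.axis.with_calibration(tuple(coeffs))
    return CalibrationFit(axis=axis, coefficients=tuple(coeffs),
                          rms_residual=rms, matched=list(zip(apparent, np.sort(known))))


def correct_instrument_response(intensities: np.ndarray,
                                measured_standard: np.ndarray,
                                known_curve: np.ndarray) -> np.ndarray:
    """Step 5: divide out the optical-chain response.

    The correction factor is (measured standard / known emission curve),
    normalized to unit mean so the overall count scale is preserved.
    """
    measured_standard = np.asarray(measured_standard, dtype=float)
    known_curve = np.asarray(known_curve, dtype=float)
    factor = measured_standard / known_curve
    if np.any(factor <= 0):
        raise PreprocessingError("response", "non-positive response estimate")
    factor = factor / factor.mean()
    return np.asarray(intensities, dtype=float) / factor


# ---------------------------------------------------------------------------
# step 7: BubbleFill baseline removal


def _grow_bubble(xn: np.ndarray, yn: np.ndarray, lo: int, hi: int,
                 alignment: str) -> tuple[np.ndarray, int]:
    """Raise one circular-arc bubble under yn[lo:hi+1]; return (arc, touch index).

    The bubble is a circle in the unit-square normalized frame whose
    chord spans the segment; segments abutting the spectrum edge use a
    half-bubble anchored at the edge so the baseline can rise there.
    """
    x = xn[lo:hi + 1]
    y = yn[lo:hi + 1]
    width = x[-1] - x[0]
    if alignment == "left":
        center, radius = x[0], width
    elif alignment == "right":
        center, radius = x[-1], width
    else:
        center, radius = 0.5 * (x[0] + x[-1]), 0.5 * width
    arc = np.sqrt(np.maximum(radius ** 2 - (x - center) ** 2, 0.0))
    lift = y - arc
    touch = int(np.argmin(lift))          # leftmost minimiser: deterministic tie-break
    return arc + lift[touch], lo + touch


def bubblefill(intensities: np.ndarray, axis_values: np.ndarray,
               min_bubble_width: float = 60.0,
               smooth: bool = True) -> BaselineResult:
    """Step 7: BubbleFill baseline estimation.

    Iteratively grows circular-arc "bubbles" beneath the y-range
    normalized spectrum: the first bubble spans the whole axis; each
    bubble is raised until it first touches the spectrum, the segment is
    split at the touch point, and the procedure recurses on both sides
    until a segment is narrower than ``min_bubble_width`` (cm^-1).  The
    assembled baseline is lightly smoothed with a moving average of one
    bubble width and clipped to never exceed the spectrum.
    """
    y = np.asarray(intensities, dtype=float)
    x = np.asarray(axis_values, dtype=float)
    if not np.all(np.isfinite(y)):
        raise PreprocessingError("baseline", "non-finite intensities")
    if y.size != x.size:
        raise PreprocessingError("baseline", "axis and intensity lengths differ")
    spacing = float(np.median(np.diff(x))) if x.size > 1 else 1.0
    if min_bubble_width <= spacing:
        raise PreprocessingError(
            "baseline", "min_bubble_width must exceed the axis spacing")

    y_range = float(y.max() - y.min())
    if y_range < 1e-12:                    # featureless: baseline is the spectrum
        return BaselineResult(baseline=y.copy(), raman=np.zeros_like(y),
                              min_bubble_width=min_bubble_width)
    yn = (y - y.min()) / y_range
    xn = (x - x[0]) / (x[-1] - x[0])
    n = y.size

    baseline_n = np.full(n, -np.inf)
    stack = [(0, n - 1)]
    while stack:
        lo, hi = stack.pop()
        if hi - lo < 1:
            continue
        left_edge, right_edge = lo == 0, hi == n - 1
        # interior segments stop at the minimum bubble width; segments
        # abutting a spectrum edge are always grown so the baseline
        # meets the spectrum at both ends instead of leaving an
        # unfitted edge lobe
        if not (left_edge or right_edge) and x[hi] - x[lo] < min_bubble_width:
            continue
        alignments = ["center"]
        if left_edge and not right_edge:
            alignments.append("left")    # half-bubble anchored at the edge
        if right_edge and not left_edge:
            alignments.append("right")
        seg = slice(lo, hi + 1)
        touches = set()
        for alignment in alignments:
            arc, touch = _grow_bubble(xn, yn, lo, hi, alignment)
            baseline_n[seg] = np.maximum(baseline_n[seg], arc)
            touches.add(touch)
        if touches <= {lo, hi}:
            # every arc touched at a segment end: re-grow anchored at the
            # far end so monotone segments still subdivide
            for touch in sorted(touches):
                alignment = "right" if touch == lo else "left"
                arc, touch2 = _grow_bubble(xn, yn, lo, hi, alignment)
                baseline_n[seg] = np.maximum(baseline_n[seg], arc)
                touches.add(touch2)
        points = sorted({lo, hi} | touches)
        for clo, chi in zip(points, points[1:]):
            if chi - clo < 1 or (clo == lo and chi == hi):
                continue
            stack.append((clo, chi))

    baseline = baseline_n * y_range + y.min()
    if smooth:
        window = max(3, int(round(min_bubble_width / spacing)))
        baseline = uniform_filter1d(baseline, size=window, mode="nearest")
    baseline = np.minimum(baseline, y)     # contract: baseline <= spectrum
    return BaselineResult(baseline=baseline, raman=y - baseline,
                          min_bubble_width=min_bubble_width)


# ---------------------------------------------------------------------------
# steps 8, 9: smoothing and normalization


def savgol_smooth(intensities: np.ndarray, window: int = 11,
                  polyorder: int = 3) -> np.ndarray:
    """Step 8: Savitzky-Golay smoothing (order 3, window 11, poly-fit edges)."""
    intensities = np.asarray(intensities, dtype=float)
    if intensities.size < window:
        raise PreprocessingError("smooth", "spectrum shorter than the filter window")
    return savgol_filter(intensities, window_length=window, polyorder=polyorder,
                         mode="interp")


def snv(intensities: np.ndarray) -> np.ndarray:
    """Step 9: standard normal variate — subtract the mean, divide by the
    population (divide-by-n) standard deviation."""
    intensities = np.asarray(intensities, dtype=float)
    sd = intensities.std()                 # ddof=0: population convention
    if sd < 1e-15:
        raise PreprocessingError("snv", "zero dispersion; SNV undefined")
    return (intensities - intensities.mean()) / sd


def snv_normalize(spectrum: Spectrum) -> Spectrum:
    return Spectrum(spectrum.axis, snv(spectrum.intensities), "snv")


# ---------------------------------------------------------------------------
# the full chain


def preprocess_acquisition(acquisition: RawAcquisition,
                           references: CalibrationReferences,
                           min_bubble_width: float = 60.0,
                           calibration: CalibrationFit | None = None,
                           return_stages: bool = False):
    """Run the full nine-step chain on one acquisition.

    Returns the final SNV :class:`Spectrum` (length 521), or, with
    ``return_stages=True``, a dict of every intermediate stage.

    ``calibration`` may be passed in to reuse one axis fit across a
    cohort (the references are shared, so the fit is identical).
    """
    frames = subtract_dark(acquisition.frames, acquisition.dark_frame)
    frames = remove_cosmic_rays(frames)

    # step 3 on the factory axis; steps 4-5 refine the axis and response
    provisional = references.axis
    mask = provisional.truncation_mask()
    frames = frames[:, mask]

    if calibration is None:
        calibration = fit_axis_calibration(references)
    # re-check the window under the fitted axis (half-bin tolerance so
    # sub-0.1 cm^-1 calibration shifts cannot evict the boundary bins)
    pixels = provisional.pixels[mask]
    calibrated = calibration.axis.values[pixels]
    keep = ((calibrated >= TRUNCATION_LOW - SPACING / 2.0)
            & (calibrated <= TRUNCATION_HIGH + SPACING / 2.0))
    frames = frames[:, keep]
    axis = WavenumberAxis(calibrated[keep], pixels[keep],
                          calibration.coefficients)
    if axis.n_bins != N_TRUNCATED_BINS:
        raise PreprocessingError(
            "truncate", f"expected {N_TRUNCATED_BINS} bins after calibration, "
            f"got {axis.n_bins}")

    measured = references.response_reference[acquisition.site][mask]
    known = references.response_known_curve[mask]
    frames = correct_instrument_response(frames, measured, known)

    mean_spectrum = Spectrum(axis, average_repeats(frames), "raw_mean")
    base = bubblefill(mean_spectrum.intensities, axis.values, min_bubble_width)
    baseline_removed = Spectrum(axis, base.raman, "baseline_removed")
    smoothed = Spectrum(axis, savgol_smooth(base.raman), "smoothed")
    final = Spectrum(axis, snv(smoothed.intensities), "snv")

    if return_stages:
        return {"raw_mean": mean_spectrum, "baseline": base,
                "baseline_removed": baseline_removed, "smoothed": smoothed,
                "snv": final}
    return final


def preprocess_cohort(cohort, min_bubble_width: float = 60.0) -> dict:
    """Preprocess every acquisition of a cohort; returns location_id -> Spectrum."""
    calibration = fit_axis_calibration(cohort.references)
    out = {}
    for acq in cohort.acquisitions:
        out[acq.location_id] = preprocess_acquisition(
            acq, cohort.references, min_bubble_width=min_bubble_width,
            calibration=calibration)
    return out
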