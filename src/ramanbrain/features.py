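"""Spectral feature engineering for tissue classification.

Features per measurement are (a) the SNV intensity of every retained
spectral bin ("band features") and (b) the height and width of up to 11
Gaussian-fitted peaks shared across the dataset ("peak features", up to
22 columns).  Peaks are detected with a prominence threshold of 0.1 and
a height threshold of 0.5 above the spectrum minimum (SNV units),
fitted with a local Gaussian, clustered across measurements within
+/- 2 cm^-1, and retained only when present in at least half of all
measurements.  The 1500-1620 cm^-1 region is excluded from band and
peak features because haemoglobin contributions there confound the
tissue signal.  Dimensionality is then reduced by ranking band and peak
columns separately with the impurity importances of a 200-tree random
forest fit on training data only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit
from scipy.signal import find_peaks, peak_widths
from sklearn.ensemble import RandomForestClassifier

from .preprocess import Spectrum

__all__ = [
    "PeakDetectionConfig",
    "PeakFeature",
    "ConsensusPeakSet",
    "fit_peaks",
    "consensus_peaks",
    "build_feature_matrix",
    "rank_features",
    "select_features",
    "band_columns",
    "peak_columns",
    "HAEMOGLOBIN_REGION",
]

#: Wavenumber window excluded from features (haemoglobin bands), cm^-1.
HAEMOGLOBIN_REGION = (1500.0, 1620.0)

GAUSS_FWHM = 2.0 * np.sqrt(2.0 * np.log(2.0))   # FWHM = 2.3548 * sigma


@dataclass(frozen=True)
class PeakDetectionConfig:
    """Detection and consensus thresholds (SNV units / cm^-1)."""

    prominence_min: float = 0.1
    height_min: float = 0.5          # relative to the spectrum minimum
    position_tolerance: float = 2.0  # cm^-1
    consensus_fraction: float = 0.5
    max_peaks: int = 11

    def __post_init__(self):
        if min(self.prominence_min, self.height_min,
               self.position_tolerance) <= 0:
            raise ValueError("peak thresholds must be positive")
        if not 0.0 < self.consensus_fraction <= 1.0:
            raise ValueError("consensus_fraction must lie in (0, 1]")


@dataclass(frozen=True)
class PeakFeature:
    """One fitted peak: position (cm^-1), height (SNV units), FWHM (cm^-1)."""

    position: float
    height: float
    width: float


@dataclass
class ConsensusPeakSet:
    """Peaks present in >= consensus_fraction of all measurements."""

    positions: list          # canonical positions (cluster medians), cm^-1
    median_widths: list      # per-cluster median FWHM, cm^-1
    occurrence: list         # number of measurements carrying the peak
    n_measurements: int


def _gaussian_offset(x, amplitude, center, sigma, offset):
    return amplitude * np.exp(-0.5 * ((x - center) / sigma) ** 2) + offset


def fit_peaks(spectrum, config: PeakDetectionConfig | None = None,
              axis_values=None) -> list:
    """Detect and Gaussian-fit the peaks of one SNV spectrum.

    Local maxima passing the prominence and relative-height thresholds
    are each fitted with a Gaussian plus constant offset over a window
    of +/- 3 initial width estimates; fits that do not converge fall
    back to the apparent position, height and FWHM.
    """
    config = config or PeakDetectionConfig()
    if isinstance(spectrum, Spectrum):
        y = spectrum.intensities
        x = spectrum.axis.values
    else:
        y = np.asarray(spectrum, dtype=float)
        x = np.asarray(axis_values, dtype=float)

    height_floor = float(y.min()) + config.height_min
    idx, _ = find_peaks(y, prominence=config.prominence_min,
                        height=height_floor)
    if idx.size == 0:
        return []

    widths_bins = peak_widths(y, idx, rel_height=0.5)[0]
    spacing = float(np.median(np.diff(x)))
    out = []
    for i, w_bins in zip(idx, widths_bins):
        fwhm0 = max(w_bins, 2.0) * spacing
        sigma0 = fwhm0 / GAUSS_FWHM
        half = max(int(round(3.0 * sigma0 / spacing)), 3)
        lo, hi = max(0, i - half), min(y.size, i + half + 1)
        xw, yw = x[lo:hi], y[lo:hi]
        apparent_height = float(y[i] - y.min())
        try:
            popt, _ = curve_fit(
                _gaussian_offset, xw, yw,
                p0=[apparent_height, x[i], sigma0, float(yw.min())],
                bounds=([0.0, xw[0], 0.1 * spacing, -np.inf],
                        [np.inf, xw[-1], (xw[-1] - xw[0]), np.inf]),
                maxfev=2000)
            amplitude, center, sigma = popt[0], popt[1], abs(popt[2])
            out.append(PeakFeature(position=float(center),
                                   height=float(amplitude),
                                   width=float(GAUSS_FWHM * sigma)))
        except RuntimeError:
            out.append(PeakFeature(position=float(x[i]),
                                   height=apparent_height,
                                   width=float(fwhm0)))
    return out


def consensus_peaks(peaks_per_measurement: list,
                    config: PeakDetectionConfig | None = None) -> ConsensusPeakSet:
    """Cluster fitted peaks across measurements and keep the consensus set.

    Peaks are clustered by position: sorted positions start a new
    cluster whenever they fall more than the position tolerance from
    the running cluster median.  Clusters present in at least
    ``consensus_fraction`` of all measurements (>= convention at the
    boundary) are retained, capped at ``max_peaks`` by descending
    occurrence; the canonical position is the cluster median.
    """
    config = config or PeakDetectionConfig()
    n = len(peaks_per_measurement)
    if n < 1:
        raise ValueError("need at least one measurement")

    records = []          # (position, width, measurement index)
    for m, peaks in enumerate(peaks_per_measurement):
        for p in peaks:
            records.append((p.position, p.width, m))
    if not records:
        return ConsensusPeakSet([], [], [], n)

    records.sort(key=lambda r: r[0])
    clusters = []
    current = [records[0]]
    for rec in records[1:]:
        if rec[0] - float(np.median([r[0] for r in current])) <= config.position_tolerance:
            current.append(rec)
        else:
            clusters.append(current)
            current = [rec]
    clusters.append(current)

    kept = []
    for cluster in clusters:
        measurements = {r[2] for r in cluster}
        if len(measurements) / n >= config.consensus_fraction:
            kept.append((
                float(np.median([r[0] for r in cluster])),
                float(np.median([r[1] for r in cluster])),
                len(measurements)))
    kept.sort(key=lambda c: (-c[2], c[0]))
    kept = kept[: config.max_peaks]
    kept.sort(key=lambda c: c[0])
    return ConsensusPeakSet(
        positions=[c[0] for c in kept],
        median_widths=[c[1] for c in kept],
        occurrence=[c[2] for c in kept],
        n_measurements=n)


def _excluded(position: float) -> bool:
    lo, hi = HAEMOGLOBIN_REGION
    return lo <= position <= hi


def build_feature_matrix(spectra: dict, peaks: dict,
                         consensus: ConsensusPeakSet,
                         config: PeakDetectionConfig | None = None) -> pd.DataFrame:
    """Assemble the per-measurement feature matrix.

    ``spectra`` maps measurement id -> SNV Spectrum; ``peaks`` maps the
    same ids -> the fitted peak list of that spectrum.  Band columns are
    the SNV intensities of every truncated-axis bin outside the
    haemoglobin exclusion window, labelled ``band_<cm-1>``.  For each
    consensus peak (outside the window) two columns are added,
    ``peak_<cm-1>_height`` and ``peak_<cm-1>_width``; a spectrum with no
    matching fitted peak within the position tolerance is imputed with
    height 0 and the consensus median width.
    """
    config = config or PeakDetectionConfig()
    ids = list(spectra.keys())
    first = spectra[ids[0]]
    axis_values = first.axis.values
    band_mask = ~np.array([_excluded(v) for v in axis_values])
    band_cols = [f"band_{v:.1f}" for v in axis_values[band_mask]]

    consensus_kept = [
        (pos, wmed) for pos, wmed in
        zip(consensus.positions, consensus.median_widths) if not _excluded(pos)]

    rows = {}
    for mid in ids:
        spec = spectra[mid]
        row = dict(zip(band_cols, spec.intensities[band_mask]))
        fitted = peaks.get(mid, [])
        for pos, wmed in consensus_kept:
            match = None
            best_gap = config.position_tolerance
            for p in fitted:
                gap = abs(p.position - pos)
                if gap <= best_gap:
                    match, best_gap = p, gap
            stem = f"peak_{pos:.0f}"
            if match is None:
                row[f"{stem}_height"] = 0.0
                row[f"{stem}_width"] = wmed
            else:
                row[f"{stem}_height"] = match.height
                row[f"{stem}_width"] = match.width
        rows[mid] = row
    matrix = pd.DataFrame.from_dict(rows, orient="index")
    matrix.index.name = "measurement_id"
    return matrix


def band_columns(matrix: pd.DataFrame) -> list:
    return [c for c in matrix.columns if c.startswith("band_")]


def peak_columns(matrix: pd.DataFrame) -> list:
    return [c for c in matrix.columns if c.startswith("peak_")]


def rank_features(X: pd.DataFrame, y, seed: int = 0,
                  n_estimators: int = 200) -> tuple:
    """Rank band and peak columns by random-forest impurity importance.

    One 200-tree forest is fit on all columns; band and peak columns are
    then ranked separately by descending importance (deterministic under
    the seed).  Returns ``(ranked_band_columns, ranked_peak_columns)``.
    """
    forest = RandomForestClassifier(
        n_estimators=n_estimators, random_state=seed, n_jobs=1)
    forest.fit(X.to_numpy(), np.asarray(y))
    importance = pd.Series(forest.feature_importances_, index=X.columns)
    bands = importance[band_columns(X)].sort_values(
        ascending=False, kind="stable")
    peaks = importance[peak_columns(X)].sort_values(
        ascending=False, kind="stable")
    return list(bands.index), list(peaks.index)


def select_features(X: pd.DataFrame, y, n_band: int, n_peak: int,
                    seed: int = 0) -> list:
    """Keep the top ``n_band`` band and ``n_peak`` peak columns by forest
    importance (fit on the given data only — call with training rows)."""
    ranked_bands, ranked_peaks = rank_features(X, y, seed=seed)
    if n_band > len(ranked_bands) or n_peak > len(ranked_peaks):
        warnings.warn("feature quota exceeds available columns; clipping")
    return ranked_bands[:n_band] + ranked_peaks[:n_peak]
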