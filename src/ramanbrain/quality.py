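"""Spectral quality factor (QF) screening.

The QF of an SNV-normalized spectrum r with N bins is the average
signed squared intensity,

    QF = (1/N) * sum_i sgn(r_i) * r_i^2 ,

bounded in [-1, 1] because an SNV spectrum has mean 0 and population
variance 1 (so the mean of r^2 is exactly 1).  Pure noise gives QF
close to 0; spectra carrying genuine Raman peaks concentrate squared
intensity in positive excursions and give QF > 0.  Equivalently
QF = 1 - 2 * E-, where E- is the mean squared negative part.

The screening cutoff is chosen by evaluating the downstream classifier
by patient-grouped cross-validation on the spectra retained at each
candidate cutoff and keeping the cutoff with the best AUC among those
that do not unbalance the classes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .preprocess import Spectrum

__all__ = [
    "QualityRecord",
    "quality_factor",
    "compute_quality",
    "apply_qf_filter",
    "select_qf_threshold",
    "QF_PRESETS",
]

#: Study presets: QF cutoffs per pathology group.
QF_PRESETS = {"glioblastoma": 0.5, "metastasis": 0.5, "meningioma": 0.3}

#: Retained minority-class fraction below which a cutoff counts as
#: class-imbalancing (the balance bound of the cutoff search).
DEFAULT_BALANCE_MIN = 0.4


@dataclass
class QualityRecord:
    qf: float
    threshold: float
    passes: bool


def quality_factor(spectrum) -> float:
    """QF of an SNV spectrum: mean of sgn(r) * r^2, in [-1, 1]."""
    if isinstance(spectrum, Spectrum):
        if spectrum.stage != "snv":
            raise ValueError(
                f"quality factor is defined on stage 'snv', got {spectrum.stage!r}")
        r = spectrum.intensities
    else:
        r = np.asarray(spectrum, dtype=float)
        if abs(r.mean()) > 1e-6 or abs(r.std() - 1.0) > 1e-6:
            raise ValueError("input is not SNV-normalized (mean 0, population sd 1)")
    return float(np.mean(np.sign(r) * r ** 2))


def compute_quality(spectra: dict, threshold: float = 0.0) -> pd.DataFrame:
    """QF table for a mapping location_id -> SNV Spectrum."""
    rows = [{"location_id": loc, "qf": quality_factor(spec),
             "passes": quality_factor(spec) > threshold}
            for loc, spec in spectra.items()]
    return pd.DataFrame(rows)


def apply_qf_filter(dataset: pd.DataFrame, threshold: float) -> pd.DataFrame:
    """Retain rows with qf > threshold; attach rejection statistics.

    ``dataset`` must carry a ``qf`` column; a ``label`` column, when
    present, is used for the per-class retained counts.  The returned
    frame exposes ``attrs['rejection_fraction']`` and
    ``attrs['retained_by_class']``.
    """
    if "qf" not in dataset.columns:
        raise ValueError("dataset has no 'qf' column")
    kept = dataset[dataset["qf"] > threshold].copy()
    if kept.empty:
        raise ValueError(f"QF threshold {threshold} rejects every spectrum")
    kept.attrs["rejection_fraction"] = 1.0 - len(kept) / len(dataset)
    if "label" in dataset.columns:
        kept.attrs["retained_by_class"] = kept["label"].value_counts().to_dict()
    return kept


def _minority_fraction(labels: pd.Series) -> float:
    counts = labels.value_counts()
    if len(counts) < 2:
        return 0.0
    return float(counts.min() / counts.sum())


def select_qf_threshold(dataset: pd.DataFrame,
                        candidate_thresholds=None,
                        balance_min: float = DEFAULT_BALANCE_MIN,
                        seed: int = 0) -> tuple[float, pd.DataFrame]:
    """Choose the QF cutoff by cross-validated AUC under a balance bound.

    For each candidate cutoff the classification workflow is re-evaluated
    by patient-grouped five-fold cross-validation on the retained
    spectra (band-intensity linear SVM).  Among cutoffs whose retained
    minority-class fraction stays >= ``balance_min``, the one with the
    highest CV AUC is returned; ties go to the smaller cutoff.  If every
    cutoff violates the balance bound, 0 is returned with a warning.

    ``dataset`` needs columns ``qf``, ``label``, ``patient_id`` plus the
    band feature columns (prefix ``band_``).

    Returns ``(threshold, table)`` where ``table`` lists per-candidate
    AUC, retained counts and balance.
    """
    from .classify import cross_validated_auc   # deferred: avoids an import cycle

    if candidate_thresholds is None:
        candidate_thresholds = np.round(np.arange(0.0, 0.91, 0.1), 10)
    feature_cols = [c for c in dataset.columns if c.startswith("band_")]
    if not feature_cols:
        raise ValueError("dataset has no band feature columns")

    rows = []
    for cut in candidate_thresholds:
        kept = dataset[dataset["qf"] > cut]
        minority = _minority_fraction(kept["label"]) if len(kept) else 0.0
        balanced = minority >= balance_min and len(kept) >= 20
        auc = np.nan
        if balanced:
            auc = cross_validated_auc(
                kept[feature_cols].to_numpy(),
                (kept["label"] == "tumor").to_numpy(),
                kept["patient_id"].to_numpy(), seed=seed)
        rows.append({"threshold": float(cut), "n_retained": int(len(kept)),
                     "minority_fraction": minority, "balanced": balanced,
                     "cv_auc": auc})
    table = pd.DataFrame(rows)

    eligible = table[table["balanced"]]
    if eligible.empty:
        warnings.warn("every candidate QF cutoff unbalances the classes; "
                      "falling back to threshold 0")
        return 0.0, table
    # ties -> smaller cutoff: stable argmax over ascending thresholds
    best = eligible.loc[eligible["cv_auc"].idxmax()]
    return float(best["threshold"]), table
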