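"""Patient-grouped linear-SVM classification of tissue spectra.

The modelling surface follows the fit-then-results idiom: build a
:class:`RamanTissueClassifier` from a feature matrix with labels,
patient ids and sites, call :meth:`~RamanTissueClassifier.fit`, and
read estimates, holdout ROC metrics and a ``summary()`` table off the
returned :class:`RamanClassifierResults`.

Training protocol: a patient-grouped 80/20 split (every patient's
measurements are entirely in training or entirely in holdout, with the
holdout matching the training site mix), a grid search over the
feature-count and regularization hyperparameters (n_band in [5, 25],
n_peak in [2, 20], C in [0.01, 5]) scored by the total count of false
positives plus false negatives over five patient-grouped
cross-validation folds, feature selection re-run inside each fold so
the validation fold never informs it, a final class-weighted linear
SVM refit on the whole training set, and ROC evaluation on the
holdout.  Class weights follow the inverse class-frequency ratio.

The module also carries the study's power statistics: the exact
two-sample t-test sample-size computation (noncentral t) and Cohen's d.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_curve
from sklearn.svm import SVC

from .features import rank_features

__all__ = [
    "HyperParams",
    "HyperGrid",
    "SplitPlan",
    "TrainedModel",
    "EvaluationReport",
    "PowerSpec",
    "split_train_holdout",
    "patient_grouped_folds",
    "grid_search_cv",
    "train_final",
    "evaluate",
    "cross_validated_auc",
    "power_sample_size",
    "cohens_d",
    "RamanTissueClassifier",
    "RamanClassifierResults",
]


@dataclass(frozen=True)
class HyperParams:
    """Linear-SVM regularization C and the per-type feature quotas."""

    C: float
    n_band: int
    n_peak: int

    def __post_init__(self):
        if not 0.01 <= self.C <= 5.0:
            raise ValueError("C must lie in [0.01, 5]")
        if not 5 <= self.n_band <= 25:
            raise ValueError("n_band must lie in [5, 25]")
        if not 2 <= self.n_peak <= 20:
            raise ValueError("n_peak must lie in [2, 20]")

    @property
    def N(self) -> int:
        """Total feature count; ranges over [7, 45] on the default grid."""
        return self.n_band + self.n_peak


@dataclass(frozen=True)
class HyperGrid:
    C: tuple = (0.01, 0.05, 0.1, 0.5, 1.0, 2.0, 5.0)
    n_band: tuple = (5, 10, 15, 20, 25)
    n_peak: tuple = (2, 5, 10, 15, 20)

    def points(self):
        for nb in self.n_band:
            for npk in self.n_peak:
                for c in self.C:
                    yield HyperParams(C=c, n_band=nb, n_peak=npk)


@dataclass
class SplitPlan:
    """Patient-disjoint training / holdout assignment."""

    train_patients: list
    holdout_patients: list
    holdout_fraction_achieved: float
    site_mix_train: dict
    site_mix_holdout: dict

    def __post_init__(self):
        overlap = set(self.train_patients) & set(self.holdout_patients)
        if overlap:
            raise ValueError(f"patients in both partitions: {sorted(overlap)}")


@dataclass
class TrainedModel:
    """Selected features and the fitted class-weighted linear SVM."""

    selected_features: list
    weights: np.ndarray
    bias: float
    class_weights: dict
    params: HyperParams
    qf_threshold: float | None
    svm: SVC = field(repr=False, default=None)

    def decision_scores(self, X: pd.DataFrame) -> np.ndarray:
        return self.svm.decision_function(
            X[self.selected_features].to_numpy())


@dataclass
class EvaluationReport:
    """Holdout ROC metrics at the FP+FN-minimizing operating point."""

    auc: float
    accuracy: float
    sensitivity: float
    specificity: float
    roc_fpr: np.ndarray
    roc_tpr: np.ndarray
    threshold: float
    confusion: dict          # tp, fp, tn, fn

    def to_dict(self) -> dict:
        return {
            "auc": self.auc, "accuracy": self.accuracy,
            "sensitivity": self.sensitivity, "specificity": self.specificity,
            "operating_threshold": self.threshold,
            "confusion": dict(self.confusion),
            "roc": {"fpr": [float(v) for v in self.roc_fpr],
                    "tpr": [float(v) for v in self.roc_tpr]},
        }


@dataclass(frozen=True)
class PowerSpec:
    """Two-sample t-test design: effect size d, alpha, target power."""

    d: float
    alpha: float = 0.05
    power: float = 0.95
    tails: str = "two"

    def __post_init__(self):
        if self.d <= 0:
            raise ValueError("effect size d must be positive")
        if not (0 < self.alpha < 1 and 0 < self.power < 1):
            raise ValueError("alpha and power must lie in (0, 1)")
        if self.tails not in ("one", "two"):
            raise ValueError("tails must be 'one' or 'two'")


# ---------------------------------------------------------------------------
# splitting


def split_train_holdout(meta: pd.DataFrame, holdout_fraction: float = 0.2,
                        seed: int = 0) -> SplitPlan:
    """Greedy patient-level 80/20 split, site-proportional.

    ``meta`` needs one row per measurement with columns ``patient_id``
    and ``site``.  Within each site, patients are shuffled (seeded) and
    moved to the holdout while doing so brings the holdout measurement
    share closer to ``holdout_fraction``.  Deterministic per seed.
    """
    rng = np.random.default_rng(seed)
    holdout: list = []
    train: list = []
    for site, grp in meta.groupby("site", sort=True):
        counts = grp.groupby("patient_id").size()
        patients = list(counts.index)
        rng.shuffle(patients)
        total = counts.sum()
        target = holdout_fraction * total
        held = 0
        for p in patients:
            c = counts[p]
            if abs(held + c - target) < abs(held - target):
                holdout.append(p)
                held += c
            else:
                train.append(p)
        site_holdout = [p for p in holdout if p in counts.index]
        if not site_holdout and len(patients) >= 2:
            warnings.warn(f"site {site}: no patient fit the holdout target; "
                          "forcing the smallest patient into the holdout")
            smallest = counts.idxmin()
            train.remove(smallest)
            holdout.append(smallest)

    n_holdout = meta["patient_id"].isin(holdout).sum()
    mix = {}
    for part, pats in (("train", train), ("holdout", holdout)):
        sub = meta[meta["patient_id"].isin(pats)]
        mix[part] = (sub["site"].value_counts(normalize=True).to_dict()
                     if len(sub) else {})
    return SplitPlan(
        train_patients=sorted(train), holdout_patients=sorted(holdout),
        holdout_fraction_achieved=float(n_holdout / len(meta)),
        site_mix_train=mix["train"], site_mix_holdout=mix["holdout"])


def patient_grouped_folds(patients, labels, n_folds: int = 5,
                          seed: int = 0) -> list:
    """Assign patients to folds by seeded greedy size balancing.

    Returns a list of ``n_folds`` boolean masks over measurements; every
    patient's measurements land in exactly one fold.  If some fold's
    validation part ends up single-class the folds are re-drawn once
    with a derived seed, then the function fails.
    """
    patients = np.asarray(patients)
    labels = np.asarray(labels)

    def draw(s):
        rng = np.random.default_rng(s)
        unique, counts = np.unique(patients, return_counts=True)
        order = rng.permutation(len(unique))
        fold_of = {}
        fold_sizes = np.zeros(n_folds)
        for i in order:
            f = int(np.argmin(fold_sizes))
            fold_of[unique[i]] = f
            fold_sizes[f] += counts[i]
        return [np.array([fold_of[p] == f for p in patients])
                for f in range(n_folds)]

    for attempt, s in enumerate((seed, seed + 7919)):
        masks = draw(s)
        if all(len(np.unique(labels[m])) == 2 for m in masks if m.any()):
            return masks
        if attempt == 0:
            warnings.warn("single-class validation fold; re-drawing folds once")
    raise ValueError("could not form five patient-grouped folds with both "
                     "classes in every validation fold")


# ---------------------------------------------------------------------------
# grid search, final fit, evaluation


def _fit_svm(X: np.ndarray, y: np.ndarray, C: float) -> SVC:
    svm = SVC(kernel="linear", C=C, class_weight="balanced")
    svm.fit(X, y)
    return svm


def grid_search_cv(X: pd.DataFrame, y, patients, grid: HyperGrid | None = None,
                   n_folds: int = 5, seed: int = 0):
    """Five-fold patient-grouped grid search minimizing FP + FN.

    For each fold, band and peak columns are ranked by forest importance
    on the four training folds only; each grid point then keeps its
    quotas, fits a class-weighted linear SVM and counts false positives
    plus false negatives on the validation fold.  Counts are summed over
    folds and the argmin returned — ties break to smaller N, then
    smaller C.

    Returns ``(best HyperParams, cv table DataFrame)``.
    """
    grid = grid or HyperGrid()
    y = np.asarray(y, dtype=bool)
    folds = patient_grouped_folds(patients, y, n_folds=n_folds, seed=seed)

    per_fold_rankings = []
    for f, val_mask in enumerate(folds):
        if not val_mask.any():
            per_fold_rankings.append(None)
            continue
        train_mask = ~val_mask
        per_fold_rankings.append(rank_features(
            X[train_mask], y[train_mask], seed=seed + f))

    records = []
    for hp in grid.points():
        errors = 0
        for ranking, val_mask in zip(per_fold_rankings, folds):
            if ranking is None:          # fewer patients than folds
                continue
            ranked_bands, ranked_peaks = ranking
            cols = ranked_bands[:hp.n_band] + ranked_peaks[:hp.n_peak]
            train_mask = ~val_mask
            svm = _fit_svm(X.loc[train_mask, cols].to_numpy(),
                           y[train_mask], hp.C)
            pred = svm.predict(X.loc[val_mask, cols].to_numpy())
            errors += int(np.sum(pred != y[val_mask]))
        records.append({"C": hp.C, "n_band": hp.n_band, "n_peak": hp.n_peak,
                        "N": hp.N, "fp_plus_fn": errors})
    table = pd.DataFrame(records)
    best_row = table.sort_values(
        ["fp_plus_fn", "N", "C"], kind="stable").iloc[0]
    best = HyperParams(C=float(best_row["C"]), n_band=int(best_row["n_band"]),
                       n_peak=int(best_row["n_peak"]))
    return best, table


def train_final(X: pd.DataFrame, y, params: HyperParams, seed: int = 0,
                qf_threshold: float | None = None) -> TrainedModel:
    """Refit feature selection and the linear SVM on the full training set."""
    y = np.asarray(y, dtype=bool)
    ranked_bands, ranked_peaks = rank_features(X, y, seed=seed)
    cols = ranked_bands[:params.n_band] + ranked_peaks[:params.n_peak]
    svm = _fit_svm(X[cols].to_numpy(), y, params.C)
    n_pos, n_neg = int(y.sum()), int((~y).sum())
    n = n_pos + n_neg
    class_weights = {"tumor": n / (2.0 * n_pos), "brain": n / (2.0 * n_neg)}
    return TrainedModel(
        selected_features=cols,
        weights=svm.coef_.ravel().copy(),
        bias=float(svm.intercept_[0]),
        class_weights=class_weights,
        params=params, qf_threshold=qf_threshold, svm=svm)


def roc_report(scores: np.ndarray, y: np.ndarray) -> EvaluationReport:
    """ROC analysis of decision scores against binary labels.

    AUC is the trapezoidal area under the ROC points.  The operating
    point minimizes FP + FN over the ROC thresholds; ties go to the
    point with higher sensitivity.
    """
    y = np.asarray(y, dtype=bool)
    if len(np.unique(y)) < 2:
        raise ValueError("ROC analysis needs both classes in the holdout")
    fpr, tpr, thresholds = roc_curve(y, scores)
    auc = float(np.trapezoid(tpr, fpr))

    n_pos, n_neg = int(y.sum()), int((~y).sum())
    fp = fpr * n_neg
    fn = (1.0 - tpr) * n_pos
    total_err = fp + fn
    best = np.lexsort((-tpr, total_err))[0]
    thr = float(thresholds[best])

    pred = scores >= thr
    tp = int(np.sum(pred & y))
    tn = int(np.sum(~pred & ~y))
    fp_n = int(np.sum(pred & ~y))
    fn_n = int(np.sum(~pred & y))
    return EvaluationReport(
        auc=auc,
        accuracy=(tp + tn) / y.size,
        sensitivity=tp / (tp + fn_n) if tp + fn_n else float("nan"),
        specificity=tn / (tn + fp_n) if tn + fp_n else float("nan"),
        roc_fpr=fpr, roc_tpr=tpr, threshold=thr,
        confusion={"tp": tp, "fp": fp_n, "tn": tn, "fn": fn_n})


def evaluate(model: TrainedModel, X: pd.DataFrame, y) -> EvaluationReport:
    """Apply a trained model to the holdout set and report ROC metrics."""
    return roc_report(model.decision_scores(X), np.asarray(y, dtype=bool))


def cross_validated_auc(X, y, patients, C: float = 1.0, n_folds: int = 5,
                        seed: int = 0) -> float:
    """Patient-grouped CV AUC of a fixed-C linear SVM (pooled scores).

    Lightweight diagnostic used by the QF-cutoff search and negative
    controls; no feature selection or hyperparameter tuning.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=bool)
    folds = patient_grouped_folds(patients, y, n_folds=n_folds, seed=seed)
    scores = np.empty(y.size)
    for val_mask in folds:
        if not val_mask.any():
            continue
        svm = _fit_svm(X[~val_mask], y[~val_mask], C)
        scores[val_mask] = svm.decision_function(X[val_mask])
    fpr, tpr, _ = roc_curve(y, scores)
    return float(np.trapezoid(tpr, fpr))


# ---------------------------------------------------------------------------
# power statistics


def _achieved_power(n: int, spec: PowerSpec) -> float:
    df = 2 * n - 2
    nc = spec.d * np.sqrt(n / 2.0)
    if spec.tails == "two":
        crit = stats.t.ppf(1.0 - spec.alpha / 2.0, df)
        return float(1.0 - stats.nct.cdf(crit, df, nc)
                     + stats.nct.cdf(-crit, df, nc))
    crit = stats.t.ppf(1.0 - spec.alpha, df)
    return float(1.0 - stats.nct.cdf(crit, df, nc))


def power_sample_size(spec: PowerSpec) -> int:
    """Smallest per-group n for which the two-sample t-test reaches the
    target power, by noncentral-t iteration from the normal start.

    The normal-approximation start is
    ``n0 = 2 ((z_{1-a} + z_{power}) / d)^2``; n is then decreased while
    power still holds and increased until it does, so the returned n is
    exact. Floor of 2 per group.
    """
    z_a = stats.norm.ppf(1.0 - (spec.alpha / 2.0 if spec.tails == "two"
                                else spec.alpha))
    z_b = stats.norm.ppf(spec.power)
    n = max(2, int(np.ceil(2.0 * ((z_a + z_b) / spec.d) ** 2)))
    while n > 2 and _achieved_power(n - 1, spec) >= spec.power:
        n -= 1
    while _achieved_power(n, spec) < spec.power:
        n += 1
    return n


def cohens_d(group_a, group_b) -> float:
    """|mean difference| over the pooled standard deviation."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 values")
    pooled = np.sqrt(((a.size - 1) * a.var(ddof=1)
                      + (b.size - 1) * b.var(ddof=1))
                     / (a.size + b.size - 2))
    if pooled == 0:
        if a.mean() == b.mean():
            return 0.0
        raise ValueError("zero pooled standard deviation")
    return float(abs(a.mean() - b.mean()) / pooled)


# ---------------------------------------------------------------------------
# model / results surface


class RamanTissueClassifier:
    """Tumor-versus-brain classifier over a spectral feature matrix.

    Parameters
    ----------
    features : DataFrame
        Feature matrix (band and peak columns) indexed by measurement id.
    labels : array-like of str
        "tumor" or "brain" per measurement.
    patients : array-like of str
        Patient id per measurement (grouping unit for all splits).
    sites : array-like of str, optional
        Acquisition site per measurement; a single pseudo-site is
        assumed when omitted.
    name : str
        Model name used in the summary (e.g. the pathology).
    """

    def __init__(self, features: pd.DataFrame, labels, patients, sites=None,
                 name: str = "tumor-vs-brain", qf_threshold: float | None = None):
        n = len(features)
        labels = np.asarray(labels)
        patients = np.asarray(patients)
        if labels.size != n or patients.size != n:
            raise ValueError("labels/patients length must match the matrix")
        bad = set(np.unique(labels)) - {"tumor", "brain"}
        if bad:
            raise ValueError(f"unknown labels: {sorted(bad)}")
        self.features = features
        self.labels = labels
        self.patients = patients
        self.sites = (np.asarray(sites) if sites is not None
                      else np.full(n, "site-0"))
        self.name = name
        self.qf_threshold = qf_threshold

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, label_col: str = "label",
                       patient_col: str = "patient_id", site_col: str = "site",
                       name: str = "tumor-vs-brain",
                       qf_threshold: float | None = None):
        """Build from one DataFrame holding features plus metadata columns."""
        feature_cols = [c for c in df.columns
                        if c.startswith("band_") or c.startswith("peak_")]
        sites = df[site_col].to_numpy() if site_col in df.columns else None
        return cls(df[feature_cols], df[label_col].to_numpy(),
                   df[patient_col].to_numpy(), sites=sites, name=name,
                   qf_threshold=qf_threshold)

    def fit(self, grid: HyperGrid | None = None,
            holdout_fraction: float = 0.2, seed: int = 0):
        """Run the full protocol; returns :class:`RamanClassifierResults`."""
        meta = pd.DataFrame({"patient_id": self.patients, "site": self.sites})
        split = split_train_holdout(meta, holdout_fraction, seed=seed)
        train_mask = np.isin(self.patients, split.train_patients)
        hold_mask = np.isin(self.patients, split.holdout_patients)
        if not train_mask.any() or not hold_mask.any():
            raise ValueError("split produced an empty partition")

        y = self.labels == "tumor"
        X_train = self.features[train_mask]
        best, cv_table = grid_search_cv(
            X_train, y[train_mask], self.patients[train_mask],
            grid=grid, seed=seed)
        model = train_final(X_train, y[train_mask], best, seed=seed,
                            qf_threshold=self.qf_threshold)
        report = evaluate(model, self.features[hold_mask], y[hold_mask])
        return RamanClassifierResults(
            name=self.name, model=model, report=report, split=split,
            cv_table=cv_table, n_train=int(train_mask.sum()),
            n_holdout=int(hold_mask.sum()), seed=seed)


@dataclass
class RamanClassifierResults:
    """Fit results: the trained model, its holdout ROC report and diagnostics."""

    name: str
    model: TrainedModel
    report: EvaluationReport
    split: SplitPlan
    cv_table: pd.DataFrame
    n_train: int
    n_holdout: int
    seed: int

    def summary(self) -> str:
        p = self.model.params
        r = self.report
        lines = [
            f"Raman tissue classifier — {self.name}",
            "=" * 58,
            f"{'Training measurements':<34}{self.n_train:>8d}",
            f"{'Holdout measurements':<34}{self.n_holdout:>8d}",
            f"{'Training patients':<34}{len(self.split.train_patients):>8d}",
            f"{'Holdout patients':<34}{len(self.split.holdout_patients):>8d}",
            f"{'Holdout fraction achieved':<34}"
            f"{self.split.holdout_fraction_achieved:>8.3f}",
            "-" * 58,
            f"{'Selected features N (= n_band + n_peak)':<40}{p.N:>6d}"
            f"  ({p.n_band}+{p.n_peak})",
            f"{'Regularization C':<40}{p.C:>6.2f}",
            f"{'QF threshold applied':<40}"
            + (f"{self.model.qf_threshold:>6.2f}" if self.model.qf_threshold
               is not None else "  none"),
            "-" * 58,
            f"{'Holdout AUC':<34}{r.auc:>8.3f}",
            f"{'Accuracy':<34}{r.accuracy:>8.3f}",
            f"{'Sensitivity':<34}{r.sensitivity:>8.3f}",
            f"{'Specificity':<34}{r.specificity:>8.3f}",
            f"Confusion (tp/fp/tn/fn): {r.confusion['tp']}/"
            f"{r.confusion['fp']}/{r.confusion['tn']}/{r.confusion['fn']}",
            "=" * 58,
        ]
        return "\n".join(lines)

    def plot_roc(self, ax=None):
        """Plot the holdout ROC curve; returns the matplotlib axes."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.report.roc_fpr, self.report.roc_tpr,
                label=f"{self.name} (AUC = {self.report.auc:.3f})")
        ax.plot([0, 1], [0, 1], ls="--", c="grey", lw=0.8)
        ax.set_xlabel("False positive rate")
        ax.set_ylabel("True positive rate (sensitivity)")
        ax.legend(loc="lower right")
        return ax

    def to_dict(self) -> dict:
        p = self.model.params
        return {
            "name": self.name,
            "hyperparams": {"C": p.C, "n_band": p.n_band, "n_peak": p.n_peak,
                            "N": p.N},
            "qf_threshold": self.model.qf_threshold,
            "selected_features": list(self.model.selected_features),
            "weights": [float(w) for w in self.model.weights],
            "bias": self.model.bias,
            "class_weights": self.model.class_weights,
            "n_train": self.n_train, "n_holdout": self.n_holdout,
            "train_patients": list(self.split.train_patients),
            "holdout_patients": list(self.split.holdout_patients),
            "seed": self.seed,
            **self.report.to_dict(),
        }
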