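"""End-to-end orchestration: simulate -> preprocess -> qc -> features ->
train -> evaluate, with a reproducibility manifest.

A :class:`RunConfig` fully determines a run; re-running with the same
config reproduces every report bit-identically.  The manifest records
the config hash, the seed, and a checksum per stage output.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .classify import HyperGrid, RamanTissueClassifier
from .features import (
    PeakDetectionConfig,
    build_feature_matrix,
    consensus_peaks,
    fit_peaks,
)
from .preprocess import PreprocessingError, preprocess_cohort
from .quality import QF_PRESETS, quality_factor, select_qf_threshold
from .synthetic import GeneratorConfig, generate_cohort

__all__ = ["RunConfig", "RunResult", "StageError", "run_all",
           "assemble_model_dataset"]

MODEL_TARGETS = ("glioblastoma", "metastasis", "meningioma", "all")


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name for diagnostics."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage '{stage}' failed: {message}")


@dataclass
class RunConfig:
    """One reproducible pipeline run.

    ``qf_policy`` is ``"preset"`` (study cutoffs: 0.5 for glioblastoma
    and metastasis, 0.3 for meningioma), ``"auto"`` (cross-validated
    ROC search per model), ``"none"``, or a fixed float cutoff.
    """

    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    qf_policy: object = "preset"
    models: tuple = MODEL_TARGETS
    grid: HyperGrid = field(default_factory=HyperGrid)
    holdout_fraction: float = 0.2
    min_bubble_width: float = 60.0
    seed: int = 0

    def to_dict(self) -> dict:
        return {
            "generator": self.generator.to_dict(),
            "qf_policy": self.qf_policy,
            "models": list(self.models),
            "grid": {"C": list(self.grid.C), "n_band": list(self.grid.n_band),
                     "n_peak": list(self.grid.n_peak)},
            "holdout_fraction": self.holdout_fraction,
            "min_bubble_width": self.min_bubble_width,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        kwargs = dict(d)
        if "generator" in kwargs:
            kwargs["generator"] = GeneratorConfig.from_dict(kwargs["generator"])
        if "grid" in kwargs:
            g = kwargs["grid"]
            kwargs["grid"] = HyperGrid(C=tuple(g["C"]),
                                       n_band=tuple(g["n_band"]),
                                       n_peak=tuple(g["n_peak"]))
        if "models" in kwargs:
            kwargs["models"] = tuple(kwargs["models"])
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()


@dataclass
class RunResult:
    reports: dict            # model target -> report dict
    manifest: dict

    def to_json(self, indent: int = 1) -> str:
        return json.dumps({"reports": self.reports, "manifest": self.manifest},
                          indent=indent, sort_keys=True)


def _checksum(arrays) -> str:
    h = hashlib.sha256()
    for a in arrays:
        h.update(np.ascontiguousarray(a).tobytes())
    return h.hexdigest()[:16]


def assemble_model_dataset(spectra: dict, meta: pd.DataFrame, target: str,
                           peak_config: PeakDetectionConfig | None = None,
                           peaks: dict | None = None) -> pd.DataFrame:
    """Feature matrix + metadata for one model target.

    ``target`` is a pathology name (that pathology's patients: their
    tumor and brain measurements) or ``"all"`` (every measurement).
    Consensus peaks are computed within the target's own dataset, as
    the retained peak set is pathology-dependent.  Per-spectrum fitted
    peaks do not depend on the target; pass ``peaks`` to reuse them
    across models.
    """
    if target == "all":
        sel = meta
    else:
        sel = meta[meta["pathology"] == target]
    if sel.empty:
        raise ValueError(f"no measurements for model target {target!r}")
    ids = list(sel["location_id"])
    sub = {i: spectra[i] for i in ids}
    if peaks is None:
        peaks = {i: fit_peaks(sub[i], peak_config) for i in ids}
    else:
        peaks = {i: peaks[i] for i in ids}
    consensus = consensus_peaks([peaks[i] for i in ids], peak_config)
    matrix = build_feature_matrix(sub, peaks, consensus, peak_config)
    matrix = matrix.join(sel.set_index("location_id")
                         [["patient_id", "site", "pathology", "label"]])
    matrix["qf"] = [quality_factor(sub[i]) for i in matrix.index]
    return matrix


def _resolve_qf_threshold(policy, target: str, dataset: pd.DataFrame,
                          seed: int) -> float | None:
    if policy is None or policy == "none":
        return None
    if policy == "preset":
        if target == "all":
            return None               # combined model: per-pathology cuts upstream
        return QF_PRESETS[target]
    if policy == "auto":
        threshold, _ = select_qf_threshold(dataset, seed=seed)
        return threshold
    return float(policy)


def _filter_by_policy(dataset: pd.DataFrame, policy, target: str,
                      seed: int) -> tuple[pd.DataFrame, object]:
    """Apply the QF policy; for the combined model under presets, each
    measurement is screened at its own pathology's preset cutoff."""
    if policy == "preset" and target == "all":
        keep = np.array([row.qf > QF_PRESETS[row.pathology]
                         for row in dataset.itertuples()])
        return dataset[keep], dict(QF_PRESETS)
    threshold = _resolve_qf_threshold(policy, target, dataset, seed)
    if threshold is None:
        return dataset, None
    return dataset[dataset["qf"] > threshold], threshold


def run_all(config: RunConfig | None = None, outdir=None) -> RunResult:
    """Execute the full pipeline; optionally write reports + manifest.

    Any stage failure raises :class:`StageError` naming the stage.
    """
    config = config or RunConfig()
    manifest = {"config_hash": config.config_hash(), "seed": config.seed,
                "package_version": __version__, "stages": {}}

    try:
        generator = config.generator
        cohort = generate_cohort(generator)
    except ValueError as exc:
        raise StageError("simulate", str(exc)) from exc
    manifest["stages"]["simulate"] = {
        "n_locations": len(cohort.acquisitions),
        "checksum": _checksum(a.frames for a in cohort.acquisitions[:8])}

    try:
        spectra = preprocess_cohort(cohort, config.min_bubble_width)
    except PreprocessingError as exc:
        raise StageError(f"preprocess:{exc.stage}", str(exc)) from exc
    meta = cohort.patient_table()
    manifest["stages"]["preprocess"] = {
        "n_spectra": len(spectra),
        "checksum": _checksum(spectra[i].intensities
                              for i in sorted(spectra)[:32])}

    all_peaks = {loc: fit_peaks(spec) for loc, spec in spectra.items()}
    manifest["stages"]["peaks"] = {
        "n_spectra": len(all_peaks),
        "n_peaks_total": int(sum(len(p) for p in all_peaks.values()))}

    reports = {}
    for target in config.models:
        try:
            dataset = assemble_model_dataset(spectra, meta, target,
                                             peaks=all_peaks)
            filtered, threshold = _filter_by_policy(
                dataset, config.qf_policy, target, config.seed)
            qf_value = (threshold if isinstance(threshold, (int, float))
                        else None)
            model = RamanTissueClassifier.from_dataframe(
                filtered, name=target, qf_threshold=qf_value)
            results = model.fit(grid=config.grid,
                                holdout_fraction=config.holdout_fraction,
                                seed=config.seed)
        except (ValueError, KeyError) as exc:
            stage = "split" if "partition" in str(exc) or "holdout" in str(exc) \
                else "train"
            raise StageError(f"{stage}:{target}", str(exc)) from exc
        report = results.to_dict()
        report["qf_policy"] = (dict(threshold) if isinstance(threshold, dict)
                               else threshold)
        report["n_rejected_by_qf"] = int(len(dataset) - len(filtered))
        reports[target] = report
        manifest["stages"][f"train:{target}"] = {
            "n_measurements": int(len(filtered)),
            "checksum": _checksum([np.asarray(report["weights"])])}

    result = RunResult(reports=reports, manifest=manifest)
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        (outdir / "reports.json").write_text(result.to_json())
        (outdir / "manifest.json").write_text(
            json.dumps(manifest, indent=1, sort_keys=True))
    return result
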