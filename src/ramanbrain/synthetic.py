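"""Synthetic Raman acquisition cohort with known ground truth.

Emulates the data structure of an intraoperative Raman study of brain
tumors: two hospital sites, patients with one pathology each
(glioblastoma, metastasis, meningioma), ~30 probed locations per
patient split evenly between bulk tumor and non-tumoral brain, and 20
repeat CCD frames plus a dark frame per location.

Each location's noiseless Raman signal is a sum of Gaussian bands on
the instrument axis, sitting on a smooth fluorescence baseline, scaled
by a per-site instrument response, offset by dark counts, corrupted by
shot noise and occasional cosmic-ray spikes.  Class contrasts follow
the band biology: tumor tissue carries more protein signal (1004 cm^-1
phenylalanine, 1340 cm^-1 tryptophan) and less lipid signal (1299 and
1441 cm^-1), with no class difference at 1659 cm^-1 (amide I / C=C).
Tumor amplitudes vary less between measurements than brain amplitudes.

The generator returns the true baseline and true noiseless signal per
location so downstream estimators can be tested against ground truth.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .axis import WavenumberAxis, factory_axis

__all__ = [
    "Band",
    "GeneratorConfig",
    "RawAcquisition",
    "LocationTruth",
    "CalibrationReferences",
    "SyntheticCohort",
    "generate_cohort",
    "generate_references",
    "expected_snv_cohens_d",
    "write_cohort",
    "load_cohort",
    "DEFAULT_BANDS",
    "REQUIRED_BANDS",
]

#: Bands whose class means must be configured (cm^-1).
REQUIRED_BANDS = (1004.0, 1299.0, 1340.0, 1441.0, 1659.0)

#: Known Raman peak positions of the wavenumber-calibration standard
#: (polycarbonate-like resin), cm^-1.
REFERENCE_PEAK_POSITIONS = (703.0, 887.0, 1114.0, 1235.0, 1602.0, 1775.0)

#: Band groups sharing a patient-level amplitude random effect.
BAND_GROUPS = {
    856.0: "protein", 936.0: "protein", 1004.0: "protein",
    1209.0: "protein", 1340.0: "protein",
    1299.0: "lipid", 1441.0: "lipid",
    1086.0: "other", 1553.0: "other", 1659.0: "other",
}


@dataclass(frozen=True)
class Band:
    """One Raman band: Gaussian sigma (cm^-1) and class mean amplitudes (counts)."""

    sigma: float
    brain: float
    tumor: float

    def amplitude(self, label: str) -> float:
        return self.tumor if label == "tumor" else self.brain


# Mean amplitudes are on the photon-count scale of a single CCD frame.
# The 1441 cm^-1 lipid/protein band is set to a full width (FWHM) of
# ~60 cm^-1 (sigma 25.5), the width that motivates the minimum bubble
# diameter of the baseline-removal step; the remaining bands use sigmas
# of 3-10 cm^-1 typical of tissue fingerprint peaks.
DEFAULT_BANDS: dict[float, Band] = {
    856.0: Band(4.0, 95.0, 105.0),
    936.0: Band(4.0, 75.0, 80.0),
    1004.0: Band(3.5, 480.0, 770.0),   # phenylalanine: higher in tumor
    1086.0: Band(5.0, 95.0, 95.0),
    1209.0: Band(5.0, 65.0, 80.0),
    1299.0: Band(5.0, 450.0, 270.0),   # lipid CH2 twist: lower in tumor
    1340.0: Band(6.0, 320.0, 530.0),   # tryptophan: higher in tumor
    1441.0: Band(25.5, 320.0, 210.0),  # lipid/protein CH2: lower in tumor
    1553.0: Band(6.0, 110.0, 110.0),   # inside the haemoglobin exclusion zone
    1659.0: Band(8.0, 190.0, 190.0),   # amide I / C=C: no class contrast
}

DEFAULT_BASELINE_PARAMS = {
    "amplitude": 2500.0,      # counts at the low-wavenumber end
    "decay": 900.0,           # cm^-1 e-folding of the fluorescence tail
    "hump_amplitude": 0.35,   # broad hump, fraction of amplitude
    "hump_center": 1300.0,
    "hump_sigma": 380.0,
    "amplitude_sd": 0.30,     # log-normal sd of the per-location amplitude
}


@dataclass
class GeneratorConfig:
    """Study-design parameters of the synthetic cohort.

    ``n_patients_per_site`` counts patients per pathology per site, so the
    default of 4 yields 4 x 3 pathologies x 2 sites = 24 patients.  Each
    patient contributes ``n_locations_per_patient`` probed locations with
    balanced tumor / non-tumoral-brain labels, each measured as
    ``n_repeats`` successive CCD frames plus one dark frame.
    """

    n_patients_per_site: int = 4
    n_locations_per_patient: int = 30
    n_repeats: int = 20
    class_band_means: dict = field(default_factory=lambda: dict(DEFAULT_BANDS))
    patient_effect_sd: float = 0.10
    location_effect_sd: dict = field(
        default_factory=lambda: {"brain": 0.12, "tumor": 0.06})
    site_response_distortion: float = 0.10
    baseline_params: dict = field(
        default_factory=lambda: dict(DEFAULT_BASELINE_PARAMS))
    dark_mean: float = 120.0
    cosmic_rate: float = 0.1
    noise_model: str = "poisson"        # "poisson" | "gaussian" | "none"
    lowq_fraction: float = 0.26
    lowq_signal_scale: float = 0.03
    response_curve: str = "default"     # "default" | "flat"
    sites: tuple = ("MNI-H", "MSH")
    pathologies: tuple = ("glioblastoma", "metastasis", "meningioma")
    # Mild pathology-specific scaling of the tumor protein bands so the
    # three tumor types are not statistically identical.
    subtype_protein_scale: dict = field(default_factory=lambda: {
        "glioblastoma": 1.00, "metastasis": 1.05, "meningioma": 0.95})
    seed: int = 0

    def validate(self) -> None:
        for name in ("n_patients_per_site", "n_locations_per_patient", "n_repeats"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be a positive count")
        if self.cosmic_rate < 0:
            raise ValueError("cosmic_rate must be >= 0")
        if not 0.0 <= self.lowq_fraction <= 1.0:
            raise ValueError("lowq_fraction must lie in [0, 1]")
        missing = [b for b in REQUIRED_BANDS if b not in self.class_band_means]
        if missing:
            raise ValueError(f"class_band_means omits required bands: {missing}")
        if self.location_effect_sd["tumor"] > self.location_effect_sd["brain"]:
            raise ValueError(
                "tumor amplitude variance parameter must not exceed the brain one")
        if self.noise_model not in ("poisson", "gaussian", "none"):
            raise ValueError(f"unknown noise_model {self.noise_model!r}")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["class_band_means"] = {
            str(pos): asdict(band) if isinstance(band, Band) else dict(band)
            for pos, band in self.class_band_means.items()}
        d["sites"] = list(self.sites)
        d["pathologies"] = list(self.pathologies)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "GeneratorConfig":
        d = dict(d)
        if "class_band_means" in d:
            d["class_band_means"] = {
                float(pos): Band(**band) if isinstance(band, dict) else band
                for pos, band in d["class_band_means"].items()}
        for key in ("sites", "pathologies"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass
class RawAcquisition:
    """All frames recorded at one probed tissue location."""

    location_id: str
    patient_id: str
    site: str
    pathology: str
    label: str                 # "tumor" or "brain"
    frames: np.ndarray         # (n_repeats, n_pixels) photon counts
    dark_frame: np.ndarray     # (n_pixels,) laser-off background


@dataclass
class LocationTruth:
    """Ground truth for one location, on the raw axis, pre-response units."""

    baseline: np.ndarray
    signal: np.ndarray
    label: str
    lowq: bool


@dataclass
class CalibrationReferences:
    """Calibration measurements shared by a cohort.

    ``wavenumber_reference`` is the measured spectrum of a standard with
    known peak positions (for the pixel -> cm^-1 fit).
    ``response_reference`` maps site -> measured spectrum of an emission
    standard whose true smooth curve is ``response_known_curve``.
    """

    wavenumber_reference: np.ndarray
    known_peak_positions: tuple
    response_reference: dict
    response_known_curve: np.ndarray
    axis: WavenumberAxis


@dataclass
class SyntheticCohort:
    acquisitions: list
    references: CalibrationReferences
    truth: dict                # location_id -> LocationTruth
    axis: WavenumberAxis
    config: GeneratorConfig

    def patient_table(self) -> pd.DataFrame:
        rows = [
            {"location_id": a.location_id, "patient_id": a.patient_id,
             "site": a.site, "pathology": a.pathology, "label": a.label}
            for a in self.acquisitions]
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# signal model


def _base_response(values: np.ndarray, config: GeneratorConfig) -> np.ndarray:
    if config.response_curve == "flat":
        return np.ones_like(values)
    return 0.75 + 0.5 * np.exp(-0.5 * ((values - 1200.0) / 450.0) ** 2)


def _site_gain(values: np.ndarray, site_index: int, config: GeneratorConfig) -> np.ndarray:
    if site_index == 0 or config.site_response_distortion == 0:
        return np.ones_like(values)
    # smooth +/- distortion gain curve, one slow oscillation over the axis
    return 1.0 + config.site_response_distortion * np.cos(
        2.0 * np.pi * (values - 400.0) / 2200.0)


def site_response(values: np.ndarray, site_index: int,
                  config: GeneratorConfig) -> np.ndarray:
    """Total optical-chain response of a site (base response x site gain)."""
    return _base_response(values, config) * _site_gain(values, site_index, config)


def _gaussian(values: np.ndarray, center: float, sigma: float) -> np.ndarray:
    return np.exp(-0.5 * ((values - center) / sigma) ** 2)


def _known_response_curve(values: np.ndarray) -> np.ndarray:
    # bright emission standard (long-integration measurement)
    return 20000.0 + 30000.0 * np.exp(-0.5 * ((values - 1100.0) / 500.0) ** 2)


def _band_amplitudes(config: GeneratorConfig, label: str, pathology: str,
                     group_factors: dict) -> dict:
    """Mean-times-random-effect amplitude per band for one location."""
    amps = {}
    protein_scale = config.subtype_protein_scale.get(pathology, 1.0)
    for pos, band in config.class_band_means.items():
        amp = band.amplitude(label)
        group = BAND_GROUPS.get(pos, "other")
        if label == "tumor" and group == "protein":
            amp *= protein_scale
        amps[pos] = amp * group_factors[group]
    return amps


def _raman_signal(values: np.ndarray, config: GeneratorConfig,
                  amplitudes: dict) -> np.ndarray:
    signal = np.zeros_like(values)
    for pos, band in config.class_band_means.items():
        signal += amplitudes[pos] * _gaussian(values, pos, band.sigma)
    return signal


def _baseline_curve(values: np.ndarray, config: GeneratorConfig,
                    amplitude: float) -> np.ndarray:
    p = config.baseline_params
    shape = (np.exp(-(values - values[0]) / p["decay"])
             + p["hump_amplitude"]
             * np.exp(-0.5 * ((values - p["hump_center"]) / p["hump_sigma"]) ** 2))
    return amplitude * shape


def _group_factors(rng: np.random.Generator, sd: float) -> dict:
    groups = ("protein", "lipid", "other")
    if sd == 0:
        return {g: 1.0 for g in groups}
    return {g: float(rng.lognormal(0.0, sd)) for g in groups}


def _apply_noise(lam: np.ndarray, rng: np.random.Generator, model: str) -> np.ndarray:
    if model == "none":
        return lam.copy()
    if model == "poisson":
        return rng.poisson(lam).astype(float)
    # gaussian: shot-noise-like variance equal to the mean
    return lam + rng.normal(size=lam.shape) * np.sqrt(np.maximum(lam, 0.0))


def _add_cosmic_rays(frame: np.ndarray, lam: np.ndarray,
                     rng: np.random.Generator, rate: float) -> np.ndarray:
    if rate <= 0:
        return frame
    n_spikes = rng.poisson(rate)
    for _ in range(n_spikes):
        pos = int(rng.integers(0, frame.size))
        width = int(rng.integers(1, 4))
        factor = rng.uniform(10.0, 100.0)
        hi = min(pos + width, frame.size)
        frame[pos:hi] += factor * np.maximum(lam[pos:hi], 1.0)
    return frame


# ---------------------------------------------------------------------------
# public operations


def generate_references(config: GeneratorConfig) -> CalibrationReferences:
    """Generate the wavenumber and instrument-response calibration spectra.

    The wavenumber standard has Gaussian peaks at known cm^-1 positions
    observed through the true pixel map; the response standard's measured
    spectrum equals its known smooth emission curve times each site's
    total optical response, plus shot noise.
    """
    config.validate()
    axis = factory_axis()
    rng = np.random.default_rng([config.seed, 1])

    # calibration standards are bright and measured as many averaged
    # frames (long integration), so their shot noise is far below the
    # tissue-frame noise level
    n_frames = 64

    wn = 200.0 * np.ones_like(axis.values)
    for pos in REFERENCE_PEAK_POSITIONS:
        wn = wn + 5000.0 * _gaussian(axis.values, pos, 4.0)
    wn = np.mean([_apply_noise(wn, rng, config.noise_model)
                  for _ in range(n_frames)], axis=0)

    known = _known_response_curve(axis.values)
    response_ref = {}
    for s, site in enumerate(config.sites):
        lam = known * site_response(axis.values, s, config)
        response_ref[site] = np.mean(
            [_apply_noise(lam, rng, config.noise_model)
             for _ in range(n_frames)], axis=0)

    return CalibrationReferences(
        wavenumber_reference=wn,
        known_peak_positions=REFERENCE_PEAK_POSITIONS,
        response_reference=response_ref,
        response_known_curve=known,
        axis=axis,
    )


def generate_cohort(config: GeneratorConfig | None = None) -> SyntheticCohort:
    """Generate a full synthetic cohort (acquisitions, references, truth).

    Reproducible bit-for-bit given ``config.seed``.  Tumor and brain
    location counts are balanced within every patient.
    """
    config = config or GeneratorConfig()
    config.validate()
    axis = factory_axis()
    values = axis.values
    rng = np.random.default_rng([config.seed, 0])
    references = generate_references(config)

    acquisitions: list[RawAcquisition] = []
    truth: dict[str, LocationTruth] = {}
    p_base = config.baseline_params

    for s, site in enumerate(config.sites):
        response = site_response(values, s, config)
        for pathology in config.pathologies:
            for i in range(config.n_patients_per_site):
                patient_id = f"{site}-{pathology[:3]}-{i:02d}"
                patient_factors = _group_factors(rng, config.patient_effect_sd)
                for j in range(config.n_locations_per_patient):
                    label = "tumor" if j % 2 == 0 else "brain"
                    location_id = f"{patient_id}-loc{j:03d}"
                    lowq = bool(rng.random() < config.lowq_fraction)

                    loc_factors = _group_factors(
                        rng, config.location_effect_sd[label])
                    factors = {g: patient_factors[g] * loc_factors[g]
                               for g in patient_factors}
                    amps = _band_amplitudes(config, label, pathology, factors)
                    signal = _raman_signal(values, config, amps)

                    if p_base["amplitude_sd"] > 0:
                        base_amp = p_base["amplitude"] * rng.lognormal(
                            0.0, p_base["amplitude_sd"])
                    else:
                        base_amp = p_base["amplitude"]
                    if lowq:
                        # fluorescence-dominated, weak Raman scattering
                        signal = signal * config.lowq_signal_scale
                        base_amp = base_amp * 1.5
                    baseline = _baseline_curve(values, config, base_amp)

                    lam = response * (baseline + signal) + config.dark_mean
                    frames = np.empty((config.n_repeats, values.size))
                    for f in range(config.n_repeats):
                        frame = _apply_noise(lam, rng, config.noise_model)
                        frame = _add_cosmic_rays(
                            frame, lam, rng, config.cosmic_rate)
                        frames[f] = frame
                    dark = _apply_noise(
                        np.full(values.size, config.dark_mean), rng,
                        config.noise_model)

                    acquisitions.append(RawAcquisition(
                        location_id=location_id, patient_id=patient_id,
                        site=site, pathology=pathology, label=label,
                        frames=frames, dark_frame=dark))
                    truth[location_id] = LocationTruth(
                        baseline=baseline, signal=signal, label=label,
                        lowq=lowq)

    return SyntheticCohort(acquisitions=acquisitions, references=references,
                           truth=truth, axis=axis, config=config)


def expected_snv_cohens_d(config: GeneratorConfig, band: float,
                          pathology: str = "glioblastoma",
                          n: int = 4000, seed: int = 12345) -> float:
    """Closed-form-model Cohen's d of the SNV intensity at ``band``.

    Independent oracle for the generated cohort: draws amplitude random
    effects directly from the configured log-normal laws (total log-sd
    per group = sqrt(patient_sd^2 + location_sd^2)), evaluates the
    noiseless Gaussian-mixture signal on the truncated axis, applies SNV,
    and computes the standardized mean difference between tumor and
    brain at the bin nearest ``band``.  No frames, noise, baseline or
    preprocessing are involved.
    """
    config.validate()
    axis = factory_axis().truncate()
    values = axis.values
    bin_idx = int(np.argmin(np.abs(values - band)))
    rng = np.random.default_rng(seed)
    samples = {}
    for label in ("tumor", "brain"):
        sd = float(np.hypot(config.patient_effect_sd,
                            config.location_effect_sd[label]))
        out = np.empty(n)
        for i in range(n):
            factors = _group_factors(rng, sd)
            amps = _band_amplitudes(config, label, pathology, factors)
            signal = _raman_signal(values, config, amps)
            snv = (signal - signal.mean()) / signal.std()
            out[i] = snv[bin_idx]
        samples[label] = out
    a, b = samples["tumor"], samples["brain"]
    pooled = np.sqrt(((a.size - 1) * a.var(ddof=1) + (b.size - 1) * b.var(ddof=1))
                     / (a.size + b.size - 2))
    return float(abs(a.mean() - b.mean()) / pooled)


# ---------------------------------------------------------------------------
# on-disk schema (documented in the README)


def write_cohort(cohort: SyntheticCohort, directory) -> None:
    """Write a cohort to ``directory`` in the documented CSV/JSON schema."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)

    meta = {
        "config": cohort.config.to_dict(),
        "axis": {"calibration": list(cohort.axis.calibration),
                 "n_pixels": cohort.axis.n_bins},
        "known_peak_positions": list(cohort.references.known_peak_positions),
        "patients": {},
        "locations": {},
    }
    for acq in cohort.acquisitions:
        meta["patients"].setdefault(acq.patient_id, {
            "site": acq.site, "pathology": acq.pathology})
        meta["locations"][acq.location_id] = {
            "patient_id": acq.patient_id, "label": acq.label}
    (directory / "metadata.json").write_text(json.dumps(meta, indent=1))

    rows = []
    for acq in cohort.acquisitions:
        n_pix = acq.dark_frame.size
        rows.append(pd.DataFrame({
            "location_id": acq.location_id, "frame_index": -1,
            "pixel": np.arange(n_pix), "counts": acq.dark_frame}))
        for f in range(acq.frames.shape[0]):
            rows.append(pd.DataFrame({
                "location_id": acq.location_id, "frame_index": f,
                "pixel": np.arange(n_pix), "counts": acq.frames[f]}))
    pd.concat(rows, ignore_index=True).to_csv(
        directory / "acquisitions.csv", index=False)

    refs = cohort.references
    ref_rows = [pd.DataFrame({
        "kind": "wavenumber", "pixel": np.arange(refs.wavenumber_reference.size),
        "value": refs.wavenumber_reference})]
    ref_rows.append(pd.DataFrame({
        "kind": "response_known", "pixel": np.arange(refs.response_known_curve.size),
        "value": refs.response_known_curve}))
    for site, measured in refs.response_reference.items():
        ref_rows.append(pd.DataFrame({
            "kind": f"response:{site}", "pixel": np.arange(measured.size),
            "value": measured}))
    pd.concat(ref_rows, ignore_index=True).to_csv(
        directory / "references.csv", index=False)

    truth_rows = []
    for loc_id, t in cohort.truth.items():
        truth_rows.append(pd.DataFrame({
            "location_id": loc_id, "pixel": np.arange(t.baseline.size),
            "baseline": t.baseline, "signal": t.signal,
            "label": t.label, "lowq": t.lowq}))
    pd.concat(truth_rows, ignore_index=True).to_csv(
        directory / "truth.csv", index=False)


def load_cohort(directory) -> SyntheticCohort:
    """Load a cohort previously written by :func:`write_cohort`."""
    directory = Path(directory)
    meta = json.loads((directory / "metadata.json").read_text())
    config = GeneratorConfig.from_dict(meta["config"])
    n_pixels = int(meta["axis"]["n_pixels"])
    axis = factory_axis()
    if axis.n_bins != n_pixels:
        raise ValueError("stored axis does not match the instrument grid")

    acq_df = pd.read_csv(directory / "acquisitions.csv")
    ref_df = pd.read_csv(directory / "references.csv")
    truth_df = pd.read_csv(directory / "truth.csv")

    refs_by_kind = {kind: grp.sort_values("pixel")["value"].to_numpy()
                    for kind, grp in ref_df.groupby("kind")}
    response_ref = {kind.split(":", 1)[1]: arr
                    for kind, arr in refs_by_kind.items()
                    if kind.startswith("response:")}
    references = CalibrationReferences(
        wavenumber_reference=refs_by_kind["wavenumber"],
        known_peak_positions=tuple(meta["known_peak_positions"]),
        response_reference=response_ref,
        response_known_curve=refs_by_kind["response_known"],
        axis=axis,
    )

    acquisitions = []
    for loc_id, grp in acq_df.groupby("location_id", sort=False):
        loc_meta = meta["locations"][loc_id]
        pat_meta = meta["patients"][loc_meta["patient_id"]]
        pivot = grp.pivot(index="frame_index", columns="pixel", values="counts")
        pivot = pivot.sort_index()
        dark = pivot.loc[-1].to_numpy()
        frames = pivot.drop(index=-1).to_numpy()
        acquisitions.append(RawAcquisition(
            location_id=loc_id, patient_id=loc_meta["patient_id"],
            site=pat_meta["site"], pathology=pat_meta["pathology"],
            label=loc_meta["label"], frames=frames, dark_frame=dark))

    truth = {}
    for loc_id, grp in truth_df.groupby("location_id", sort=False):
        grp = grp.sort_values("pixel")
        truth[loc_id] = LocationTruth(
            baseline=grp["baseline"].to_numpy(),
            signal=grp["signal"].to_numpy(),
            label=str(grp["label"].iloc[0]), lowq=bool(grp["lowq"].iloc[0]))

    return SyntheticCohort(acquisitions=acquisitions, references=references,
                           truth=truth, axis=axis, config=config)
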