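"""Shared fixtures: synthetic cohorts at several scales.

The session-scoped default cohort (full study conditions) is expensive
and shared by the end-to-end tests; the tiny cohorts are for unit
tests.  Hypothesis runs derandomized so the suite is reproducible.
"""

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from ramanbrain.pipeline import assemble_model_dataset
from ramanbrain.preprocess import preprocess_cohort
from ramanbrain.features import fit_peaks
from ramanbrain.synthetic import GeneratorConfig, generate_cohort

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def tiny_cohort():
    """24 locations, 8 repeats, no low-quality acquisitions: unit-test scale."""
    config = GeneratorConfig(n_patients_per_site=1, n_locations_per_patient=4,
                             n_repeats=8, lowq_fraction=0.0, seed=7)
    return generate_cohort(config)


@pytest.fixture(scope="session")
def noiseless_cohort():
    """Deterministic cohort: no noise, no cosmic rays, flat response, no
    baseline, no random effects — every frame equals the planted truth
    exactly.  All bands are narrow relative to the minimum bubble
    diameter so baseline removal is near-null on the pure signal (the
    broad-band interaction is exercised by the BubbleFill tests)."""
    from ramanbrain.synthetic import Band

    bands = dict(GeneratorConfig().class_band_means)
    b1441 = bands[1441.0]
    bands[1441.0] = Band(8.0, b1441.brain, b1441.tumor)
    config = GeneratorConfig(
        n_patients_per_site=1, n_locations_per_patient=2, n_repeats=5,
        class_band_means=bands,
        noise_model="none", cosmic_rate=0.0, patient_effect_sd=0.0,
        location_effect_sd={"brain": 0.0, "tumor": 0.0},
        site_response_distortion=0.0, response_curve="flat",
        lowq_fraction=0.0, seed=3)
    config.baseline_params = dict(config.baseline_params,
                                  amplitude=0.0, amplitude_sd=0.0)
    return generate_cohort(config)


@pytest.fixture(scope="session")
def default_cohort():
    """The full study conditions (defaults): 24 patients x 30 locations."""
    return generate_cohort(GeneratorConfig(seed=11))


@pytest.fixture(scope="session")
def default_processed(default_cohort):
    """SNV spectra, fitted peaks and metadata for the default cohort."""
    spectra = preprocess_cohort(default_cohort)
    peaks = {loc: fit_peaks(spec) for loc, spec in spectra.items()}
    return {"cohort": default_cohort, "spectra": spectra, "peaks": peaks,
            "meta": default_cohort.patient_table()}


@pytest.fixture(scope="session")
def default_datasets(default_processed):
    """Per-model feature matrices (with qf column) for the default cohort."""
    out = {}
    for target in ("glioblastoma", "metastasis", "meningioma", "all"):
        out[target] = assemble_model_dataset(
            default_processed["spectra"], default_processed["meta"], target,
            peaks=default_processed["peaks"])
    return out


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)
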