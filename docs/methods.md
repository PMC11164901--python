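# Methods

This note documents the models, the numerical choices and the scope of
validity of `ramanbrain`: what the pipeline computes, what the
synthetic cohort generator does and does not emulate, and which design
decisions were genuinely open.

## Problem setting

Intraoperative fiber-probe Raman spectroscopy measures the inelastic
scattering fingerprint of brain tissue during tumor resection.  Each
probed location yields 20 successive CCD frames plus a laser-off dark
frame.  The analytical task is (i) conditioning these raw counts into a
comparable, normalized spectrum, (ii) screening out acquisitions whose
photon budget is too low to carry the tissue fingerprint, and
(iii) classifying tumor versus non-tumoral brain with a model whose
validation respects the patient as the sampling unit.

## Spectral conditioning chain

Nine steps run in a fixed order: dark-count subtraction; cosmic-ray
removal; truncation to the fingerprint window; wavenumber calibration;
instrument-response correction; repeat averaging; baseline removal;
Savitzky–Golay smoothing (order 3, window 11); SNV normalization.

*Truncation.* The retained window is the closed interval
[800, 1750] cm⁻¹.  On the instrument grid (spacing 950/520 ≈
1.83 cm⁻¹, anchored so that 800 and 1750 cm⁻¹ are exact grid points)
this is exactly 521 bins.  Truncation precedes calibration in the
chain, so it is applied on the nominal factory axis; after the
calibration fit the window is re-checked with a half-bin tolerance and
the 521-bin contract asserted.  A literal zero-tolerance re-check
would evict the two boundary bins under any nonzero calibration shift;
the half-bin tolerance keeps the contract meaningful while still
dropping genuinely drifted bins.

*Cosmic rays.* Spikes are uncorrelated across the 20 repeat frames, so
the repeat dimension is the natural detector: a value deviating from
the per-bin median of the repeats by more than k = 8 robust scales
(1.4826 × MAD) is replaced by that median.  Only flagged values change.
With fewer than 3 repeats the filter passes through with a warning.

*Wavenumber calibration.* A polycarbonate-like standard with six known
peak positions is measured on the same pixels.  Apparent peak pixels
are refined by parabolic interpolation on log intensities — exact for
a Gaussian line shape on a uniform grid, unlike the plain three-point
parabola, which carries a sub-pixel bias that scales with the offset
of the true apex from the grid.  A degree-1 polynomial (configurable
to 3) maps pixel → cm⁻¹; the residual RMS is reported.

*Response correction.* The measured spectrum of an emission standard
divided by its known smooth curve estimates the optical-chain
response; the correction factor is normalized to unit mean so the
count scale is preserved.  The correction is applied per frame before
averaging (division is linear, so the order relative to averaging is
immaterial; the enumerated order is kept).

*BubbleFill baseline removal.* Tissue autofluorescence forms a smooth
background several times larger than the Raman signal.  The baseline
estimator grows circular-arc "bubbles" beneath the y-range-normalized
spectrum: the first bubble spans the whole axis; each arc is raised
until it first touches the spectrum (leftmost touching bin on ties),
the segment splits at the touch point, and recursion continues on each
side until a segment is narrower than the minimum bubble width
(default 60 cm⁻¹ — the full width of the ubiquitous lipid/protein band
near 1441 cm⁻¹, so that band survives baseline removal).  Segments
abutting the spectrum edge are always grown, with a half-bubble
anchored at the edge; without this the edge bins sit on unfitted lobes
of the large parent arcs, and the leftover "structure" masquerades as
signal in downstream quality scoring.  The assembled baseline is
smoothed with a moving average of one bubble width and clipped to
never exceed the spectrum, so the Raman residual is non-negative.

*SNV.* Per-spectrum standard normal variate, with the population
(divide-by-n) standard deviation.  The convention is pinned by tests:
after SNV the mean of r² is exactly 1, which is what bounds the
quality factor below.

## Spectral quality factor

For an SNV spectrum r with N bins,

    QF = (1/N) Σ sgn(rᵢ) rᵢ² = 1 − 2·E⁻ ,

where E⁻ is the mean squared negative part.  Because Σ rᵢ²/N = 1, QF
is bounded in [−1, 1]; symmetric noise gives QF ≈ 0 and peak-bearing
spectra QF > 0.  QF is computed on the final-stage spectrum (after
smoothing); the alternative — before smoothing — shifts all values
toward 0 without changing the ordering, and the final-stage choice is
pinned by tests.

The screening cutoff is selected by re-evaluating the downstream
classifier at each candidate cutoff (grid 0, 0.1, …, 0.9) by
patient-grouped five-fold cross-validated AUC on the retained spectra,
keeping the best-AUC cutoff among those that retain a minority-class
fraction of at least 40% (ties → smaller cutoff).  Two deliberate
simplifications: the per-cutoff evaluation uses a fixed-C
band-intensity SVM rather than the full grid search (the full search
per cutoff multiplies cost without changing the ordering of cutoffs),
and the 40% balance bound is a configuration knob — the underlying
study reports the constraint qualitatively without a number.  The
study presets are retained as configuration: cutoff 0.5 for
glioblastoma and metastasis runs, 0.3 for meningioma runs.

## Feature engineering

Band features are the SNV intensities of the 521 bins, minus the
1500–1620 cm⁻¹ window (haemoglobin bands confound the tissue signal
there).  Peak features come from Gaussian fits (position, height,
width) at local maxima with prominence ≥ 0.1 and height ≥ 0.5 above
the spectrum minimum, fitted over ±3 initial width estimates with a
constant offset; non-converged fits fall back to apparent values.
Peaks are clustered across measurements within ±2 cm⁻¹; clusters
present in ≥ 50% of all measurements (boundary inclusive, global
rather than per-class) are retained, capped at 11 by occurrence, two
columns each (height, width), up to 22 peak columns.  A spectrum with
no matching fitted peak is imputed with height 0 and the consensus
median width — the imputation rule is this package's choice.

Dimensionality reduction ranks band and peak columns separately by the
impurity importances of one 200-tree random forest and keeps the top
n_band and n_peak.  The separate per-type quotas are the only reading
consistent with the stated search ranges (bands 5–25, peaks 2–20,
total 7–45).  Inside cross-validation the forest is fit on the
training folds only.

## Classification protocol

Patients are the sampling unit: the 80/20 training/holdout split
assigns whole patients greedily per site toward a 20% measurement
share, preserving the site mix; the five cross-validation folds are
also patient-grouped (stricter than grouping the holdout alone, and
the only choice that prevents within-patient leakage during model
selection).  The grid search over (n_band, n_peak, C) — defaults
C ∈ {0.01, 0.05, 0.1, 0.5, 1, 2, 5}, n_band ∈ {5,…,25},
n_peak ∈ {2,…,20} — scores each point by the total count of false
positives plus false negatives over the five validation folds; ties
break to smaller N, then smaller C.  The final model is a
class-weighted linear SVM (weights inverse to class frequencies)
refit on the whole training set with feature selection re-run there.

Holdout evaluation is a ROC analysis of the decision scores: AUC by
the trapezoid over the ROC points; the operating point for accuracy,
sensitivity and specificity is the ROC threshold minimizing FP + FN,
ties going to higher sensitivity.  The operating-point rule is this
package's pin — "computed from the ROC curve" admits several
conventions and this one matches the FP+FN criterion used in model
selection.

## Power statistics

`power_sample_size` computes the smallest per-group n at which a
two-sample t-test of effect size d reaches the target power, by
noncentral-t iteration (df = 2n−2, noncentrality d·√(n/2)) from the
normal-approximation start, decreasing then increasing n so the result
is exact.  At d = 0.5, α = 0.05 two-sided, power 0.95 the exact answer
is 105 per group (cross-checked in tests against the independent
statsmodels solver); 100 per category is therefore read as the rounded
design floor that the exact computation must meet or exceed.
`cohens_d` is |mean difference| over the pooled standard deviation.

## Synthetic cohort generator

The generator defines the study conditions the tests run under.  Two
sites with a smooth ±10% relative gain difference; three pathologies;
4 patients per pathology per site by default; 30 locations per patient
balanced tumor/brain; 20 repeat frames plus one dark frame per
location (frames can be reduced for unit-test fixtures).

Each location's noiseless signal is a sum of ten Gaussian bands.
Contrast direction follows the band biology: tumor higher at 1004 and
1340 cm⁻¹ (protein), lower at 1299 and 1441 cm⁻¹ (lipid), no contrast
at 1659 cm⁻¹.  The 1441 band has FWHM ≈ 60 cm⁻¹ — the width that
motivates the minimum bubble diameter — and the remaining bands use
widths of 3.5–8 cm⁻¹.  Amplitudes carry a log-normal patient effect
(sd 0.10, shared within band groups: protein/lipid/other) and a
log-normal location effect whose sd is smaller for tumor (0.06) than
brain (0.12), reproducing the lower spectral variance of tumor tissue.
Band amplitudes were chosen so that (i) SNV spectra span roughly −1 to
+7, (ii) the noiseless quality factor of good spectra sits near
0.6–0.8 so the preset cutoffs separate quality classes, and (iii) the
standardized class contrast at 1441 and 1004 cm⁻¹ exceeds 1.8 — the
regime the analysis is designed for.

The background is a per-location log-normal-amplitude exponential
fluorescence tail plus a broad hump; frames are Poisson counts of
response × (baseline + signal) + dark (dark mean 120 counts), with
optional Gaussian (variance = mean) or noiseless modes.  Cosmic rays
arrive per frame as a Poisson number (rate 0.1) of 1–3-bin spikes at
10–100× the local level.  A configurable fraction of locations
(default 0.26) is generated fluorescence-dominated, with Raman
amplitudes scaled by 0.03 and 1.5× background — these land at QF below
the presets and model the low-quality acquisitions the QF cut removes.

What the generator does **not** emulate: tissue optics (scattering,
absorption, probe-tissue coupling), detector nonlinearity and readout
structure, wavelength-dependent noise correlations, intra-patient
spatial correlation beyond the shared patient effect, and any
morphological heterogeneity within a pathology.  Passing tests
therefore demonstrate the correctness and internal consistency of the
analysis pipeline under the assumed signal model — not clinical
performance on real tissue.  The ±10% inter-site gain curve is a
stand-in; the underlying study does not quantify inter-site spectral
differences.

## Problem sizes and numerical tolerances

The default cohort (24 patients, 720 locations, 20 repeats, 875
pixels) preprocesses in a few seconds and completes the full
four-model workflow in under three minutes on one core; the test suite
uses this cohort once (session fixture) plus much smaller fixtures for
unit tests.  SNV and QF identities are asserted to 1e−9/1e−12;
BubbleFill baseline ≤ spectrum to 1e−9 (enforced by the final clip);
baseline recovery to 5% RMS of the planted range and peak heights to
10%; calibration to 0.1 cm⁻¹ RMS against the true map.  Degenerate
inputs are defined failures: zero-dispersion SNV, empty truncation,
single-class ROC, all-rejecting QF cutoffs.

## Known limitations

- The BubbleFill arc geometry (circle in the unit-square normalized
  frame) follows the published description qualitatively; different
  normalization conventions change the baseline at the few-count level
  under strong curvature.
- The QF-cutoff search optimizes a simplified surrogate of the final
  workflow (fixed-C band SVM); in pathological cases the full-search
  optimum could differ by one grid step.
- With few patients per pathology (the default is 8 per per-pathology
  model), the holdout contains 1–2 patients and holdout metrics are
  coarse-grained; the defaults are chosen so the class contrast
  dominates this granularity.
- Consensus peak retention is global, not per-class; a peak carried by
  under half of all measurements but all of one class is dropped.
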