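# Methods

This note documents the models, defaults and numerical choices behind
`ecgkit`, what the synthetic generators do and do not emulate, and the
known limitations.

## Spectral diagnostics

**Spectrum estimation.** Per-lead Welch periodogram averaging: Hann
window, 2 s segments (0.5 Hz resolution on a 10 s record), 50% overlap,
per-segment mean detrending. Detrending matters: without it the DC
component of a unipolar beat train leaks into the sub-1 Hz bins through
the window's main lobe and contaminates the low-frequency trigger.

**Low-frequency excess.** Mean log10 power over the open interval
(0, 1) Hz minus mean log10 power over [1, 30] Hz, per lead. The
high-pass trigger fires above 1.0 (one logarithmic unit). The log-ratio
is invariant to global amplitude rescaling. Both a per-lead and a
per-record trigger scope are provided (`trigger_scope="lead"|"record"`);
the per-lead scope is the default because wander induced by a loose
electrode is a per-lead phenomenon.

**Artifact-peak detection.** Candidates are 50/60 Hz and their
harmonics below Nyquist (3 harmonics by default; configurable — an
unconstrained scan is deliberately not attempted, since powerline
interference is the only narrowband artifact this pipeline targets).
For each candidate the statistic is the *mean* log10 power over the
±1 Hz zone around the candidate, compared against the per-bin mean +
k·SD (k = 2) of the surrounding ±5 Hz window, zone excluded. Averaging
over the zone is the key numerical choice: a single-bin statistic
exceeds a 2-SD threshold with probability ~2–3% per candidate on
perfectly clean input, which across 6–8 candidate frequencies would
flag ~15–20% of clean records. The zone mean shrinks the null
fluctuation by roughly the square root of the zone width (5 bins at the
default resolution) while a genuine tone — spectrally a line — still
clears the threshold by an order of magnitude. A second, absolute guard
requires the zone to stand at least 6 dB above the local mean: the
relative rule alone still fires on ~3% of clean records with marginal
2-4 SD exceedances, but those sit below 1 dB of absolute prominence
whereas the weakest tone in scope (10x the background amplitude) is
20+ dB proud of the floor, leaving a ~7x margin on both sides of the
guard. Detection pools leads by default (powerline pickup is
common-mode); per-lead detection is available.

## Harmonization

**Stage order** is fixed: conditional high-pass → peak detection +
flattening → amplitude matching, with per-stage disable switches. The
spectrum is recomputed after the high-pass so peak detection sees the
filtered signal.

**High-pass.** Order-4 Butterworth at 1 Hz applied forward-backward
(zero phase, effective order 8), chosen so the ST segment and T wave
are not skewed by group delay. The filter is applied with a long
odd-extension pad (5·fs/cutoff samples, capped at the record length):
with scipy's default padding, edge transients from a wander component
100× the signal amplitude remain visible in the passband and in
amplitude percentiles. With the long pad the residual of a sub-band
sinusoid is ~5 × 10⁻⁵ of its amplitude.

**Flattening.** Operates on the full-length FFT, not the Welch
estimate, so inversion is exact and untouched bins are numerically
unchanged. For each peak, log10 magnitude is fitted by LOESS (local
linear, statsmodels `lowess`, span 0.5 of the fit window) over the bins
within ±5 Hz of the peak excluding the peak's own ±1 Hz zone; the zone
bins' magnitudes are replaced by the LOESS prediction and the original
phase is kept. Peaks within the exclusion width of DC or Nyquist are
rejected. Spectral surgery was chosen over time-domain notch filtering
because it leaves non-peak bins exactly alone and needs no filter
design per peak.

**Amplitude matching.** Per-lead multiplicative scaling onto a
reference profile of pooled p1–p99 amplitude percentiles. The
percentiles are measured on a brick-wall 2–40 Hz band-limited copy of
the waveform, with 0.5 s trimmed from each end. Rationale: raw-waveform
percentiles are not invariant under the 1 Hz high-pass — the filter's
transition band attenuates the beat-train fundamental (~1.2 Hz at
72 bpm) by ~20%, which reshapes the baseline between beats and inflates
the raw span by tens of percent. That would make "scale to the
reference range" give different answers for filtered and unfiltered
copies of the same heart signal. Measured on a band where all pipeline
stages are transparent, the amplitude statistic is consistent: a
half-scale record is restored with factor 2.000 ± 0.5%. The edge trim
discards the IIR settle region. Degenerate (flat or all-zero) leads are
left unscaled and flagged rather than failing the record.

**Replayability.** The log stores the filtered leads, the removed peaks
and the scale factors; `replay(input, log)` re-applies exactly those
operations and reproduces the output bit for bit. Determinism holds
because every stage is a deterministic function of (input, config).

## Evaluation metrics

AUROC is the midrank (Mann-Whitney) estimator, ties counted half; it is
tested for exact agreement with a pair-counting brute force. AUPRC is
the average-precision step integral. The overall AUROC concatenates all
(record, label) cells into one vector (micro aggregation).

"Bootstrap" CIs subsample 70% of *records* without replacement, 1000
iterations, percentile 2.5/97.5 bounds; a with-replacement mode exists
behind a flag since usage of the term varies. Resampling is at record
level, not cell level, to respect within-record label correlation.
Iterations that hit a degenerate label are redrawn (up to 10 times) so
the iteration count stays exact. The DeLong test uses the structural
components (midrank) covariance estimator with a two-sided normal
p-value; zero-variance differences (identical scores) return p = 1
flagged rather than dividing by zero. It is tested against a
10,000-draw paired permutation oracle.

Threshold selection evaluates balanced accuracy (mean of sensitivity
and specificity, predicting positive at score ≥ t) at every unique
score; ties are broken toward the lowest optimal candidate and the
returned threshold is the midpoint of the bounding interval —
deterministic and symmetric. Thresholds are fitted once on a training
set and frozen. No multiple-testing correction is applied across
labels by default (a Holm option would be a trivial extension); p-values
from label-wise tests should be read accordingly.

## Fairness audit

Equalized odds: a classifier is fair when TPR and FPR match across
groups. Age is binned as under 55 / 55–75 / over 75, boundaries
inclusive for the middle bin (55.0 and 75.0 both map to 55–75; the
bin labels do not disambiguate this, so the convention is declared and
unit-tested). Within each group all (record, label) cells are pooled at
the frozen thresholds (micro-averaging). Disparity is the mean of
|rate_i − rate_j| over all unordered group pairs (for two groups this is
just the absolute difference). The bootstrap mirrors the metric CIs:
1000 iterations × 70% record subsamples; iterations in which a group
loses all positives or negatives are redrawn and counted. Zero
denominators therefore never propagate NaNs into the report.

## Privacy audit

The membership-inference attack labels train/held-out logit rows by
membership, balances class sizes by subsampling the larger set (so the
null AUROC is exactly 0.5), splits 80/20 stratified, fits a 50-tree
random forest (Gini impurity, unlimited depth — defaults beyond the
tree count are declared, not inherited), and reports AUROC on the held-
out 20%. The protocol repeats over a predefined seed list (default
0–9) giving a percentile CI and elementwise-averaged impurity
importances. t-SNE (perplexity 30, PCA init, up to 10,000 rows per set)
embeds the combined sample in 2-D; the silhouette of the membership
tags on the embedding quantifies separation. The silhouette score is
this package's own addition to make "more separation ⇒ more
re-identifiable" testable; it is not part of the attack itself.

## Attribution

Each lead is tiled into equal-width half-open segments (default 10 per
lead: 1 s windows on a 10 s record, roughly one beat at resting heart
rate; the last segment absorbs the division remainder). Binary masks
(Bernoulli 0.5 per segment, the unperturbed mask always included)
switch segments off, replacing them with a zero baseline (lead-mean
baseline available). The black box scores each perturbed record; a
ridge-penalized weighted least squares surrogate (penalty 10⁻⁴,
intercept unpenalized) regresses scores on masks with proximity weights
exp(−h/w²) on mask Hamming distance h, w = 0.25·√(number of segments).
Coefficients are the attribution; a constant-output model yields zero
weights with the fit quality flagged undefined. Labels are analyzed
independently — the attribution for one label provably never reads
other labels' outputs.

## Synthetic data

The generators define the conditions every test and the acceptance
script run under.

* **Pseudo-ECG**: a strictly periodic train of five Gaussian bumps
  (P, Q, R, S, T; R amplitude 1 mV) at 72 bpm, 500 Hz, 10 s, 12 leads
  with per-lead amplitude multipliers drawn from U(0.6, 1.4), plus
  white measurement noise of 0.02 mV SD. This is a morphology model,
  not a dynamical one: it reproduces the spectral band occupancy
  (~1–40 Hz line spectrum over a noise floor) that the pipeline's
  triggers and filters actually depend on. 72 bpm places the beat
  fundamental at 1.2 Hz, safely inside the 1–30 Hz reference band; a
  60 bpm default would sit exactly on the trigger-band boundary. It
  deliberately does not model RR variability, conduction abnormalities,
  arrhythmia morphologies, or electrode-motion artifacts other than
  sinusoidal wander.
* **Contaminations** are additive sinusoids whose exact traces are
  stored in record metadata, so removal can be checked against a
  subtraction oracle. Contaminated test records use wander at 100× the
  clean RMS amplitude, a 0.5 mV 50 Hz tone (25× the noise floor) and a
  0.5× global scale — a deliberately extreme but unambiguous repair
  problem.
* **Prediction sets** draw the binary outcome first (label from the
  group's prevalence, predicted-positive from its TPR/FPR) and then a
  score from a Beta(2,2) shape mapped strictly above or below 0.5, so
  the 0.5-threshold confusion rates are exact by construction and
  empirical rates converge to targets at rate 1/√n. Fairness tests use
  20,000 records × 77 labels (the label-panel width such audits face
  in practice); with fewer labels the Monte-Carlo floor of the
  disparity estimate (~1/√(positive cells per group)) would not resolve
  gaps below ~0.01.
* **Logit sets** are unit-covariance Gaussians differing by a known
  mean shift; shift 0 gives exchangeability (attack null), 10 SD gives
  separability (attack power).

Because these generators are idealized, passing tests demonstrate the
correctness and calibration of the *machinery* — not that any real
dataset is harmonizable to any particular fidelity, nor that a real
model is fair or private.

## Problem sizes and tolerances

The test-suite and acceptance scales are: 200 contaminated + 200 clean
records for the pipeline (band-power preservation asserted at <5% in
2–30 Hz), 100 random sets for each brute-force oracle (exact agreement
at 10⁻¹²), 20,000 × 77 prediction cells for fairness (designed 0.2 gap
recovered ±0.02, identical-group floor ≤0.005), 2×1000 logit rows × 20
replicates for attack calibration (mean AUROC in [0.45, 0.55] under the
null), and 100 seeds × 300 perturbations for attribution recovery.
These sizes make every Monte-Carlo tolerance a small multiple of its
standard error.

## Known limitations

* The trigger-scope question (per lead vs per record) has no single
  right answer; both are implemented and the default is a choice.
* Flattening removes genuine signal inside the ±1 Hz peak zone; for
  ECG content at 50/60 Hz this is negligible (<0.5% RMS in tests) but
  it is not signal-preserving in that band.
* Amplitude matching assumes a multiplicative gain difference between
  datasets; nonlinear or frequency-dependent gain mismatches are out of
  scope.
* The attack accepts raw logits or post-sigmoid probabilities alike and
  does not distinguish them; callers should record which they supply.
* Waveform I/O is delimited text with a JSON sidecar; binary waveform
  container formats are not parsed.
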