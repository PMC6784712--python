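# Methods notes

## The screening model

`lcsleep` estimates obstructive sleep apnea severity from the composite
pressure signal of four under-mattress load cells. The method does not
detect individual apnea or hypopnea events; it maps whole-recording
spectral shape statistics to an apnea-hypopnea index (AHI). The core
assumption is that apnea/hypopnea activity amplitude-modulates the
quasi-periodic components of the bed signal (breathing and its
harmonics, the ballistocardiogram and its respiratory sidebands), and
that this modulation reshapes the distribution of Fourier-coefficient
magnitudes inside narrow fixed sub-bands in a severity-dependent way.
Skewness and kurtosis are used because they are invariant to sensor
gain: after standardization, no calibration of the load cells is needed.

The classifier is deliberately two-stage. Detection (normal vs abnormal)
and grading (how severe) are different statistical problems on a small
cohort: a shallow decision tree on {X1, X4, X6} handles the first, and a
three-term linear regression on {X2², X3, X5}, fit only on abnormal
studies, handles the second. The shipped default regression
coefficients (11.94, 23.06, 8.74, −15.04) are the frozen pilot-study
model; the split thresholds of the pilot detection tree were never
published, so any use of stage one requires a fitted tree (Gini
impurity, depth ≤ 3, fixed seed, restricted to X1/X4/X6). Refitting both
stages is done with leave-one-patient-out cross-validation: all nights
of a subject are held out together, because nights of one subject share
physiology and would otherwise leak.

Severity boundaries: AHI < 5 normal, 5 ≤ AHI ≤ 15 mild, AHI > 15
moderate/severe. The boundary value 15.0 itself is mild. Clinical usage
varies between "5–14" and "5–15" for mild; the pipeline follows the
convention under which the pilot predictions were scored, and moderate
and severe are collapsed into one predicted class because both are
managed with CPAP. A stage-two estimate below 5 for a night the tree
gated abnormal is clamped up to 5.0 so that category, AHI and severity
never contradict each other; censored "<5" reports appear exactly when
the gate says normal.

## Night and subject protocol

Nights recorded concurrently with a gold standard are scored from the
whole valid recording (clinician-invalidated spans are excised, not
imputed, since the features are distributional over frequency).
Unattended nights have no validity annotation, so they are scored by
overlapping 3-h windows (step 1 h), a centered rolling-median filter
(span 5) that drops window estimates deviating more than 10 events/h
from the local median, and the mean of the survivors; a majority of
normal-gated windows censors the night. The window length follows the
2–4 h minimum recording recommended for sleep apnea testing; the step,
median span and rejection threshold are engineering defaults, all
configurable and logged. Multi-night subject aggregation takes the
maximum night AHI — OSA has high night-to-night variability and
screening prefers false alarms over missed disease; the bundled pilot
tables show the cost of that rule (subject-level specificity 50%).

## Evaluation conventions

All pilot-table statistics are recomputed from the bundled per-night
result tables (checksummed CSVs transcribed verbatim, including the
censored "<5" entries and the one zero-duration clinic study, which is
kept as an unscored row so cohort accounting stays correct).
Conventions that the printed headline numbers depend on:

- positive class = abnormal; metrics reported to one decimal, half-up;
- severity is scored per study night on three classes, with predicted
  class derived from the per-night predicted AHI and actual class from
  the gold-standard AHI (recorded labels are a fallback);
- Bland–Altman differences are actual − predicted (positive bias =
  device underestimates), limits are bias ± 1.96 × population SD, and
  only the 20 study nights with numeric AHI on both sides enter the
  agreement, error and correlation statistics;
- the bias (2.06) and lower limit (−25.53) reproduce to two decimals;
  the upper limit computes to 29.66 against a printed 29.69 — limits of
  agreement are by construction symmetric about the bias, and no
  symmetric pair rounds to both printed values, so agreement at one
  decimal (29.7) is the attainable precision;
- the paired HSAT-wear comparison imputes censored nights at 2.5
  events/h (midpoint of the normal range) before per-subject averaging;
  the imputation is a documented convention, and only the qualitative
  conclusion (no significant effect, p > 0.05) is asserted;
- the cohort-mean AHI threshold mentioned alongside the pilot scatter
  (3-sigma cutoff 40.35 events/h) is not recomputable from the tables
  and is not used anywhere in the pipeline.

## What the simulator emulates — and what it does not

The generator produces 4-channel recordings whose composite contains
breathing at 0.2975 Hz, a BCG pulse at 1.1125 Hz amplitude-modulated by
the breath waveform and by a 0.07 Hz low-frequency hemodynamic cycle,
random-walk drift, white sensor noise, and occasional movement bursts.
Events suppress respiratory amplitude for 10–60 s (Poisson onsets,
disjoint), with labored slow effort during the obstruction and a brief
recovery hyperpnea after it.

The oscillator frequencies are chosen so that steady sleep places
narrowband power *inside* the six analysis bands (0.07; 0.2975 + 0.07 =
0.3675; 3×0.2975 + 0.07 = 0.9625; 4×0.2975 = 1.19; 1.1125 + 0.2975 =
1.41), and they are held metronomically stable. That stability is the
central idealization: shape statistics such as sub-band skewness and
kurtosis respond to the *line-to-floor contrast* within a band, not to
absolute power (they are scale-free), so a carrier that wanders by even
a few hundredths of a hertz over a night smears across a 0.02 Hz band
and destroys the statistic regardless of disease. Real breathing and
heart rate wander far more; real devices cope because their feature
bands were selected empirically on real spectra. Consequently, passing
the simulation-based tests demonstrates that the pipeline machinery —
preprocessing, feature extraction, two-stage fitting without leakage,
the windowed protocol — recovers a planted severity signal; it does not
demonstrate that these six fixed bands are informative for any
particular real sensor installation.

Other non-goals of the generator: no sleep staging or REM structure, no
position changes, no night-to-night first-night effect (only ±20% AHI
jitter around a subject's latent severity), no inter-subject anatomy
differences beyond the event process itself.

Default cohort composition mirrors a small clinical screening
population: 6:5:3 normal : mild : moderate/severe, subject AHIs uniform
within class ranges (0–4, 6–15, 16–45 events/h).

## Numerical choices

- Band grid anchored at 0 Hz, half-open intervals [k·0.02, (k+1)·0.02);
  a band needs ≥ 3 FFT bins, hence the 150 s minimum signal duration.
- Single full-length FFT, rectangular window by default (keeps Parseval
  exact; Hann available). Moments are computed on raw magnitudes, not
  squared power.
- Skewness: adjusted Fisher–Pearson; kurtosis: excess, bias-corrected
  (normal → 0). A zero-variance band reports 0 for both, with a warning.
- Standardization uses the population (n) SD so spectral magnitudes are
  exactly reproducible.
- Butterworth order 4 applied forward–backward; the default lower cutoff
  0.05 Hz preserves the slowest feature band (0.06–0.08 Hz) while
  removing drift.
- Test and acceptance simulations use 3-h nights sampled at 25 Hz — the
  same generator as the 250 Hz default, scaled so the suite completes in
  minutes; 25 Hz leaves the 5 Hz filter edge well inside Nyquist and the
  features depend only on sub-5 Hz content.

## Known limitations

- The six fixed bands encode the pilot device's geometry and cohort; a
  different bed, sensor layout or population would need re-selection
  (the `anova_select` routine exists for exactly that).
- Censored "<5" outputs make the estimator non-informative within the
  normal range; rank-based comparisons impute 2.5 events/h.
- The windowed protocol's outlier threshold (10 events/h) is a fixed
  default; very short nights (< one window) cannot be scored.
- Severity grading inherits the regression's compression of extreme
  AHIs: the pilot's one very severe study (73 events/h) was predicted an
  order lower while still classed moderate/severe, and the same behavior
  should be expected here.
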