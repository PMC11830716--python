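# Methods

## The analysis problem

The pipeline targets a specific experimental design: subjects listen
to six one-minute music pieces, each conveying one emotion (fear,
sadness, anger, calmness, happiness, tension), and read a short text
aloud starting at the 40-second mark. Five frontal EEG channels (F7,
Fp1, Fz, Fp2, F8) are recorded at 1000 Hz; a mono audio track captures
the read-aloud interval. The scientific questions are (i) whether the
band-wise variability of the EEG differs between emotions, separately
for the quiet (30–40 s) and speaking (40–50 s) windows, and (ii) how
well the emotion can be decoded from short EEG slices using different
feature families.

Because no public dataset with this design exists, the package ships a
synthetic generator that produces data with the statistical structure
the analysis assumes. All empirical statements in this document refer
to that synthetic data; the tests and `scripts/acceptance.py` compute
every number quoted here.

## Synthetic data model

Each channel of a trial is a sum of independent components:

* **Five band-limited oscillations**, one per rhythm (δ, θ, α, β, γ),
  generated as order-4 Butterworth-filtered Gaussian noise. Each
  component is normalised by its realised spectral power inside the
  band (Parseval over the in-band DFT bins), so the configured band
  power is reproduced exactly as the measured band-limited variance —
  empirical total-variance normalisation would under-represent bands
  with proportionally wide filter transition regions.
* **A narrow alpha component** (1 Hz-wide, order 2) carrying 70 % of
  the alpha power, centred at an emotion-dependent frequency.
* **Broadband sensor noise** (SD 3 µV), **slow drift** (low-pass
  < 0.3 Hz Gaussian noise, SD 10 µV; stationary, and removable by the
  0.5 Hz band edge, which is the property the preprocessing relies
  on), and **50 Hz line interference** (5 µV sinusoid, random phase).
* During the speaking window: a per-band multiplicative power gain
  plus **EMG-like high-passed (> 20 Hz) noise** (SD 2.5 µV). This
  emulates speech contamination as extra high-frequency power without
  claiming physiological fidelity.

The recording extends 0.3 s beyond the stimulus at both ends, so the
alignment stage is always exercised. Per-subject log-normal channel
gains (SD 0.05) add between-subject variability. Units are nominal
microvolts; no downstream statistic depends on the absolute scale.

### How emotions are encoded — and why three feature families differ

Emotion identity enters the generator through two separate routes:

1. **Band powers.** Each emotion multiplies each band's power by
   `exp(effect_size * channel_sensitivity * offset)`, with offsets
   below 0.1 in log units (roughly ±10 % power). A second offset set
   applies only while speaking, so the between-emotion contrast is
   larger in the speaking state — the spatial/state pattern the
   significance analysis is meant to detect. Channel sensitivities
   are 1.0 on Fp1/Fz/Fp2 and 0.15 on F7/F8, giving the
   midline-frontal dominance in the ANOVA tables.
2. **Alpha peak position.** The narrow alpha component sits at
   `10.5 + effect_size * o_e` Hz with per-emotion offsets
   `o_e ∈ {−1.5, −0.9, −0.3, 0.3, 0.9, 1.5}` — 0.6 Hz spacing.

Route 1 is visible to every feature family (band variance, band
power, leaf energies alike). Route 2 is visible only at sub-band
resolution: the 0.5 Hz wavelet-packet leaves resolve the 0.6 Hz
spacing, the 2 Hz periodogram bins blur neighbouring emotions
together, and band-level statistics cannot see it at all. This is the
designed reason the held-out accuracies order as
wavelet > psd > stats on synthetic data, mirroring the qualitative
finding the pipeline is built to study. The effect sizes are free
parameters of the generator, not estimates of any real recording;
with `effect_size=0` both routes vanish and the six classes are
exchangeable, which the chance-level controls use.

What the generator does **not** emulate: volume conduction and
channel correlations, eye-blink/movement artifacts, non-stationarity
within a state, subject-specific spectral shapes, or any genuine
physiology of emotion. Passing tests therefore demonstrate that the
pipeline's machinery is correct and calibrated — not that these
accuracies would transfer to real EEG.

## Preprocessing

Order of operations: align → downsample → centre → notch → segment →
band-pass.

* **Alignment** keeps exactly `[stim_start, stim_end)` using the
  stored per-sample timestamps; trial time is seconds from stimulus
  onset and windows are half-open.
* **Downsampling** 1000 → 256 Hz uses polyphase resampling (32/125)
  with its built-in anti-aliasing low-pass; the ratio is non-integer,
  so plain decimation is not available.
* **Notch**: second-order IIR at 50 Hz, quality factor 30, applied
  forward-backward. Whether the notch precedes or follows
  downsampling is an open design choice; it is applied after, where
  50 Hz still lies below the 128 Hz Nyquist.
* **Band-pass**: order-4 Butterworth per rhythm, applied
  forward-backward (zero phase, effective order 8) so band-SD
  features are not phase-distorted.
* **Segmentation**: consecutive non-overlapping 5-s slices (1280
  samples); a slice is labelled *speaking* iff it lies inside the
  40–60 s read-aloud interval. Only the 30–40 s (quiet) and 40–50 s
  (speaking) windows enter the analysis datasets; the remaining
  slices are produced but excluded, since speech onsets cluster 2–4 s
  into the interval and end within ~14 s.

Filtering is linear and centring idempotent; both are asserted as
property tests.

## Feature families

All families are computed per 5-s slice and channel.

* **stats** (150 columns): mean, variance (N−1), SD, bias-corrected
  skewness and excess kurtosis, and average power (mean square) of
  each band-filtered signal.
* **psd**: periodogram `P_k = |X_k|²/N` of the broadband slice
  (Parseval holds exactly under this normalisation and is asserted on
  every call path), log-averaged in 2-Hz bins over 0.5–44 Hz plus a
  log total power per band. Band-level summaries alone would
  duplicate the stats family's information; the binned spectrum is
  what gives this family its intermediate resolution.
* **wavelet**: full db4 wavelet-packet tree to level 8 with periodic
  boundary handling, which keeps the transform orthonormal (node
  energies sum to the signal energy to 1e−8 relative; verified
  against both Parseval and pywt). Natural tree order interleaves
  frequency because every high-pass branch mirrors its children's
  spectrum; leaves are re-ranked by the Gray-code rule
  `natural = f ^ (f >> 1)` before nominal 0.5 Hz bins are mapped onto
  bands (δ 7, θ 8, α 12, β 32, γ 28 leaves). The default feature is
  the log mean-square coefficient per leaf. Raw coefficient
  concatenation is available but not the default: packet coefficients
  are zero-mean with class information only in their variance, so
  class means coincide and a linear discriminant provably cannot use
  them.

## Fisher LDA

Implemented from the scatter matrices (within-class `S_w` as the sum
of per-class scatter, between-class `S_b` weighted by class counts);
projection directions are the leading generalized eigenvectors of
`(S_b, S_w + λI)`, at most c−1 of which carry a nonzero criterion
(five for six emotions). Numerical choices:

* **Ridge** `λ = 1e−4 · trace(S_w)/d` by default — mandatory for the
  wavelet family, where d (435) exceeds n (192 training rows) and
  `S_w` is singular; `λ = 0` raises an explicit singularity error.
* **Standardisation** of columns before the solve (an invertible
  affine map, so the criterion is unchanged where `S_w` is
  nonsingular, but the default ridge becomes scale-free).
* When d > n the eigenproblem is solved in the span of the centred
  data: `S_w` and `S_b` map the span to itself and every direction
  with nonzero between-class scatter lies inside it, so the
  restriction is exact while the solve drops from O(d³) to O(n³).
  Tested to agree with the dense full-dimension solve.
* **Sign convention**: each eigenvector's largest-magnitude component
  is made positive, for reproducibility.
* LDA is fitted on training rows only and applied to test rows;
  fitting on all rows (which leaks test labels) is available as an
  explicit option but never the default.

## Classifier and evaluation

The FCNN is a from-scratch numpy MLP: layers 5 → 512 → 1024 → 512 →
512 → 256 → 6, ReLU hidden activations (sigmoid available), softmax
output, cross-entropy loss (MSE available), Adam (lr 1e−3, batch 32),
50 epochs, all seeded. Per-epoch held-out accuracy is recorded;
best-epoch parameters are retained alongside final-epoch ones, and
both accuracies are reported, because best-epoch selection on the
evaluation set is optimistic. Evaluation follows the study's
conventions: confusion matrices as percentages of the whole test set
(all 36 cells sum to 100) and one-vs-rest ROC/AUC per emotion. The
6-way stratified 8:2 split of 1,440 slice rows gives 1,152/288. The
split is slice-wise, not subject-wise; slices of one subject can land
on both sides, so accuracies are optimistic relative to a
new-subject deployment. Baselines (AdaBoost, GaussianNB,
GradientBoost, KNN, RandomForest, SVM) are standard library
implementations run on the same LDA-reduced features.

## Endpoint detection

Classic dual-threshold voice-activity detection: 25 ms Hamming frames
with 10 ms hop; thresholds derived from the first 0.5 s (assumed
non-speech): `T_low = μ_E + 3σ_E`, `T_high = 5·T_low`,
`T_zcr = μ_Z + 2σ_Z`. A segment is seeded at the first frame above
`T_high`, extended while energy exceeds `T_low`, then while the ZCR
exceeds its threshold (energy-only mode available). Only the first
segment per window is reported, matching the single read-aloud event.
Thresholds are relative to the noise floor, so detection is invariant
to global gain, and raising `T_high` can only shorten or abolish the
detection. On 200 generated clips the detector recovers onsets within
0.25 s and durations within 0.5 s (typical errors are an order of
magnitude smaller).

## Significance analysis

Each 5-s analysis window contributes one band-SD observation per
channel and band (windows are not pooled, matching the slice-level
dataset sizes). Per (band, channel, state) a one-way fixed-effects
ANOVA compares the six emotions; the implementation delegates to the
standard library routine and is tested against a brute-force
sums-of-squares oracle and a Monte-Carlo type-I calibration (5 % ± 2
percentage points over 500 null replicates drawn from the generator's
band-limited noise). Bonferroni correction uses family size m = 50
(5 bands × 5 channels × 2 states), the value consistent with the
correction arithmetic the pipeline reproduces (0.0005 → 0.025,
0.0093 → 0.465); m is configurable. Pairwise contrasts use two-sided
pooled-variance t-tests (Welch by flag, and automatically when the
pooled variance degenerates), thresholded at raw α = 0.05 without
multiplicity correction — the 6×6 masks are descriptive displays, and
an optional correction can be applied to the returned p-matrices.

## Problem sizes and defaults

The packaged experiment runs 20 subjects × 6 stimuli (480 analysis
slices, 240 per state), a scale chosen so a complete run finishes in
a few minutes on one core while every stage still operates exactly as
it would at 120 subjects; all counts scale linearly through the same
code path. The acceptance script uses 200 endpoint-detection clips
and 500 ANOVA null replicates. The FCNN keeps the full
512/1024/512/512/256 architecture at this scale.

## Known limitations

* Synthetic effect sizes are design choices, not estimates; absolute
  accuracies are not comparable to any real recording.
* Slice-wise splitting leaks subject identity across the split (see
  above); subject-wise evaluation would require more subjects per
  class than the default scale provides.
* Best-epoch reporting inflates the headline accuracy; final-epoch
  numbers are always reported next to it.
* No artifact rejection (ocular/ICA) is implemented, and the audio
  path does no phonetic analysis — endpoints only.
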