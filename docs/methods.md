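# Methods

## Problem and pipeline

`preictal` implements per-patient seizure *prediction* from continuous
multichannel scalp EEG. Unlike seizure detection, the object of interest is
the **preictal** state: the interval of fixed, assumed length (the
*qualifying window*) immediately preceding each seizure onset. The pipeline
is a binary classification problem between preictal and interictal windows:

1. **Ingest** — EDF recordings are read; channels not present in every file
   of a patient are discarded so the feature space is constant across the
   whole record. No filtering or artifact rejection is applied.
2. **Segmentation** — each recording is tiled with non-overlapping 5-second
   windows; the trailing remainder is dropped. A window overlapping a
   seizure is *discarded* (ictal data carry no predictive value); a window
   wholly inside `[onset − qw, onset)` is *preictal*; everything else,
   including post-seizure time, is *interictal*. Precedence:
   discarded > preictal > interictal. Because published window lengths for
   this task range from minutes to hours, `qw` is a free parameter
   (defaults 15/30/60/120 min).
3. **Features** — per channel: nine time-domain descriptors (mean,
   variance, SD, skewness, kurtosis, zero crossings, range, peak |x|,
   trapezoid area of |x|); periodogram power in the six canonical bands
   δ 1–3, θ 4–7, α 8–13, β 14–30, γ₁ 31–55, γ₂ 65–110 Hz plus total power;
   7-level db4 wavelet detail energies (dyadic bands 64–128 … 1–2 Hz at
   256 Hz, the <1 Hz approximation band dropped); decorrelation time. Per
   channel pair: the signed normalized cross-correlation at the
   maximum-|ρ| lag. A raw mode (flattened window samples instead of
   features) is available for comparison.
4. **Sequences** — the classifier consumes ordered blocks of L consecutive
   same-label segments (stride 1, never crossing a label change or
   recording boundary). Each block is attributed to its last segment.
5. **Classifier** — a gated-recurrence (LSTM) network with a 30-unit ReLU
   dense layer and a 2-unit softmax head, trained with cross-entropy and
   Adam.
6. **Scoring** — segment-level sensitivity/specificity, and event-level
   scoring where a seizure counts as predicted if ≥1 of its qualifying
   segments is flagged, with a false-prediction rate (FPR) in alarms per
   monitored interictal hour.

## The recurrence and training

With `[g, x]` the concatenation of the previous hidden state and the
current input and φ the logistic sigmoid:

    i = φ(ω_i[g,x] + a_i),  f = φ(ω_f[g,x] + a_f),  o = φ(ω_o[g,x] + a_o)
    ȳ = tanh(ω_c[g,x] + a_c)
    y_t = f ⊙ y_{t−1} + i ⊙ ȳ,    g_t = o ⊙ tanh(y_t)

Three architectures are supported: LSTM_1 (1 layer × 32 cells), LSTM_2
(1 × 128), LSTM_3 (2 × 128). Forward pass, backpropagation through time
and Adam are implemented directly in NumPy; training is therefore
bit-reproducible from the seed, and the backward pass is verified against
central finite differences (relative error ~1e-9 at ε = 1e-5).

Defaults (all configurable): batch size 10, 10 epochs, learning rate
0.001, β₁ 0.9, β₂ 0.999, ε 1e-8, decay 0, sequence length L ∈ [1, 50],
dropout 0.2 after every recurrent layer (train-time only; no published
rate exists, 0.2 is a conventional choice). Weights are Glorot-uniform;
the forget-gate bias starts at 1 (remember-by-default), a standard
initialization that speeds early training. Features are z-scored with
training-split statistics (disable with `standardize=False`); mixed-unit
features (µV², counts, seconds) otherwise produce poorly conditioned
optimization.

## Numerical choices

- **Periodogram**: raw (no taper/averaging), one-sided, |rfft|²/N with
  interior bins doubled; band edges inclusive; total power excludes DC.
  Only power ratios matter downstream, so any consistent normalization is
  equivalent. γ₂ is truncated at Nyquist (with a warning) when fs < 220 Hz.
- **Wavelet pyramid**: db4 ("fourth Daubechies", 4 vanishing moments,
  filter length 8; configurable), periodized boundaries so the transform
  is exactly orthogonal — detail + approximation energies reproduce the
  signal energy to ~1e-15 relative, which the tests assert at 1e-8.
- **Zero crossings**: strict sign change; exact-zero samples are
  transparent (do not count, do not break a crossing pair). Deterministic
  under floating point.
- **Kurtosis** is non-excess (Gaussian → 3); skewness/kurtosis of a
  zero-variance window are 0 by convention.
- **Cross-correlation**: means removed, normalized by the two population
  SDs and by the per-lag overlap length (unbiased). The unbiased estimator
  can marginally exceed |1| at short overlaps; the reported coefficient is
  clipped to [−1, 1]. Lag ties on |ρ| (exact for periodic signals at
  whole-period lags) are resolved to the smallest |lag|, then the negative
  lag, after rounding |ρ| to 12 decimals so floating-point noise cannot
  break an exact tie. Default lag range is fs/2 samples (0.5 s).
- **Decorrelation time**: first lag k ≥ 1 with normalized autocorrelation
  ≤ 0, returned as k/fs; if none occurs within the window the value is
  censored at the window duration and flagged. Note that for white noise
  the lag-1 autocorrelation is ~N(0, 1/n), so the first non-positive lag
  is geometric(1/2) — about 2 lags on average, not deterministically 1.
- **EDF I/O**: reading goes through MNE, with amplitudes rescaled from SI
  back to the file's physical units; files whose channels declare
  different sampling rates are rejected rather than resampled. A minimal
  16-bit EDF writer produces fixtures whose round-trip error is bounded by
  the quantization step 2·max|x|/65535.

## Evaluation protocol

Class imbalance: interictal sequences are partitioned (seeded) into
disjoint subgroups the size of the preictal-sequence pool; a model is
trained per subgroup and segment metrics are reported as the subgroup
average. Balancing happens at the *sequence* level because a random
segment-level partition would destroy the temporal contiguity sequences
need when L > 1.

Train/test split: the default is a **time-blocked stratified split with a
purge gap**. Stride-1 sequences overlap in L−1 of L segments, so a random
split at the sequence level leaks near-duplicates across the partition; in
a negative control (no preictal signature at all) the random split
produced 0.99 "held-out" accuracy where chance is 0.5, entirely through
shared-segment memorization. The blocked split takes one contiguous chunk
per class as the test set (seeded random position) and drops training
sequences within L−1 segment indices of any test sequence. The leaky
random split remains available (`split="random"`) for comparison.

Event scoring applies the first subgroup's model to every scored sequence
across the full timeline (the train/test protocol for event-level scoring
is not standardized in this literature; this choice is recorded here).
False alarms are maximal runs of flagged truly-interictal segments; runs
with gaps within a refractory period (default 300 s) merge into one alarm,
and the raw flagged-segment count is reported alongside. Segments that are
not the last element of any length-L run (the first L−1 of each run) are
unscored.

## Synthetic data

The generator emulates just enough structure to give every pipeline stage
a ground truth: per-channel 1/f-weighted Gaussian noise (flattened below
1 Hz, 50 µV RMS) mixed with a shared component at configurable coupling;
seizures as 3× background-RMS 4 Hz oscillations; and a parametric preictal
signature — variance rescaled by `variance_ratio`, sparse ±spikes (rate
0.01/sample) sized to raise kurtosis by roughly `kurtosis_boost`, and
FFT-masked band components rescaled by `band_shift` multipliers. It does
**not** model real artifacts (eye blinks, EMG), montage geometry, or any
biophysics; passing tests demonstrate that the pipeline recovers effects
of known size and location, not clinical performance on patients.

Problem sizes used by the end-to-end checks (the package's own choice of
desk-scale study conditions): a 3-channel, 3.5-hour, 256 Hz recording with
five seizures and a strong signature (variance ratio 0.3, kurtosis boost
3, α-power ×3) for the positive run — expected event sensitivity ≥ 0.9
with FPR ≤ 0.5/h over ~2.1 interictal hours — and a 2-channel, 2-hour
recording with three seizures and the identity signature for the negative
control, where held-out accuracy should be ≈ 0.5. Across seeds the
negative control scatters roughly ±0.1 around 0.53: the blocked test chunk
is contiguous in time, so residual slow autocorrelation inflates the
variance of the accuracy estimate beyond the binomial bound (and leaves a
small optimistic bias). This is a property of any temporally blocked
evaluation of overlapping-sequence models.

## Known limitations

- Clinical-scale validation (multi-patient EDF databases, hours of
  recordings, leave-one-seizure-out protocols) is out of scope of the test
  suite; the CLI can run such data but no claims are made.
- No post-ictal exclusion buffer or lead-seizure clustering.
- The NumPy trainer is single-threaded-friendly and exact, but not tuned
  for large raw-mode inputs (flattened 5-s windows at 256 Hz give
  ~1280×channels input dimensions).
- EDF+ annotations-in-file, resampling and montage conversion are
  unsupported by design.
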