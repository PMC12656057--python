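# Methods

This note documents the models, conventions and design choices behind
ictalnet: what each stage computes, which parameters matter, what the
synthetic data does and does not emulate, and the numerical decisions a
maintainer would otherwise have to reverse-engineer from the code.

## Signal model and preprocessing

Recordings are real matrices (channels × samples) in microvolts at 250 or
400 Hz; both rates are handled natively and never resampled, so temporal
feature scales are preserved exactly. Preprocessing runs in a fixed order:

1. **Bandpass** — 4th-order Butterworth, 0.5–40 Hz, applied
   forward–backward (`sosfiltfilt`), i.e. zero net phase and an effective
   8th-order magnitude response. The passband covers the five clinical
   bands the feature extractor measures. Recordings shorter than the
   filter warm-up (~3× the filter order in samples) are rejected rather
   than silently padded.
2. **Notch** — second-order IIR notch at 60 Hz, quality factor 30, also
   zero-phase. The order/Q are our choice (unstated upstream); Q = 30
   gives a −3 dB width of 2 Hz, far from the 30–40 Hz band of interest.
3. **Montage** — the first 20 channels are retained and re-referenced to
   the average *of the retained 20* (not of all recorded electrodes; the
   alternative reading exists, but computing the reference over the kept
   channels makes the operation self-contained and gives an exact,
   testable invariant: every time-sample means to zero, and any
   common-mode signal is rejected).

A consequence of the 0.5 Hz high-pass edge worth knowing: its impulse
response lasts ~2 s, so narrowband stopband tests must separate the
steady-state component (which obeys the squared magnitude response, e.g.
|H(60 Hz)|² ≈ 0.013) from low-frequency edge transients that can reach the
middle of a 10 s record.

## Windowing and class balancing

Annotated events are cut into non-overlapping 10 s windows. An event of
duration d contributes ⌊d/10⌋ full windows; a trailing remainder < 10 s is
discarded; an event shorter than 10 s contributes exactly one window,
zero-padded *at the end* (keeping seizure onset at the window start). The
padding flag is metadata only — feature extraction treats the data as-is.

Minority classes are balanced by noisy duplication: copies of existing real
windows of that class (drawn with replacement) plus Gaussian noise with
per-channel SD equal to 1% of that channel's SD (≈40 dB SNR), until each
class reaches `round(0.2 × majority count)`. Balancing is applied to the
raw windows of the *training split only*, before feature extraction, so
validation data is never synthetic and noise propagates into both feature
domains consistently.

## Features

Per channel: mean, SD, max, min, IQR (linear-interpolation percentiles),
median, variance, mean absolute amplitude, line length; then the mean Welch
PSD over delta/theta/alpha/beta/high-beta. Conventions:

* Welch window `round(1.024 × fs)` samples (256 at 250 Hz, 410 at 400 Hz),
  Hann taper, 50% overlap (`nperseg // 2`), per-window constant detrend,
  one-sided density scaling. With these settings the integrated PSD of a
  broadband signal reproduces its variance to within a few percent
  (Parseval), which pins the normalization; power below the ~1 Hz window
  resolution is invisible to the estimator by construction.
* Band edges are half-open `[low, high)` so 4, 8, 13 and 30 Hz are counted
  once; the last band closes at 40 Hz to include the passband edge.
* Features come from filtered but otherwise raw µV signals. The 20 × 14
  matrix flattens row-major (channel-major) to 280 values.

## The network

Input 20 × 14 (electrodes spatial, features as channels):
conv 64/k7 (bias-free) → BN → ReLU → channel attention (r = 8) → maxpool/2 →
residual block 128/k5 → maxpool/2 → residual block 256/k3 → global average ∥
max pooling (512) → dense 512 → BN → ReLU → dropout 0.5 → dense 5 → softmax.
Residual blocks are conv→BN→ReLU→attention→conv→BN plus a 1×1 projection
skip, then ReLU. Total: 758,725 parameters, counting batch-norm rows as 4C
(scale, offset and both moving statistics). Fidelity details:

* The *first* convolution carries no bias (7·14·64 = 6272) while block and
  projection convolutions do (e.g. 5·64·128 + 128 = 41,088) — both pinned
  by the published per-layer counts, which we treat as authoritative over
  the in-text formula.
* The attention bottleneck MLP is shared between the average- and
  max-pooled paths, bias only on the expansion layer
  (2·C·C/r + C → 1088/4224/16,640 at C = 64/128/256).
* The attention gate is computed *literally* as σ applied inside each path
  and again after summation — an unusual double squashing that bounds the
  gate to (0.5, 0.881) but reproduces the published formulation;
  `double_sigmoid=False` switches to the conventional single-σ variant.
* Max-pooling is size 2/stride 2/valid (20→10→5); convolutions use "same"
  padding; head batch-norm precedes the ReLU.

The network, its backward pass and Adam are implemented in NumPy
(`ictalnet.nn`): im2col convolutions, batch-norm over all-but-channel axes
(eps 1e-3, moving-statistic momentum 0.99), argmax-routed pooling
gradients, inverted dropout. Every layer's gradient is verified against
central finite differences in the development history; initialization is
Glorot-uniform with an explicit seed, so inference and training are bit
reproducible.

## Training and evaluation

Adam (lr 1e-4, β₁ 0.9, β₂ 0.999), batch 32, ≤15 epochs. Per-sample loss
weights w_c = N/(K·N_c) with K the number of task classes. The plateau
schedule (factor 0.5, patience 3, floor 1e-6) monitors validation loss;
early stopping (patience 5, best-weights restore) monitors validation
accuracy — the monitored quantities are configurable because only the
early-stopping monitor is pinned upstream.

**Feature standardization.** The classifier z-scores the 280 features
using training-split statistics (stored as fitted attributes,
`standardize=True` by default). We deviate here from the "unnormalized
features into the network" formulation deliberately: the first batch-norm
layer normalizes per conv map *after* mixing, so it cannot equalize input
features whose scales span four orders of magnitude (line length ~10⁴
against ~0-mean amplitudes), and within the pinned budget (~600 Adam steps
at desk scale) the raw-scale network plateaus around 90% per-fold macro F1
on data a standardized linear probe separates perfectly. With
standardization the same budget reaches ~100%. Scale is part of the model,
never leaked from validation data.

**Folds.** Cross-validation is patient-exclusive: patients are sorted by
the global segment count of their rarest class (rarest first, seeded
shuffle breaking ties) and greedily assigned to the fold with the fewest
segments of that class (ties: fewest total segments, then lowest index).
Tie-breaking is our documented choice; the upstream description fixes only
the ordering principle. A class contributed by fewer than k patients
triggers a warning and is necessarily absent from some folds; its
per-class metrics are NaN there and excluded from macro averages (with a
warning). Patient disjointness of every train/validation pair is asserted
at run time, not assumed.

**Metrics.** One-vs-rest TP/FP/FN/TN per class; sensitivity, specificity,
precision, F1 as percentages; unweighted macro averages; row-normalized
confusion matrices. Cross-fold summaries use the t distribution:
mean ± t₀.₉₇₅,ₙ₋₁ · SD/√n with sample SD (n−1); for five folds the
multiplier is 2.776. (The source formulation prints "SD/5", but its own
printed intervals — e.g. 99.59 ± 0.28 → (99.24, 99.94) — only reproduce
with SD/√5, which is what we implement.)

## Synthetic cohorts

Background is pink noise (power ∝ 1/f, SD 20 µV) plus a per-channel alpha
sinusoid (9.5–10.5 Hz, ~10 µV, random phase) — the spectral structure the
band-power features assume for wakeful inter-ictal EEG. Signatures, chosen
to be unambiguous on the measured feature set (amplitudes are free
parameters; the source specifies phenomenology, not levels):

| class | signature |
|---|---|
| ABSZ | ~3 Hz spike-and-wave on all channels (120 µV spikes on 70 µV slow waves) |
| FNSZ | 13–35 Hz band noise + beta tone on a contiguous 4-channel block |
| SPSZ | intermittent 5–7 Hz bursts (~1 s on/off) on a 4-channel block |
| TCSZ | 2.5× background gain; sustained 10 Hz phase evolving into ~3–5 Hz bursting at 150 µV |
| TNSZ | sustained 31–38 Hz global tone, constant envelope |

Event durations are log-uniform over `duration_range` (default 4–120 s) so
both zero-padded and multi-window events occur. Default class proportions
follow the event mix of a large clinical corpus
(43 : 6924 : 942 : 247 : 380); counts use largest-remainder rounding.
Each cohort derives one root seed sequence, split per event by counter, so
cohorts are bit-reproducible and any event can be regenerated independently.

**What this does and does not show.** The generator guarantees class
separability (a linear probe on the 280 features reaches macro F1 1.0), so
passing pipeline tests demonstrates correct wiring, leakage-free
evaluation and trainability — not clinical performance. Real scalp EEG has
artifacts (EMG, eye blinks, electrode pops), inter-patient morphology
differences, drifting baselines and far noisier signatures; none of these
are modelled beyond additive noise. Myoclonic seizures are excluded.

**Scale of the shipped checks.** The end-to-end recovery check uses 500
events across 25 patients with *equal* class proportions. At the default
corpus imbalance, 500 events contain only ~2–3 absence events, so that
class cannot reach all five folds and per-fold recovery would rest on one
or two segments of a single unseen patient — a sample-size degeneracy, not
a property of the method. Equal proportions make per-fold recovery
well-defined; the imbalance machinery (class weights, balance plans,
cohort apportionment) is tested separately at the corpus mix.

## Complexity and power audit

FLOPs: 2·n·k·C_in·C_out per convolution with n the *output* spatial
length, 2·N_in·N_out per dense layer, attention MLPs counted per pooling
path; batch norm, activations and pooling excluded (~5% extra in
practice). Under this convention the convolutional total is ≈6.1 M FLOPs;
published figures computed under other conventions (e.g. counting
pre-pooling lengths, or MACs vs FLOPs) will differ, and the report makes
no attempt to reconcile them. Model size is parameters × 4 bytes, reported
in decimal MB (758,725 → ≈3.0 MB). Power is P_idle + (P_max − P_idle) ×
utilization (defaults 2.7/6.4 W), rounded to one decimal; battery life is
capacity/power (37 Wh ≈ 9.25 h at 4.0 W). Attention entropy is Shannon
entropy of the normalized weight vector divided by log C (base-free), 1
for uniform gating, 0 for one-hot.

## Known limitations

* The NumPy training loop is single-core and unbatched across folds;
  cohorts beyond a few thousand segments become slow.
* The EDF writer is minimal (16-bit, 1 s records, symmetric physical
  range, zero-padding to whole records) — sufficient for round trips and
  interchange, not a general-purpose exporter; annotations travel in a CSV
  sidecar rather than EDF+ annotation channels.
* With ~600 gradient steps the double-sigmoid attention gate barely
  differentiates (its output range is compressed); attention-map analyses
  on desk-scale runs reflect initialization more than learned structure.
* `estimate_flops` audits the canonical topology family (three stages,
  two residual blocks); arbitrary architectures are out of scope.
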