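# Methods

## Scope and model

The package implements a stacked fusion architecture for multi-label
arrhythmia detection: independent 1-D CNN "channel models" learn
representations of the raw multi-lead signal, a hand-crafted branch
contributes nine HRV indices plus demographics, and the concatenated
multi-resolution representation (MRR) trains a gradient-boosted
classifier per cross-validation fold, fused by majority voting. The
original study of this architecture ran on ~20k clinical 8-lead records
with 34 long-tailed label categories on GPU hardware; this package
reproduces the *method* end to end at desk scale on synthetic data, plus
the internal arithmetic of the published result tables. Absolute
clinical-scale scores are out of scope.

## Synthetic data generator

Records are template-based: each beat is a sum of five Gaussian bumps
(P, Q, R, S, T) with fixed offsets/widths; R-peak times follow
`RR = 60000/heart_rate_bpm + N(0, rr_jitter_sd)` ms. Premature beats
are one shortened coupling interval (0.6×base) followed by a
compensatory pause (1.4×base), never two ectopies in a row. Leads share
one waveform scaled by a fixed per-lead amplitude profile (V1 negative),
and white Gaussian noise is added at a configured record-level SNR
(default 25 dB). Age is uniform on [18, 90); gender is a fair coin.

The generator reproduces the statistical structure the pipeline's
features respond to — rate, rhythm irregularity, ectopy, amplitude — and
none of the morphological subtleties of real ECG (no baseline wander, no
powerline interference, no beat-to-beat morphology change, no
conduction-block waveshapes). Passing tests therefore demonstrate that
the pipeline's math and plumbing are correct and that its features
separate rhythm-level classes; they do not demonstrate clinical
recognition performance. Eight rhythm classes have ready-made specs; the
full 34-name class universe is available so label vectors have realistic
width. Everything is deterministic given the config seed (per-record
seeds are spawned from one root sequence).

## Preprocessing

Denoising: db6 wavelet, decomposition to level `min(8, max feasible)`,
soft universal threshold `σ·sqrt(2 ln n)` on all detail bands with the
robust σ from the finest band (MAD/0.6745); the approximation band is
untouched, so DC survives. Augmentations (training folds only):
amplitude scaling by `1+τ`, `τ ~ N(0, 0.1)` (the (0, 0.1) convention is
read as mean/SD), redrawn per copy; whole-signal translation, circular
by default so length and sample multiset are preserved (zero-fill is a
switch); one contiguous zero mask with length uniform on (0, 1] s at the
same position on all leads, applied with probability 0.5 per copy.

## HRV branch

R-peak detection is a Pan–Tompkins-style chain (5–15 Hz band-pass,
squared derivative, 150 ms moving-window integration, adaptive threshold
at 0.25× the 90th-percentile candidate height, 200 ms refractory period,
refinement to the band-passed extremum). The nine indices are SDNN
(population 1/N variance), max/min/mean RR, pNN50 with strict `> 50 ms`,
R density (peaks/s), RMSSD, and sample entropy of the RR series at m=1
and m=2 with tolerance `r = 0.2 × SD(series)` — the "two values" of the
sample-entropy feature. Sample entropy uses Chebyshev distance, excludes
self-matches, counts both template lengths over the first N−m start
positions, and returns an infinity sentinel when no (m+1)-template pair
matches; inside the feature vector that sentinel is capped at 10 and a
constant series scores 0. Records where detection finds fewer than two
beats yield an all-zero feature vector with `valid=False`, so fusion
never fails.

## Channel models

The layer framework (convolution, batch norm, pooling, dense, dropout,
Adam) is implemented in numpy with explicit backpropagation; gradients
are verified against central finite differences in the test suite.
Reference profiles: the inception family uses a 2-conv stem and nine
inception modules (1/3/5 kernels plus pooled 1×1 branch, channel totals
growing 256→832) with two auxiliary heads tapped after modules 3 and 6
— the taps sit at weighted-layer depths 10 and 16 of the 22-layer
reference stack; the residual family uses four stages (64–512 channels,
two blocks each). A `width` multiplier scales all channel counts and
`n_inception`/`stage_blocks` scale depth; the desk profile is width
0.25, two inception modules or two single-block stages, one aux tap.
Parameter counts are reported by `count_params`, not asserted against
the published clinical-scale counts (whose exact layer tables are not
available); the published overhead percentages are recomputed from the
published counts themselves.

SE gates squeeze each channel to its global average, pass a bottleneck
of reduction 16 (floored at width ≥ 1), and rescale channels by sigmoid
scalars. Both published variants exist: dense bottleneck ("fc") and the
same bottleneck realized by 1-D convolutions ("conv", kernel size
configurable, default 1). In the residual family the gate acts on F(x)
before the skip addition; in the inception family on the concatenated
output.

Losses: class weights `w_i = 1/ln n_i` use the natural log (the base is
a uniform rescale and cannot change class ranking); training-fold counts
are clamped at 2 before the log. Probabilities are clipped at 1e−7
inside logs. The loss is the mean over (record, class) pairs; auxiliary
heads use the same class weights (symmetry — nothing suggests
otherwise) with the 0.3/0.3 composite weighting.

Deep features default to the last dense layer's pre-sigmoid outputs
(dimension C); the phrase "middle-layer features from the last fully
connected layer" is ambiguous, so the penultimate pooled representation
is available via `feature_source="pooled"`.

## Training protocol

Folds come from hand-rolled iterative multi-label stratification
(rarest class first, each record to the fold most short of that class,
capacities n/k ± 1): no installed library offers a multi-label
stratified k-fold. Within a round, fold f is the untouched test fold,
fold (f+1) mod k validates (model selection = best validation micro-F1),
and the remaining k−2 folds train — i.e. a 3/1 train/validation split of
the non-test folds at k=5. Defaults: Adam, lr 0.001, 50 epochs, ×0.1
drops when the epoch count reaches 35 and 45, batch 32, batch norm after
every convolution, dropout before the head. All randomness (folds,
initialization, batching, augmentation, dropout) flows from one root
seed through named substreams; two runs with one seed are bit-identical.

Desk-scale study conditions (used by the demonstration run, the
end-to-end tests and the acceptance script): 200 records, two cleanly
separated rhythm classes (50 vs 150 bpm), 100 Hz sampling for the deep
stage (R-peak tests use the 500 Hz default), tiny model profiles,
6 epochs at lr 0.003 with one drop at epoch 5. These were fixed once as
a configuration a single CPU handles comfortably; the demonstration task
is intentionally easy, and all schemes saturating near F1 = 1 is the
expected outcome, not a finding.

## Fusion and evaluation

The MRR column order is recorded in a schema (deep parts per model, nine
HRV columns, age/100, gender one-hot with unknown as zeros) and
validated at build time. The boosted stage is one binary LightGBM model
per label per fold (leaf-wise growth, 80 rounds, 15 leaves,
deterministic single-thread mode); how the original multi-label stage
was factored is unstated, so one-vs-rest was chosen as the conventional
reduction. Labels in a training fold with only one value get a constant
predictor. Thresholds are 0.5 per label; fold predictions fuse by strict
majority (ties at even k resolve negative; at k=5 ties cannot occur).

Within cross-validation, k−1 of the k voters saw any given record during
training; every report therefore also carries leakage-free held-out
scores (each record predicted only by its own fold's artifacts) and
`scheme_2` reports flag that concatenated fold-model features inherit
this exposure. The held-out path is the scientifically meaningful score;
the voted path exercises the fusion rule.

Micro averaging (pool TP/FP/FN, then P/R/F1) is the default, consistent
with pooled-count phrasing of the published evaluation; macro is a flag.
All 0/0 ratios resolve to 0.

## Numerical and tolerance choices

* Published-table consistency: printed P/R carry 4-decimal rounding;
  propagated through 2PR/(P+R) this allows up to ~1e−4 discrepancy,
  plus 5e−5 for the printed F1's own rounding — hence the 1.5e−4
  tolerance (derived a priori, not fitted). The fused row reproduces to
  all four printed decimals.
* The published relative-gain list includes one value (for the inception
  baseline) that differs in the last digit when recomputed from the
  rounded table F1s; it is excluded from the recomputed targets as a
  rounding artifact of unpublished precision.
* R-peak recall is scored with a ±50 ms match window; the jitter-free
  recovery test requires RR = 1000 ms within one sample at 500 Hz.
* Gradient checks accept 1e−4 relative error against central
  differences at ε = 1e−6.

## Known limitations

* The generator's realism ceiling (above): morphology-level classes
  (e.g. bundle-branch blocks, ST/T changes) are not distinguishable in
  the synthetic data; only rhythm/amplitude classes are exercised.
* Channel models at reference depth are CPU-trainable but slow; the
  shipped configurations are desk-scale. Parameter counts at reference
  width do not match the (unavailable) clinical-scale layer tables.
* Frequency-domain HRV, ectopic RR correction, 12-lead derivation and
  streaming input are out of scope.
* WFDB-format reading is not included; the on-disk dialect is the
  package's own columnar CSV + JSON manifest.
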