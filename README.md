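# mrrecg

Multi-label arrhythmia detection on multi-lead ECG via a
**multi-resolution representation (MRR)**: several 1-D convolutional
channel models learn deep feature vectors from the raw 8-lead signal,
these are concatenated with nine hand-crafted heart-rate-variability
(HRV) indices plus age and gender, and the fused vector trains a
gradient-boosted multi-label classifier per cross-validation fold; the
fold classifiers vote on the final label set.

The package is aimed at researchers who want a self-contained,
CPU-scale, fully deterministic implementation of this stacked
deep + hand-crafted fusion architecture — including a synthetic 8-lead
ECG generator, so every stage runs and is testable without any clinical
dataset.

## The method

Each record is an 8-lead signal (leads I, II, V1–V6; 500 Hz, 10 s by
default) with age, gender, and a binary label vector over C arrhythmia
categories. The pipeline:

1. **Denoise** each lead with a db6 wavelet decomposition and universal
   soft thresholding of the detail coefficients.
2. **Channel models.** Four 1-D CNN families — a GoogLeNet-style
   inception network (with two auxiliary classifier heads), a residual
   network, and squeeze-and-excitation (SE) variants of both — train as
   multi-label classifiers with imbalance-weighted binary cross-entropy:

       loss(x, y) = mean_i( −w_i [ y_i log x_i + (1−y_i) log(1−x_i) ] ),
       w_i = 1 / log n_i

   where `n_i` counts training records positive for class i. Networks
   with auxiliary heads minimize
   `Loss = Loss_main + 0.3·Loss_aux1 + 0.3·Loss_aux0`.
   Training-fold records are augmented by amplitude scaling with
   `(1+τ), τ ~ N(0, 0.1)`, whole-signal translation, and random
   zero-masking of up to 1 s.
3. **Hand-crafted features.** R peaks are detected on lead II
   (Pan–Tompkins-style) and nine HRV indices computed: SDNN, max/min/
   mean RR, pNN50, R-wave density, RMSSD, and sample entropy of the RR
   series at m=1 and m=2.
4. **Fusion.** Per record, the channel models' feature vectors are
   concatenated with the HRV indices, age/100 and a gender one-hot into
   the MRR; one LightGBM model per label per fold learns from it.
5. **Voting.** The k fold classifiers each predict every record; a label
   is positive on strict majority (k=5 → ≥3 votes). Evaluation is
   micro-averaged precision / recall / F1 from pooled per-class
   TP/FP/FN.

Both training stages share one multi-label-stratified fold plan,
enforced by a content hash, so the classifier stage provably reuses the
channel-model splits.

## Worked example

```bash
mrrecg run --seed 0 --run-dir runs/demo
```

trains the full demonstration pipeline — 200 synthetic records (sinus
bradycardia vs sinus tachycardia, 100 Hz), four tiny channel models,
5 folds — in a few minutes on one CPU and prints:

```
scheme_1:googlenet           precision=1.0000 recall=1.0000 f1=1.0000
scheme_1:resnet              precision=1.0000 recall=1.0000 f1=1.0000
scheme_1:se_inception        precision=1.0000 recall=1.0000 f1=1.0000
scheme_1:se_resnet           precision=1.0000 recall=1.0000 f1=1.0000
scheme_2:googlenet           precision=1.0000 recall=1.0000 f1=1.0000
scheme_2:resnet              precision=1.0000 recall=1.0000 f1=1.0000
scheme_2:se_inception        precision=1.0000 recall=1.0000 f1=1.0000
scheme_2:se_resnet           precision=1.0000 recall=1.0000 f1=1.0000
multi_model_mrr              precision=1.0000 recall=1.0000 f1=1.0000
```

(output of this exact command, seed 0)

`scheme_1` is direct voting of one family's five fold sub-models;
`scheme_2` fuses that family's five fold feature vectors into a
single-family MRR before the boosted classifier; `multi_model_mrr` is
the full method. The two demonstration classes are deliberately well
separated (50 vs 150 bpm), so all schemes saturate — the run
demonstrates the machinery, not a hard benchmark. The run directory
holds the fold plan, per-fold checkpoints and `report.json`; re-running
with the same seed reuses cached stages and reproduces the report
exactly.

Other entry points: `mrrecg simulate` writes a synthetic labelled
dataset as plain CSV + JSON; `mrrecg hrv` emits one nine-column HRV
feature row per record; `mrrecg evaluate` prints the headline scores of
a finished run.

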