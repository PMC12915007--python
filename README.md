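# drivemeg

Analysis toolkit for dual-task neuroergonomics studies that combine
whole-head MEG with eye tracking and driving telemetry in a 2 × 3
within-subject design (visuo-spatial workload: low/high × speech valence:
low/neutral/high).  It implements the full oscillatory-power and decoding
pipeline such studies run, together with a synthetic-cohort generator that
plants known condition effects so every stage can be validated against
ground truth.

## What it computes

**Oscillatory source power (main effects).**  Sensor blocks are cut into
non-overlapping 5-s epochs, cross-spectral density matrices are estimated
with Morlet wavelets (3 cycles, 1–42 Hz), and source power is obtained with
the DICS beamformer: per vertex *v* the spatial filter is

    w_v = (l_vᵀ S_r⁻¹ l_v)⁻¹ l_vᵀ S_r⁻¹,   S_r = Re(CSD) + γ·mean(diag)·I,

applied after pre-whitening with the (Ledoit–Wolf-shrunk) empty-room noise
covariance.  Per-vertex spectra are parameterized into an aperiodic 1/f
component, log₁₀P(f) = offset − χ·log₁₀f, plus Gaussian peaks (peak widths
2–6 Hz, ≤ 7 peaks, fixed mode); the aperiodic part is subtracted in linear
space, individual alpha/beta/gamma peaks (8–12 / 15–25 / 30–42 Hz) are
detected, and band power is averaged in a 2 Hz window around each peak.
Baseline-relative changes enter a per-vertex 2 × 3 repeated-measures ANOVA;
suprathreshold vertices (parametric F quantile, p < .05) are clustered by
grid adjacency and cluster mass (ΣF) is tested against a within-subject
permutation null (max-mass distribution, n = 5,000 by default).  Post-hocs
use Wilcoxon signed-rank tests with Benjamini–Hochberg FDR and
5,000-iteration percentile-bootstrap CIs; Spearman correlations relate
cluster powers.

**Interaction decoding (MVPA).**  Blocks are FIR band-passed to 30–42 Hz,
cut into 2-s epochs, and the four emotional-speech × workload conditions
are decoded per subject with multiclass CSP (whitened approximate joint
diagonalization of the class covariances, four log-variance components) and
an LDA (least-squares solver, Ledoit–Wolf shrinkage) under repeated
stratified 10-fold × 3 cross-validation (30 folds).  Decoder filters are
converted to activation patterns via the Haufe transformation
A = ΣW(WᵀΣW)⁻¹, localized with a depth-weighted (0.8) minimum-norm inverse
(SNR 3 for patterns, SNR 1 for power), averaged across subjects weighted by
their F1 scores, and gamma source power is contrasted over the vertices
above the 90th percentile of the pattern map.

**Behavioural measures.**  Gaze: duration-weighted RMS dispersion from the
duration-weighted centroid, blink rate, median pupil diameter during
fixations (after cubic-spline blink interpolation with 50 ms padding and a
500 ms gap limit, 20 ms rolling median, 1–9 mm masking), and the Index of
Pupillary Activity (thresholded wavelet modulus maxima, events/s), all
baseline-corrected against the preceding baseline block.  Driving: RMSSD
of acceleration and steering rate, mean brake actuation, lane deviation
excluding ±2 s around lane changes, violation counts, aggregated into a
min-max-normalised, inverted composite score in [0, 1].

## Worked example

`examples/03_decode_interaction.py` generates a 5-subject cohort with a
planted cross-over gamma interaction (LV > HV at low workload, reversed at
high workload) and decodes the four conditions:

```
mean F1 across subjects: 0.363 (chance for 4 classes: 0.25)
pooled confusion matrix (rows = true, cols = predicted):
           HW/HV   HW/LV   LW/HV   LW/LV
   HW/HV     135      42      27      96
   HW/LV      41     103     102      54
   LW/HV      38     119     103      40
   LW/LV     123      35      34     108
90th-percentile ROI gamma-power contrasts:
  LW/LV - LW/HV: diff +0.0032, p_fdr = 0.094
  ...
  HW/LV - HW/HV: diff -0.0028, p_fdr = 0.094
```

Decoding is well above the 4-class chance level of 0.25, and the errors are
structured: the decoder confuses exactly the condition pairs that share a
planted gamma level (LW/LV ↔ HW/HV and LW/HV ↔ HW/LV), while the ROI
contrasts reproduce the planted sign reversal (LV − HV positive under low
workload, negative under high workload).  The other examples cover cohort
generation (`01`), DICS + permutation clustering (`02`) and the
gaze/driving measures (`04`).

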