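# Methods

## The model of the data

The package analyses a within-subject 2 × 3 factorial experiment:
visuo-spatial workload (LW, HW) crossed with the valence of concurrently
presented speech (LV, NV, HV), recorded as multichannel sensor time series
(an MEG analogue), gaze/pupil streams and driving telemetry.  Conditions
are ordered workload-major — `LW/LV, LW/NV, LW/HV, HW/LV, HW/NV, HW/HV` —
everywhere, and every experimental block has a preceding baseline block
used for baseline-relative power and behavioural baseline correction.

The sensor model is linear: `x(t) = L s(t) + n(t)` with a known gain
matrix `L` (lead field).  The synthetic forward model is deliberately
abstract — sources sit on a subdivided icosahedral unit sphere and project
through a spatially smooth Gaussian kernel of chordal distance between
sensor directions and source positions, plus a small random perturbation
that guarantees full column rank.  Beamformer and minimum-norm mathematics
only require a known `L`; no anatomical head model, co-registration or
hemisphere bookkeeping is represented, and the source grid is a single
adjacency graph.  Sensor noise is diagonal-plus-low-rank (independent
channel noise plus a few shared environmental components), the same
structure the empty-room segment is drawn from.

## The synthetic cohort

Source signals are a sum of 1/f background and narrowband oscillators:

* **1/f background** — frequency-domain shaped Gaussian noise with PSD
  ∝ 10^offset / f^χ; per-source exponents are drawn uniformly from
  (0.8, 1.6) and offsets from (−0.5, 0.5), stored as ground truth.
* **Oscillators** — zero-phase 4th-order band-pass-filtered Gaussian noise
  (alpha 8.5–11.5 Hz, beta 18.5–21.5 Hz, gamma 34.5–37.5 Hz, so spectral
  peaks land at 10/20/36 Hz with realistic widths for the aperiodic
  fitter), with a default amplitude of 0.6 relative to the unit-variance
  background.

Planted effects multiply oscillator *power* inside a vertex patch by a
per-condition gain vector.  The stock configuration
(`StudyConfig.with_planted_effects`) emulates the qualitative findings the
analysis is designed to detect: a beta-power increase (×1.5) for emotional
speech, a gamma increase and beta decrease (×1.5, ×1/1.5) under high
workload, and a cross-over gamma interaction (×1.6 for LW/LV and HW/HV,
×1/1.6 for LW/HV and HW/LV).  Baseline blocks use all gains = 1.  Gaze and
telemetry blocks under high workload carry a +0.3 mm pupil offset, a
doubled pupil-step rate (1.0/s vs 0.5/s), a 30 % reduction in fixation
scatter ("visual tunnelling"), and 50 % higher acceleration/steering
volatility and lane noise.  Defaults are sized for desk scale — 12
subjects, 64 sensors, a 162-vertex (level-2 icosahedron) grid, 100 Hz
sampling, 300 s blocks; tests and examples run reduced cohorts (typically
5 subjects, 32 sensors, 40–60 s blocks) so that full pipeline runs stay in
the tens of seconds.

Everything is reproducible bit-identically from `(config, seed)`: a master
`SeedSequence` spawns independent child streams per subject and for the
empty-room segment.

**What the generator does not emulate:** real sensor physics (two sensor
types, gradiometer geometry), ocular/cardiac/muscle artefacts, head
movement, anatomical variability, speech audio, and any coupling between
the MEG, gaze and telemetry streams beyond shared condition labels.
Passing recovery tests therefore demonstrates that the *analysis* is
correct and calibrated under the assumed signal model, not that the model
captures every property of real recordings.

## Analysis choices

**Epoching and trial bookkeeping.**  Non-overlapping windows (5 s for the
spectral analysis, 2 s for decoding); the trailing partial window is
discarded.  Amplitude rejection uses the per-channel absolute maximum by
default (peak-to-peak offered), with per-sensor-group thresholds.  Trial
counts are equalized to the minimum by greedy deletion of the epoch whose
removal most reduces the summed pairwise difference of matched-rank onset
times across conditions, breaking ties toward the later onset — a
deterministic, auditable rule.

**Spectra.**  CSDs come from complex Morlet coefficients (3 cycles); band
CSDs average the bins inside the 2 Hz window around the individual peak.
PSDs use DPSS multitapers (2 Hz bandwidth) with Parseval-consistent
scaling.  The aperiodic fitter works in log₁₀ power: a robust line fit that
iteratively down-weights points above the backbone, iterative Gaussian peak
extraction from the residual (largest first, height above max(absolute
threshold 0, 1 residual SD), width clipped to 2–6 Hz, ≤ 7 peaks), an
optional joint least-squares polish of all peaks, and an aperiodic refit on
the peak-subtracted spectrum.  Bulk per-vertex fits skip the polish
(`refine=False`) since only the aperiodic component is consumed
downstream.  A numerical floor of 10⁻³ log-units prevents subtraction
residue from registering as peaks on noiseless spectra.  Periodic residuals
(linear-space subtraction) are *not* clipped at zero — clipping would bias
condition contrasts; where a baseline periodic band power is non-positive,
the pipeline falls back to raw band power for the relative-change ratio.
Band peaks absent from a cut-off range fall back to the band midpoint with
a logged flag.

**Source estimation.**  Whitening uses the eigendecomposition of the
Ledoit–Wolf-shrunk empty-room covariance with rank restriction.  DICS
filters are unit-gain (`w_v l_v = 1`) with diagonal loading at 5 % of the
mean CSD diagonal — the standard stabilisation for small grids; the real
part of the CSD enters the filter computation and power is the real part
of the quadratic form.  The frequency-resolved source spectra used for the
per-vertex aperiodic fits apply broadband filters (built from the common
across-condition mean CSD) to every per-frequency CSD.  The minimum-norm
operator is `M = R Lᵀ (L R Lᵀ + λ²C)⁻¹` with depth prior
`R_vv ∝ ‖l_v‖^(−2·0.8)`, `λ² = 1/snr²` (SNR 3 for pattern localization,
SNR 1 for band power), and no noise normalisation.  Sources are
fixed-orientation scalars; a loose-orientation weighting (factor 0.2 on
tangential components) is implemented for 3-orientation lead fields but is
not exercised by the default spherical model.

**Cluster statistics.**  The per-vertex statistic is a classical two-factor
within-subject ANOVA (each effect against its own subject-by-effect error
term; dfs (1, n−1) for workload and (2, 2(n−1)) for valence and the
interaction), vectorized over vertices and verified against a brute-force
sums-of-squares oracle and against an independent reference implementation
(pingouin).  The cluster-forming threshold is the parametric F quantile at
1 − α.  The permutation null re-labels all six cells independently within
every subject (the single-scheme reading of label reassignment); a
factor-restricted scheme is available via `scheme="factor"`.  Cluster
p-values use the positively biased estimator (1 + k)/(1 + N), and the
omnibus F is one-sided.  Wilcoxon signed-rank tests drop zero differences,
mid-rank ties, enumerate the exact 2ⁿ null for n ≤ 12 and otherwise use
the normal approximation with tie and continuity corrections.  BH-FDR is
delegated to statsmodels and tested against the step-up definition.
Bootstrap CIs are percentile intervals over subject resamples with
optional Bonferroni widening of the displayed tails.

**Decoding.**  The multiclass CSP whitens the four Ledoit–Wolf class
covariances by their grand average and jointly diagonalizes them with
orthogonal Jacobi rotations (closed-form Cardoso–Souloumiac angles,
numba-compiled; sweeps stop when the largest rotation sine falls below
10⁻⁷).  Components are ranked by the across-class variance of their
projected log-variances — a label-symmetric criterion — and the top four
retained; features are per-epoch log-variances.  The LDA uses sklearn's
least-squares solver with automatic Ledoit–Wolf shrinkage, exactly the
combination the decoding literature pairs with CSP features.  F1 is
macro-averaged (chance 0.25 for four balanced classes either way); the CI
bootstraps the 30 fold scores.  Haufe patterns are computed per fold from
the training epochs' Ledoit–Wolf covariance and sign-aligned to the first
fold before averaging (CSP filters are sign-indeterminate); averaging
precedes source projection.  The binary special case is cross-checked
against MNE-Python's CSP, which serves as an independent reference, never
as the implementation.

**Gaze.**  Preprocessing order is fixed: spline interpolation over
blink/artefact gaps (50 ms padding, gaps > 500 ms stay masked, boundary
gaps nearest-value-filled with a flag) → 20 ms centred rolling median →
masking outside 1–9 mm (masked, not clamped: out-of-range samples are
excluded, not invented).  The IPA counts modulus maxima of the level-2
detail coefficients of a Symlet-16 DWT that survive the hard universal
threshold λ = σ̂√(2 ln n), σ̂ = MAD/0.6745; one filter length of
boundary-affected coefficients is excluded at each segment edge (symmetric
extension otherwise produces spurious edge maxima), and masked runs split
the series into independently processed segments whose counts are summed
over the total valid duration.  Gaze dispersion is the duration-weighted
RMS distance from the duration-weighted centroid (the weighting of the RMS
itself is a declared choice; a single fixation yields 0 with a flag).

**Driving.**  Steering variability operates on the angular *rate*
(units rad/s).  Lane deviation excludes ±2 s around each lane change.  The
composite score min-max-normalises each of the five measures within a
subject's six blocks, averages, inverts, and min-max-rescales once more; a
measure constant across blocks contributes 0 for every block with a log
flag rather than propagating NaN.  Linear mixed-effects modelling of
subjective ratings is out of scope; group contrasts use the signed-rank /
FDR / bootstrap machinery throughout.

## Numerical and degenerate-input conventions

Zero error variance in the rmANOVA maps to F = +∞ (flagged), or 0 when the
effect variance is also zero.  All-epoch rejection, all-zero spectra,
constant pattern maps, empty ROIs, constant inputs to rank correlation and
degenerate signed-rank pairs raise errors naming the offending object.
Every stochastic routine takes an explicit seed; pipeline stages derive
child seeds from the run seed, so reruns are bit-identical.

## Problem sizes used in the validation suite

The test suite runs reduced cohorts chosen to keep full pipeline runs fast
while preserving every stage: 5 subjects × 32 sensors × 162 vertices with
40–60 s blocks for end-to-end recovery; 50 null and 20 planted-effect
cohorts of 12 subjects × 162 vertices at 200 permutations for the
type-I/power calibration of the cluster test; 20 seeds of 4 × 60–100
label-independent epochs for the chance-level anchor of the decoder.  The
acceptance script uses 20 seeds × 400 epochs × 64 channels.

## Known limitations

The equalization criterion, the band-midpoint peak fallback, the exact
DICS loading fraction and the component-ranking rule of the multiclass CSP
are declared conventions — reasonable defaults where the field has no
single standard, and all exposed as parameters.  The permutation test's
full-shuffle null is exchangeability-based and slightly conservative for
single main effects in the presence of a strong other-factor effect (the
factor-restricted scheme addresses this).  The spherical forward model
makes localization easier than real anatomy would; localization accuracies
measured here are upper bounds.
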