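# Methods

## Signal model and segmentation

A recording is a channels × samples voltage matrix at a fixed sampling
rate (default 1000 Hz, the usual rate for surface EMG whose physiological
content lies below ~450 Hz).  Cue-paced trials last 1.5 s: a 0.25 s onset
transient, a 1 s execution period, and a 0.25 s offset transient.  Feature
extraction uses only the execution period, where the contraction is
steady; transient periods are excluded because their non-stationarity
inflates within-class variance.

Window arithmetic is fixed as follows: sample indices are 0-based, window
intervals are half-open `[start, end)`, fractional sample counts from
`length_s * fs` are floored, the overlapped stride
`length * (1 - overlap)` is floored with a minimum of one sample, and
trailing partial windows are dropped.  These rules make the counts exact:
a 1 s execution period yields four disjoint 250 ms windows, and a 1 s
stream cut with 125 ms windows at 20% overlap (stride 100 ms) yields
`floor((1000 - 125)/100) + 1 = 9` windows.

## Preprocessing

The digital front end is an order-16 Butterworth band-pass (10–450 Hz)
followed by elliptic band-stops at 50 Hz and its harmonics (default
50/100/150/200 Hz, 2 Hz half-width).  All stages run forward–backward
(zero phase) so that waveform-shape features are not distorted; the
band-pass is therefore designed at half the nominal order.  The band-stops
use 0.01 dB passband ripple — with four cascaded stages each applied twice,
larger ripple would visibly sag the passband — and 40 dB stopband depth.
Filtering pads the signal by reflection for 0.5 s per side so notch edge
transients decay outside the retained samples.

ICA artifact removal runs FastICA with as many components as channels and
a fixed seed; non-convergence raises rather than silently returning a
partial fit.  The rejection rule is pluggable; the default flags
components with more than half their Welch power below 10 Hz, targeting
motion artifact and baseline drift, which concentrate below the EMG band.
With no rejections the reconstruction is the identity to ~1e-6, which the
tests assert.

MSPCA denoising decomposes each channel into wavelet sub-bands
(periodized DB4, 5 levels by default), applies PCA across channels within
each sub-band, and keeps components by a Kaiser-style rule (eigenvalues
above the eigenvalue mean) before reconstructing.  Retaining all
components reproduces the input exactly, so the retention rule is the only
lossy step.

SNR is reported as `10 log10(A_m² / A_r²)` where `A_m` and `A_r` are the
maximum windowed-RMS amplitudes of an active-muscle and a rest segment.

## Feature bank

The per-channel bank has exactly 42 dimensions.  The canonical order is
MAV, MMAV1, MMAV2, RMS, VAR, WL, ZC1–2, SSC, WAMP1–5, SSI, HEMG1–6,
AR1–4, MDF, MNF, STFT, APWC_D1–D6, APWC_A6, SDWC_D1–D6, SDWC_A6.
Definitions follow the conventions standard in the myoelectric
literature (Phinyomark et al.):

- MMAV1 weights `|x|` by 1 on the central half of the window and 0.5 on
  the flanks; MMAV2 uses the continuous ramp `4i/N` / `4(N-i)/N` on the
  flanks.
- ZC counts sign changes whose step also exceeds a deadband; SSC counts
  slope-sign reversals whose larger adjacent step exceeds a deadband;
  WAMP counts consecutive-sample differences above a threshold.
  Thresholds default to fractions of the window RMS (ZC: {0, 0.05}; SSC:
  0.05; WAMP: {0.05, 0.1, 0.2, 0.3, 0.4}) because fixed voltage
  thresholds do not transfer across gain settings; an absolute mode is
  available.  With zero thresholds the counters are scale-invariant, which
  the property tests exploit.
- HEMG is a 6-bin histogram over ±3 standard deviations of the window.
- AR coefficients come from Burg's method (stable on 250-sample windows,
  unlike Yule-Walker at this length); MDF/MNF are the half-area and
  power-weighted-mean frequencies of the Welch PSD (nperseg ≤ 256).
- The STFT feature is the mean of the spectrogram PSD — a single scalar
  summarizing short-time spectral power.
- Wavelet features use a 6-level periodized DB4 decomposition giving 7
  sub-bands (D1–D6, A6); APWC is the mean squared coefficient and SDWC
  the coefficient standard deviation per band.  Periodization makes the
  transform orthogonal, so sub-band energies sum to the window energy
  (exact at power-of-two lengths; the Parseval test uses 256 samples).
  Decomposing a 250-sample window 6 levels deep means every coefficient
  feels the boundary; this is accepted deliberately — the features are
  discriminative summaries, not reconstruction coefficients — and windows
  shorter than 2^levels are rejected.

## Separability criteria

**EC.** For feature *i*, the per-class variances are normalized to sum to
one across classes and `J_i = -Σ_k V_ki ln V_ki` with `0 ln 0 := 0`.
`J` is bounded by `ln(n_classes)`, attained exactly when all class
variances are equal — i.e. when the feature's variance carries no class
information — so features are ranked **ascending**.  If all classes have
zero variance the feature is assigned the maximum (least separable) value.

**FD.** For two classes, `D²(a,b)` is the mean squared difference over
all |a|·|b| ordered cross pairs (same-index pairs included) and `D²(a,a)`
the mean over all distinct unordered within-class pairs;
`J = D²(a,b) / (D²(a,a) + D²(b,b))`.  The implementation uses the closed
forms (cross mean = population variances plus squared mean gap; within
mean = twice the unbiased variance) and the tests verify them against
direct pair enumeration, including the hand-checkable instance
a = {0,1}, b = {3,4} → J = 4.75.  Multi-class separability is the mean of
the one-versus-all binary ratios; for two classes this reduces to the
plain binary ratio.  Zero within-class spread returns an infinite
sentinel with a warning rather than an epsilon fudge, so degenerate
features sort first and remain visible.  The ratio is translation- and
scale-invariant.

**RFE.** Features are z-scored, then a linear-kernel SVM (C = 1) is
retrained on the surviving set and the feature with the smallest squared
weight — summed over the one-vs-one weight vectors in the multi-class
case — is eliminated; the last survivor ranks first.  Removing the
smallest-|w| feature shrinks the squared margin norm the least, which is
the standard margin-based elimination criterion.  A linear kernel is used
inside RFE even when final classification is RBF, because the weight
vector is only defined for linear kernels.  Ties eliminate the earliest
feature in canonical order, and all rank ties throughout the module break
by canonical feature order, for reproducibility.

**Sweeps and aggregation.**  The optimal-feature-number (OFN) sweep
evaluates cross-validated accuracy at every subset size 1..d along a rank
and reports the smallest size attaining the maximum.  Cross-subject
aggregation min-max normalizes each report's separability values to
[0, 1], averages across subjects within a channel, sums across channels,
and takes the top k in the method's rank direction; for RFE it instead
counts how often each feature enters a report's top-k (with S subjects
and C channels the ceiling is S·C, e.g. 18 for 9 subjects × 2 channels).
Channel ranking scores each channel by the mean 10-fold CV accuracy over
all C(n,2) binary class problems using all 42 features, and keeps the top
two by default (a practical wearable-channel budget).

## Classification

Stratified k-fold cross-validation (10-fold, 5-fold for the ANN whose
training dominates runtime) pools out-of-fold predictions before scoring,
so each window counts once.  Stratification is used because at desk-scale
window counts unstratified folds can lose a class entirely.  Accuracy is
percent correct; the F-score is `2TP/(2TP+FP+FN)` per class, macro
averaged, computed from the pooled confusion counts (the tests cross-check
it against scikit-learn's macro F1).  Confusion matrices are
row-normalized to percentages.  kNN/ANN/SVM inputs are z-scored within the
training folds; the random forest is scale-free and takes raw features.
The SVM's C is grid-searched over {1, 10, 100} with 3-fold internal CV
and `gamma='scale'`; the grid is deliberately small since the synthetic
problems are not hyperparameter-sensitive, and it is configurable.
The forest's per-node feature-subset size is `round(log2 d)` (rounding to
nearest since d = 42 gives 5.39; floor would also give 5 but differ at
e.g. d = 48), floored at 1.

## Synthetic data

The generator emulates the statistical structure of cue-paced forearm
sEMG, not its physiology: each trial is white Gaussian noise band-pass
filtered to a class-specific band, normalized to unit RMS, scaled by a
class × channel gain, shaped by a raised-cosine onset/offset envelope
(0.25 s / 1 s / 0.25 s), and summed with a broadband noise floor (0.02)
and a common-phase 50 Hz sinusoid (amplitude 0.2, added before filtering
so the notch stages have something to remove).  Defaults: MF occupies
10–105 Hz, WF 105–195 Hz (the two bands where real fist-clench and
wrist-flexion power concentrates), WE is broadband 20–250 Hz, and REST is
low-amplitude broadband (gain 0.05 vs 0.4–1.0 for movements).  Each
movement couples most strongly to one of the four electrode sites (APL,
ECR, ECU, FCU), mimicking muscle-electrode geometry.  40 trials per class
by default — the count implied by 160 extracted vectors per class at
250 ms windows — with a seeded shuffled trial order.

What the generator does *not* model: motor-unit action-potential shape,
amplitude non-Gaussianity, fatigue drift, electrode lift-off, or
inter-subject variability.  Pipeline accuracies on this data are therefore
upper bounds demonstrating correctness of the machinery, not predictions
of performance on human recordings; the classes are separable by
construction, and the permutation null (≈25% for four balanced classes)
is the accompanying sanity check.

The planted-feature generator emits abstract windows × features matrices:
planted columns get a class-dependent mean shift (`effect_size` per class
step) *and* variance inflation (so variance-based EC, distance-based FD
and margin-based RFE can all detect them); the rest are i.i.d. standard
normal.  Effect size 0 is the exchangeable null.

## Control simulator

The telecar moves in fixed quanta — ±12 cm translations and ±45°
rotations — at 12 cm/s and 0.25π rad/s, so each quantum costs exactly
1 s.  Three intent-stream paradigms are simulated: (2) single channel,
command issued only when two consecutive 125 ms epochs agree, the pair
resetting after each command; (3) two channels, command issued only on
agreement, else stop-and-wait; (4) a state machine where REST toggles
between straight-line (WF forward / WE backward) and rotation (WF
anti-clockwise / WE clockwise) modes, MF stops, and a toggle is only
honoured after at least one motion in the current mode (guarding against
rest-state chatter).

Time accounting: under Paradigm 2 every analysis epoch costs its window
length and every motion 1 s (recognition precedes motion); under
Paradigms 3 and 4 recognition is concurrent with motion, so moving
decisions cost 1 s and only idle decisions (stop, disagreement, toggles)
cost window time.  Obstacles are axis-aligned rectangles that convert a
translation into a logged stop.  The kinematic lower bound for the
two-loop 40 cm square course is `320/12 + 8·(π/2)/(0.25π) ≈ 42.67 s`, and
any simulated run over the course takes at least this long.  Recognition
rate is the fraction of epochs matching the prompted intent (Paradigm 2)
or of periods where both channels agree with the intent (Paradigm 3);
Paradigm 4 has no prompted intent, so no rate is defined.

## Problem sizes and determinism

Test and acceptance runs use desk-scale data chosen to exercise every
code path while completing in seconds: 6–20 trials per class for
end-to-end pipelines, 100 seeds for planted-recovery rates, 30 windows ×
20 features for criterion tests.  Every stochastic component (generators,
fold shuffling, forest/ANN/ICA initialization) is seeded, and seeded runs
are bit-reproducible.

## Known limitations

- The EC/FD/RFE implementations are validated against enumeration oracles
  and synthetic ground truth, not against any published per-feature
  separability table, which would require the original recordings.
- The ANN is a scikit-learn MLP with early stopping rather than a
  hand-tuned backprop schedule; at the default desk scale it occasionally
  underperforms the forest on small subsets.
- MSPCA gains depend on cross-channel correlation; on uncorrelated
  channels the Kaiser rule may retain everything and denoise nothing.
- The simulator models discrete kinematics only — no acceleration,
  slippage, or auditory-cue latency.
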