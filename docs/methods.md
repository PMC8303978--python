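# Methods

## Signal model and windowing

A record is a pair of force series (left foot, right foot) sampled at a
common rate, nominally 300 Hz for the public gait database this package
targets; every window length is specified in seconds so any rate works.
The compound-foot channel CF is the elementwise sum LF + RF. Windows are
non-overlapping, contiguous from t = 0, and exact in sample count;
partial tails are discarded, so a 5-minute record yields 30 / 10 / 5
windows at 10 / 30 / 60 s, and the standard cohort (16 HC, 13 ALS,
20 HD, 15 PD) yields 1920 / 640 / 320 windows in total. Raw files may
contain small negative baseline values from the force sensor; they are
clamped to zero with a logged count, since the sensor reads 0 with no
load.

## Synthetic gait generator

The generator emulates the phenomenology of sensor-recorded gait, not
calibrated biomechanics. Per foot, stance phases are placed at
alternating step onsets; each stance occupies 55% of that foot's gait
cycle, so successive stances overlap only briefly and the CF channel
dips toward zero at every step transition — the two global minima per
gait cycle seen in healthy sensor traces, with the shallower mid-stance
valley supplying the third (local) minimum. The stance profile is a
piecewise raised-cosine interpolation through (0, 1.0, 0.8, 1.05, 0):
loading-response peak, valley, push-off peak, all configurable. Forces
are scaled to an arbitrary 0-3.5 unit range echoing the recording
hardware's output span.

Phenotype defaults (all tunable via `GaitPhenotypeConfig`):

| group | step rate (Hz) | step CV | swing floor | asymmetry | tremor | cadence walk |
|---|---|---|---|---|---|---|
| HC | 1.85 | 2% | 0 | 1.0 | — | — |
| ALS | 1.30 | 12% | 0.35 | 1.0 | — | — |
| HD | 1.70 | 6% | 0.15 | 1.0 | — | sigma 0.08/step, reflected into [1.0, 2.5] Hz |
| PD | 1.80 | 4% | 0 | 0.75 | 5 Hz, depth 0.15 | — |

The healthy step rate sits mid-way in the 1.6-2.1 Hz band where healthy
walking concentrates spectral power; ALS walks markedly slower with
raised inter-peak minima (the swing "floor" keeps the unloaded foot at
35% of peak force) and larger step-time variability; Huntington gait is
modeled purely as a bounded random walk of cadence (fluctuating walking
velocity), which raises the across-window variance of the dominant
spectral ridge rather than shifting its mean; Parkinsonian gait keeps a
near-normal cadence but loads the two feet unequally (LF/RF amplitude
ratio 0.75) and superimposes a 5 Hz tremor modulation. The left/right
asymmetry puts a stride-rate subharmonic (~0.9 Hz) into the CF spectrum,
so the PD ridge band is taken as 0.8-2.1 Hz — the dominant ridge
legitimately alternates between the stride subharmonic and the step
rate. Group effect sizes are design choices: the frequency bands are the
stated constraints, the remaining magnitudes were fixed once at values a
gait analyst would call plausible and are exposed as configuration.

What the simulator does **not** reproduce: calibrated force magnitudes,
inter-subject anthropometric variation, sensor drift and saturation
artifacts, derived stride/stance/swing interval series, or the
within-group heterogeneity of real patients. Passing the pipeline's
class-recovery tests therefore demonstrates that the chain is correct
and sensitive to the encoded spectral signatures — not that the printed
clinical accuracies of any real cohort are reproduced.

## Time-frequency transforms

**CWT.** The transform is the family of correlations
`X(s, tau) = s^{-1/2} integral x(t) psi*((t - tau)/s) dt` with the
zero-mean Morlet wavelet `psi(t) = (e^{-ift} - e^{-f^2/2}) e^{-t^2/2}`,
reference frequency f = 6 (dimensionless, the standard
admissibility-safe choice). A target frequency F in Hz maps to the scale
`s = f / (2 pi F)`. Implementation is FFT-based linear convolution per
scale with the wavelet truncated at |t| = 8 envelope widths (relative
amplitude ~1e-14); it matches direct quadrature to ~1e-15 relative
Frobenius error. Edges are zero-padded and the per-frequency
cone-of-influence width is recorded in metadata. The frequency grid is
geometric, 12 voices per octave over [0.1, 50] Hz, which resolves both
analysis bands (0.1-5 Hz and 5-50 Hz).

**STFT.** Windowed DFT magnitudes of successive segments; default
segment length 2 s with 75% overlap and a Hann taper, frequency axis
k·fs/L.

**WSST.** The phase transform is computed analytically through the
derivative-of-wavelet kernel (finite differences would amplify noise at
high frequencies). Because this wavelet's complex exponential `e^{-ift}`
puts its passband at negative frequency, the instantaneous-frequency
estimate for real signals is the *negated* phase derivative. Coefficients with
`|W| <= gamma = 1e-8 max|W|` are discarded (the phase transform is
undefined at zeros of W); the rest are reassigned to the nearest output
bin in log-frequency. Magnitude mass is conserved exactly up to the
discarded cells, squeezing concentrates a pure tone's energy by roughly
2.5x over the CWT on the same grid, and the ridge of a slow linear chirp
is tracked within one grid bin over the central 80% of the signal.

**Rendering.** Windows are mean-removed before transformation — the
constant load offset carries no gait information and, under
finite-support transforms, otherwise leaks into the lowest octaves.
Rendering is deterministic: crop to band (full 0.1-50 Hz for
classification; 0.1-5 and 5-50 Hz bands for analysis plots), log
magnitude with a 1e-6 relative floor, per-image min-max normalization (a
constant image maps to mid-scale), a frozen 256-entry monotone colormap
lookup table shipped as a versioned CSV fixture, bilinear resampling to
227×227×3 in [0, 1].

## PCA enhancement

Images are reduced to a single luminance channel before the
decomposition (a colormapped raster is rank-deficient in hue; per-channel
mode is available), centered, projected on the leading principal
components, reconstructed, clipped to [0, 1], and re-expanded to three
channels. Default retained variance is 0.95. The basis is fit on
training-fold images only and frozen for test images; fitting on the
full dataset before cross-validation is possible behind a flag but leaks
test information and is not used in any reported number. Enhancement is
a projection: idempotent up to clipping, with reconstruction error
non-increasing in the component count.

## CNN feature extractor

The network reproduces the classical AlexNet feature path exactly: five
convolutions (conv-2, conv-4, conv-5 grouped with groups = 2 — the
published weight shapes, e.g. 5×5×48×128×2, force grouping), ReLU,
cross-channel normalization (depth 5, alpha 1e-4, beta 0.75, k 2 — the
layer's classical constants, since the architecture table names the
layer without them), three 3×3/2 max poolings, then fc-16 (9216 → 4096),
ReLU, 50% dropout, fc-19 (4096 → 4096). A 227×227×3 input traverses
55×55×96 → 27×27×256 → 13×13×384 → 13×13×384 → 13×13×256 → 6×6×256.
Features are the fc-19 activations with dropout inactive.

Everything is numpy (im2col convolutions, float32). Weight modes:
seeded He-normal `random` (default for tests — random convolutional
projections preserve class-separating structure and need no assets), a
local `pretrained_file` npz loader with per-tensor shape validation
(nothing is ever downloaded), and `scratch_trained`: cross-entropy
training of the fully connected stack (fc-16, fc-19, and a temporary
softmax head) by mini-batch SGD (momentum 0.5, lr 3e-3, global
gradient-norm clipping at 1.0, batch 32) on labeled images while the
convolutional stack stays frozen at its seeded initialization. Training
the convolutions themselves is out of scope: the design mirrors the
transfer-learning usage the architecture is known for, where the
convolutional stack is a fixed feature basis and only the fully
connected layers adapt; it also keeps per-fold refitting affordable on a
single CPU. The loss history is recorded from a clean full-batch
evaluation pass after each epoch.

## SVM and evaluation

The classifier is an RBF-kernel SVC. C and gamma are chosen by Bayesian
optimization: 30 objective evaluations (8 seeded random initial points,
then expected-improvement steps with a Matern-5/2 Gaussian-process
surrogate with fixed hyperparameters over log10 C in [-3, 3] and log10
gamma in [-4, 1]), the objective being mean stratified 5-fold accuracy
on the training fold only. Everything is seeded and deterministic.

Cross-validation is leave-one-out or stratified 5-fold, at window or
subject granularity. Window-level splitting mirrors the common practice
of counting each window as an independent unit, but places windows of
one subject on both sides of the split; subject-level splitting (the
default here) keeps all windows of a subject in one fold and is the
honest estimate. Both are exposed so the leakage difference can be
reported side by side.

Reports carry two operating points. The classifier's own predictions
give the confusion matrix, sensitivity, specificity, and accuracy (as
percentages); the pooled decision scores give the ROC AUC (decision
scores, not posteriors) and Youden's index, maximized over all midpoint
cutpoints between consecutive distinct scores plus infinite sentinels —
a finite sweep that attains the supremum over all real cutpoints. The
sensitivity and specificity at the Youden cutpoint are reported
alongside and satisfy J = sens + spec - 1 exactly. Configurations are
ranked by J, ties broken by accuracy then AUC. Multi-class tasks use
one-vs-one voting for predictions and one-vs-rest decision scores for
per-class metrics.

## Numerical and design notes

- Degenerate inputs: empty spectrogram bands raise; constant-magnitude
  images map to mid-scale; identical training images give a
  zero-component PCA model whose reconstruction is the mean image;
  single-class label sets are rejected everywhere with explicit errors.
- Determinism: every stochastic component (generator, weight init,
  FC training, fold shuffling, hyperparameter search) is driven by an
  explicit seed; per-subject seeds are spawned from a master
  SeedSequence.
- Problem sizes: the end-to-end class-recovery check runs the 16 HC +
  13 ALS synthetic cohort at 120 Hz with 60-s windows (145 spectrogram
  images, subject-level 5-fold, both PCA arms); transform oracles run on
  signals of at most 512 samples; ridge surveys use four 150-s records
  per phenotype at 150 Hz. These sizes were chosen so the whole
  verification runs on a single CPU in minutes while every stage is
  exercised at full fidelity (the network geometry, grids, and search
  budgets are never reduced).
- Known limitations: no inverse transforms; no GPU path; classification
  images are full-band (band-limited images are available but the
  0.1-5 / 5-50 Hz bands are used for interpretation, not training);
  probability calibration of SVM outputs is out of scope; accuracies on
  the real public cohort require its data and pretrained weights and are
  deliberately not claimed.
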