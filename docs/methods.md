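# Methods

This note records the scientific and numerical choices behind `ecgmi`: what
each stage assumes, which parameters matter, what the synthetic generator
does and does not emulate, and where the design was genuinely open.

## Synthetic ECG generator

Each beat is the sum of five Gaussian bumps (P, Q, R, S, T) on a zero
baseline. Defaults place P at −160 ms, Q at −40 ms, S at +40 ms and T at
+240 ms relative to R, with amplitudes 0.15/−0.10/1.00/−0.15/0.30 mV and
widths 20/8/10/8/40 ms — ordinary adult resting morphology (PR ≈ 160 ms,
QRS ≈ 80 ms, Q→T ≈ 280 ms). Records default to 10 s at 1000 Hz, single lead;
additional leads are amplitude-scaled copies (seeded scale in [0.6, 1.2]) so
that relative-amplitude features are exercised.

Infarct-like morphology is imposed per beat as (i) a +0.2 mV offset over the
ST window (R+80 … R+160 ms), (ii) T-wave inversion, (iii) Q amplitude doubled.
These are the canonical ECG signatures of MI; their magnitudes are
deliberately strong so that class separation on noiseless templates is exact
and testable.

Noise models: baseline wander as a 0.3 Hz sinusoid with random phase,
powerline as a 50 Hz sinusoid, impulse noise as isolated single-sample spikes
(Poisson-timed — exactly what a median filter provably removes), and white
Gaussian noise. Beat-period and amplitude jitter are optional fractional
Gaussian perturbations.

What the generator does **not** emulate: a dynamical heart model,
respiration-modulated morphology, electrode-motion transients, arrhythmia
(ectopy, fibrillation), or inter-patient morphology variability beyond
amplitude scaling. Passing tests therefore demonstrate correctness of the
algorithms under controlled conditions, not clinical performance on real
recordings; the printed database-scale accuracies of this model family are
outside what a desk-scale synthetic study can reproduce.

## Median filter

Window length 5 at 1000 Hz by default: long enough to remove 1–2-sample
impulses, short relative to the ~80 ms QRS so the R amplitude survives. The
window is inclusive on both ends (2·ns+1 samples); an even length averages
the two middle order statistics. Edges use reflect padding, so the output
length equals the input length. Only the 1-D time-domain filter is
implemented — no band-pass, notch or wavelet denoising.

## Delineation and medical features

R detection reconstructs the discrete-wavelet detail scales (db4) whose
passbands intersect 10–25 Hz — where QRS energy concentrates at 1000 Hz —
squares and smooths them (25 ms moving average), thresholds at 0.4 × the
rolling RMS (2 s window, with a small absolute floor so a flat record yields
no detections), and refines each candidate to the raw-signal maximum within
±25 ms under a 200 ms physiological refractory period.

Q and S are the minima within 80 ms before/after R, nudged to a five-point
central-difference derivative sign change when one lies within 3 samples; P
is the maximum in (R−240, R−80) ms; T is the largest-magnitude extremum in
(R+80, R+400) ms of a 4th-order 12 Hz Butterworth low-passed copy (T is a
low-frequency wave; filtering stops QRS leakage). Beats whose search windows
leave the record are dropped rather than padded.

QT and PR are within-beat time spans (|t(T)−t(Q)|, |t(R)−t(P)|); RR and PP
are spacings of consecutive beats; all four are averaged over beats and
reported in seconds, with the mean R amplitude in mV as the fifth feature.
Interval means require at least two beats. On multi-lead records a single
designated lead is delineated (lead II preferred when named — the standard
rhythm lead); no cross-lead consensus is attempted.

## MKMFCC

Pre-emphasis Y = 0.97; 25 ms frames (within the conventional 20–40 ms
quasi-stationarity span), 10 ms hop; window ω(c) = 0.56 − 0.46·cos(2πc/(C−1))
— Hamming-shaped with non-standard constants, kept deliberately; FFT size =
next power of two ≥ frame; power spectrum |X|²/C; 40 triangular filters
equally spaced on the Mel scale m = 2595·log10(1+f/700) from 0.5 Hz to fs/2.

The "multiple kernel" weighting multiplies each Mel band energy, before the
log, by W = λ·Gauss + (1−λ)·ramp over the band index (Gaussian centred on the
middle band, width σ = 2 bands; linear ramp emphasising higher bands), each
kernel normalised to unit mean, λ = 0.5 by default. λ = 1 with σ → ∞ makes
W ≡ 1 and recovers plain MFCC — used as a cross-check in the tests.

Per frame: log energies (floor 1e−10) → orthonormal DCT-II → first 30
coefficients, with slot 0 replaced by the log frame energy; then per-frame
mean/variance normalisation **across coefficients** and averaging over frames
into one 1×30 row. Normalising across frames instead would cancel exactly
under the subsequent frame average, so the per-frame form is the only
self-consistent reading; it also makes the vector approximately invariant to
amplitude scaling. At 1000 Hz a 25 ms frame yields a coarse spectrum, so
several low-frequency Mel filters sit below the floor; the affected
coefficients are constant rather than harmful.

## Static features

Haar features use 4 decomposition levels with periodised boundaries, so the
subband energies exactly partition the signal energy; the feature is
log(ε + E_detail/E_total) per level, finest first. Mean and variance are
population moments (1/C). Relative amplitude uses per-channel maximum
absolute amplitude; single-lead records are split into 12 equal pseudo-channel
segments (66 pairs, first 50 kept, zero-padded otherwise; a 0/0 pair is 0).
Relative energy partitions the DC-free magnitude-squared spectrum into 100
equal bands and normalises to sum 1 (uniform fallback for an all-zero
signal). Entropy is the mean log squared amplitude at unit RMS — a
log-energy concentration measure, low for peaky signals (Jensen), stable in
length and scale. Kurtosis is Pearson m4/m2² (normal → 3; defined 0 at zero
variance). Information gain is label-free: log2(10) − H(histogram), the
uniformity deficit of the 10-bin amplitude histogram, so feature extraction
needs no class information. The assembled vector is 194-dimensional with a
contiguous block layout descriptor; every block length is configurable.

## Augmentation

Segment permutation (D = 4 equal parts, identity order rejected, remainder in
place) and window slicing (90 % window at a seeded offset) operate on raw
signals, with features re-extracted afterwards — shuffling a feature row
directly would scramble semantically unrelated columns. Envelope random
generation draws rows column-wise uniform within the per-class min/max of the
real rows; interpolation re-sampling fills class deficits with convex
combinations of random same-class pairs plus 1 % column-range Gaussian
jitter. Real rows are never mutated and every synthetic row carries an
`augmented` flag. Envelope generation samples columns independently and so
breaks inter-feature correlations; it is capped at a configurable fraction
(default 0.3) of the new rows.

## Residual network

The input feature vector is treated as a one-channel sequence: stem
convolution → batch-norm → ReLU → max-pool 2 → residual block(s) → global
average pooling → fully connected softmax. Presets: `tiny` (stem 2 ch k3,
block 2→4, ~130 parameters — the default), `base` (4 ch k5, 4→8, ~430) and
`small` (8 ch k7, two blocks, <20 k). Weight search by a population
metaheuristic is only reliable at low dimensionality: at a 30-agent ×
150-iteration budget the ~430-parameter preset plateaus well short of
separating even cleanly separable data, while ~130 parameters trains to
0.95–1.0 accuracy across seeds — that is why `tiny` is as small as it is.

Batch-norm gains are stored as deviations from unit gain (effective gain =
1 + parameter): a centred random position then behaves like a conventionally
initialised network instead of a mostly-dead one, which materially improves
the bounded population search. Batch statistics of the evaluation batch are
used throughout — without a gradient loop there are no running averages to
maintain — so the forward pass is deterministic for a fixed batch. There is
no backpropagation anywhere.

Known limitation: global average pooling dilutes the contribution of the few
informative feature positions among all 194, so end-to-end accuracy on the
synthetic demo (~0.73–0.77, AUC ~0.8) sits well below what a linear model
achieves on the same (linearly separable) features. This is a property of
the model class at this size, reported as-is.

## SSS optimizer

Agents live in a box [lb, ub]; fitness is the MSE between one-hot labels and
softmax outputs. The update combines the ski-driver velocity (toward the
personal best and the mean g of the current three best, gated by sin(o₁) and
the annealed factor l) with the spider-monkey social term (toward the global
leader and a random partner), merged in closed form with denominator
o₀₁ + o₁₁ (coordinates with |o₀₁+o₁₁| < 1e−6 are redrawn, at most 100 times,
else the agent skips the step). The social coefficients are drawn **per
dimension** — the social pull is defined coordinate-wise — which gives the
update a crossover character that is essential in the several-hundred-
dimensional weight space; with a single scalar draw per agent the search
stalls. `sss_update` broadcasts, so scalar draws reproduce the closed-form
arithmetic exactly in the oracle tests.

Candidates are clipped to the box and accepted greedily (only on fitness
improvement), which makes the best-fitness trace monotone non-increasing and
realises the feasibility-evaluation step; non-finite fitness rejects the
candidate. l anneals linearly from 2.0 to 0.0 over the budget
(exploration → exploitation). Defaults y = 30 agents, K = 100 iterations;
optional early stop when improvement stays below `tol` for `patience`
iterations. Classifier training defaults to bounds ±0.7, chosen together
with the l schedule as the optimizer's calibration for weight search.
Pure ski-driver and pure spider-monkey-position updates (both with greedy
acceptance) are included as reference baselines for head-to-head tests only.

## Evaluation

MI is the positive class everywhere. Rates are computed in exact rational
arithmetic and rounded half-up to two decimals on the percentage scale for
display (9456/9546/1051/700 → 91.56 %). ROC curves always include (0,0) and
(1,1) with trapezoid AUC. Splits are stratified (k-fold or a learning
percentage) and seeded. The pipeline holds out records **before**
feature-level augmentation and scores only held-out original rows — synthetic
rows are training aids, and evaluating on them would flatter the metrics.
Signal-level augmented copies share a source record with no cross-split
bookkeeping, a mild optimism source documented here and acceptable for a
synthetic-data demonstration.

## Reproducibility

Every stochastic component takes an explicit seed; the pipeline derives one
seed per stage from the global seed by CRC-32 substream hashing, so stages
rerun independently yet identically. Problem sizes used by the default
configuration and the test suite (10 s records, 12 records per class at
500 Hz in the demo, n = 300 rows for parameter recovery, 20 seeds on the
sphere benchmark) were chosen as the package's own desk-scale study
conditions.
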