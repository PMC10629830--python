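# Methods

## The model

`predstack` implements a hierarchy of *stacks*: single-hidden-layer 3D
convolutional networks trained, one at a time from the bottom up, to predict
the immediate future of their own input. Stack 1 sees grayscale movie clips
(y × x × t tensors, one channel); each later stack sees the hidden activity
of the stack below. For stack input channels U_i, hidden unit j computes

    H_j = relu(b_j + Σ_i U_i ∗ W_ji)

with a valid (unpadded) strided 3D convolution, and a linear head with
kernels M_kj of temporal depth one estimates the input one time-step ahead:

    V̂_k = c_k + Σ_j H_j ∗ M_kj .

When the hidden layer is spatially strided, the head operates on the
zero-dilated hidden activity (a fractionally-strided convolution), which
makes its output size exactly `(n_h − 1)·s + k` — the input size, for any
geometry accepted by `StackSpec`. The hidden window ending at frame
`t + T′ − 1` produces the head's estimate of frame `t + T′`; the final
hidden step has no realized target and is excluded from the loss. The loss
per stack is the mean squared prediction error over all compared elements
plus `λ (Σ|W| + Σ|M|)`, minimized with Adam (β₁ = 0.9, β₂ = 0.999,
minibatch 32). "Iterations" are optimizer update steps. Gradients never
cross stack boundaries.

The full-scale architecture (`full_scale_specs`) uses 181×181×20 clips, a
21×21×5 kernel at stride (10, 10, 1) with 50 units in stack 1, then 3×3×5
kernels at stride 1 with 100/200/400 units; learning rates 10⁻² then 10⁻⁴,
L1 strengths 10⁻⁴·⁵ then 10⁻⁶. Its shape algebra (hidden-unit counts
14,450/22,500/33,800/48,400; receptive extents 21→41→61→81 px and 5→9→13→17
frames) is computed, not stored.

All network arithmetic — forward convolutions, the fractionally-strided
head, and the backward passes for every objective — is written directly in
numpy (`predstack.conv`), with analytic adjoints verified against numerical
differentiation in the test-suite. Training runs in float32 with the
sliding-window tensors of the training set materialized once and sliced per
minibatch; minibatches are contiguous slices of one shuffled clip order,
with the batch sequence reshuffled each epoch. Weight initialization
(unspecified in the original description) is fan-in-scaled uniform with a
recorded seed; biases start at zero.

## Control objectives

Two alternative objectives reuse the identical architecture and plumbing:

* **Sparse autoencoder** — the head targets the *current* frame (the most
  recent frame of each window, so every hidden step has a target), with an
  added activity penalty `λ₁·mean|H|` and weight penalty `λ₂`.
* **Slowness** — no head at all. Hidden activity is batch-normalized per
  channel, and the loss is the mean squared difference of consecutive
  time-steps plus the mean absolute Pearson correlation over all unordered
  channel pairs (computed per clip over flattened space × time, after
  adding uniform jitter on (0, 10⁻⁴) to avoid zero-variance divisions; the
  jitter is redrawn at every evaluation). The decorrelation normalizer is
  2/(N·J·(J−1)). Batch normalization is applied after the rectification,
  before both loss terms; with J < 2 the loss is undefined and rejected.

Two perturbation controls: **weight shuffling** permutes each trained input
kernel's entries across space and time (value multiset preserved; the
permutations are recorded so the operation can be inverted bit-exactly),
and **frame shuffling** permutes the frame order within each training clip
before training.

## Movies

Training clips are 20-frame (800 ms at 25 frames/s) square grayscale
tensors, each normalized to zero mean and unit variance on its own;
zero-variance clips are rejected rather than zero-filled. Preprocessing
center-crops the longest dimension (a symmetric, deterministic choice),
downsamples bilinearly, and drops the trailing remainder of a sequence.
Panning augmentation shifts frame t horizontally by `shift · t` pixels with
wrap-around boundaries — wrapping avoids blank borders that would dominate
learned features, at the cost of a seam that real panning footage would not
have. The train/validation split is 90/10 at clip granularity, seeded.

The synthetic generator (`synth_movies`) stands in for unredistributable
filmed footage. Each clip is an independent periodic random-phase texture
with radial amplitude spectrum ∝ f^(−1) (power slope −2, the natural-image
regularity), rigidly translated at a per-clip constant velocity by Fourier
phase ramps (exact subpixel translation, wrap-around boundaries). Defaults:
20% of clips are still, 30% pan horizontally only, the rest translate
freely with per-component speeds uniform up to 3 px/frame — mirroring
footage from still, panning, and freely moving cameras, and matching the
±1–3 px/frame panning augmentation range. What the generator deliberately
omits: occlusion, independent object motion, zoom, luminance
nonstationarity, and photometric noise. Tests passing on these movies
therefore show that the pipeline learns and measures *rigid-motion*
structure correctly, not that the full phenomenology of wildlife footage
would be reproduced.

## In-silico physiology

Units are probed like neurons. A *convolutional unit* is one kernel
replicated over space; its response is the activity of the spatially
central copy at all valid time-steps. Probe stimuli are generated at the
stack-1 input resolution and center-cropped to the unit's spatiotemporal
extent, which reduces the probed stack to a single spatial position —
full-field drifting stimuli make position immaterial up to phase, so this
is a computational convenience, recorded here as a convention. Valid
convolution already trims the first T′−1 frames, so no additional onset
window is excluded from time-means.

* **Receptive fields**: stack-1 RFs are the input kernels themselves (the
  LN-model reading); deeper RFs are estimated by reverse correlation — the
  response-weighted average of ±3 binary noise over the unit's extent,
  normalized by the summed response, using the unit's graded activity in
  place of spikes. Units with zero summed response are flagged undefined.
* **Gabor fits**: 2D Gabors `A·exp(−(x′/2σx)² − (y′/2σy)²)·cos(2πf x′+φ)`
  are fitted to the most recent RF time-step by least squares over all
  eight parameters. The optimizer is seeded from the 2D spectrum peak
  (frequency, orientation and phase read off the dominant Fourier
  component) plus a small grid of fallback orientations, and uses an
  analytic Jacobian. Fit quality is the pixel-wise Pearson correlation;
  units above 0.4 qualify as putative simple cells.
* **Gratings**: drifting sinusoids of amplitude ±3 on a gray (0)
  background; temporal frequency in Hz maps to cycles/frame through the
  40 ms frame interval. The optimal-grating search grid is directions
  0–355° in 5° steps, 8 log-spaced spatial frequencies from 0.02 to 0.4
  cycles/px, and temporal frequencies {0.625, 1.25, 2.5, 5, 7.5} Hz. The
  temporal grid is capped at 7.5 Hz (3.3 samples/cycle): faster nominal
  drift rates approach the frame-rate Nyquist limit, where the stimulus
  degenerates into counterphase flicker and every unit aliases onto the
  same modulated response. Ties in the argmax break toward the lowest
  spatial frequency, then temporal frequency, then direction. Units with
  mean response below 1% of the per-stack maximum are excluded (a 0.1%
  population-wide variant is available for pooled analyses).
* **Metrics**: circular variance with angle doubling on the 5° direction
  grid; orientation bandwidth as half the angular width at 70.7% of the
  peak of the tuning curve smoothed with a raised-cosine (Hanning) kernel
  of half-width-at-half-height 13.5° (the 1/√2 criterion is the default;
  half-amplitude is available), capped at 180°; modulation ratio F1/F0
  with F1 from a least-squares sinusoid at the known stimulus frequency
  (tolerant of non-integer cycle counts, unlike an FFT bin) and F0 the
  time-mean; and three direction indices, DSI1 = (rp−rnp)/(rp+rnp),
  DSI2 = (rp−rnp)/rp, DSI3 = 1−(rnp−rnull)/(rp−rnull), the last exceeding
  1 when the opposite direction is suppressed below the blank response.
* **Classification**: simple = Gabor fit > 0.4 ∧ CV < 0.9 ∧ MR > 1;
  complex = CV < 0.9 ∧ MR < 1; otherwise non-oriented; undefined MR/CV or
  an exclusion yields "excluded". Simple or complex units with DSI1 > 0.5
  are flagged direction-tuned.
* **Plaids**: two half-amplitude (1.5) gratings at ± half the component
  separation around the pattern direction, optionally windowed by a
  circular mask. Pattern/component classification uses the standard
  two-predictor partial correlation of the observed plaid tuning against
  the unit's own grating tuning (pattern prediction) and its average
  displaced to the two component directions (component prediction), with
  Fisher-z scores and a 1.28 criterion; a descriptive smoothed peak count
  is reported alongside, since the original analysis presents tuning
  curves without naming an index.

## Neural readout

Any stimulus→activity feature provider can be scored against a recording.
Activity is reduced to at most 500 principal components (centered PCA,
fitted on the cross-validation split only); the components at bins t−1 and
t−2 are concatenated to absorb response latency, and per-neuron weights
m_l with bias d_l are fitted in `r̂ = softplus(m_l·h + d_l)` by minimizing
the negative Poisson likelihood −(1/LT)Σ(r ln r̂ − r̂) + λ_read Σ‖m_l‖₁
with Adam (batch 1024, learning rate 0.002, 300 epochs). λ_read is chosen
from nine log-spaced values (10⁻⁶·⁵…10⁻²·⁵) by five-fold cross-validation
grouped at stimulus-file granularity, then the readout is refitted on the
whole cross-validation split. Performance is CC_norm: the Pearson
correlation with the trial-mean response divided by CC_max, estimated from
trial-to-trial variability by the signal-power construction
CC_max = √(SP/var(ȳ)) with SP = (var(Σᵢyᵢ) − Σᵢvar(yᵢ))/(n(n−1)); neurons
with non-positive signal-power estimates are flagged rather than scored.
Models are compared by a paired bootstrap over neurons (10,000 resamples;
exact ties split evenly so that identical score vectors give p = 0.5), and
a spatial rescale search (0.66×, 1×, 1.5×) with best-stack selection is
provided. The synthetic-neuron generator plants sparse softplus readouts
on known latents and draws independent Poisson trials, so the whole
harness is testable with ground truth known.

## The miniature benchmark study

Training the full architecture on ~1305 clips of 181×181 footage for 1000
iterations per stack is beyond a test suite, so the package pins one
desk-scale study (`predstack.benchmark`): 60 synthetic 64×64×20 clips in
which every clip translates (the still fraction is set to zero — the
natural yardstick, copying the last seen frame forward, is exact on a
still clip, so an all-translating set is the condition under which
one-step prediction is a meaningful test), split 90/10; two stacks with 8
and 16 units (16×16×4 kernel at stride (6, 6, 1), then 6×6×3 at stride 1),
300 iterations per stack. The stack-1 kernel is kept at 256 pixels because
Gabor fits to unstructured 12×12 slices frequently exceed the 0.4
criterion by chance, while 16×16 noise slices stay safely below it — the
same role the 21×21 kernels play at full scale. Learning rates are 10⁻²
and 10⁻³; stack-wise λ grids are supported but the miniature uses the
specs' fixed values to keep the run inside a test budget.

## Numerical choices and degenerate inputs

* Convolution is implemented as cross-correlation (the convnet
  convention) consistently in forward and backward passes and in the
  brute-force test oracles.
* Zero-variance clips, all-zero RF slices, zero total tuning response,
  zero-mean response traces, single-trial recordings, and single-channel
  slowness stacks all raise or flag explicitly; nothing is silently
  zero-filled.
* L1 subgradients use sign(0) = 0. Batch-normalization uses ε = 10⁻⁵.
* The float32 training path is deterministic for a fixed seed on a fixed
  BLAS; returned weights are cast to float64.
* Orientation from a Gabor fit is reported modulo 180°; grating "direction"
  is stripe orientation + 90°, tuning curves run over 360° of motion
  direction, and the circular variance doubles angles so opposite
  directions reinforce.

## Known limitations

* The training loop materializes sliding windows (fast, memory-hungry);
  above ~2 GB of windows it falls back to per-batch construction. The
  full-scale Table-1 configuration trains, but slowly — the package's
  quantitative claims about it are architectural, not about trained
  full-scale weights.
* Classical closed-form slow-feature analysis is out of scope; the
  slowness control is the gradient-trained variant.
* The readout harness ships adapters only for array-shaped recordings;
  loaders for specific public datasets are left to the user.
* Pattern/component classification at miniature scale rarely produces
  pattern-selective units (they were rare at full scale too); the plaid
  machinery is validated against hand-built component- and
  pattern-selective oracle units instead.
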