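# Methods

## The regression model

The predictor is a general regression neural network (GRNN): Gaussian
Nadaraya–Watson kernel regression over stored training rows. Training is
pattern storage — there is no iterative optimization of weights — so the
model has exactly one free parameter, the kernel bandwidth σ shared
across all input dimensions. Predictions are convex combinations of the
stored targets; they can therefore never extrapolate outside the training
target range, which is the model's main structural assumption: the
held-out span must not contain postures outside the training span's
envelope. Per-dimension bandwidths, compressed pattern layers and
incremental updates are deliberately out of scope.

Numerics: the squared distances $D_i^2$ are computed from the expanded
Gram form and clipped at zero; the per-query minimum $D_i^2$ is
subtracted inside the exponentials before normalization. The shift
cancels exactly between numerator and denominator, so the stabilized form
is mathematically identical to the naive one, but it keeps the weights
representable when σ is far below the pattern spacing (with σ ≈ 0.01–0.2
on [0,1]-normalized 7-dimensional inputs the raw exponentials underflow
routinely). In the σ → 0 limit the model degenerates gracefully to
nearest-pattern recall, and in the σ → ∞ limit to the global target mean;
both limits are tested against closed forms.

## Bandwidth selection

σ minimizes the leave-one-out mean squared error. In-sample MSE is
degenerate for a kernel regressor (it vanishes as σ → 0 whenever the
patterns are distinct), so each sample is predicted with itself excluded;
the pairwise distance matrix is built once and reused across all
objective evaluations. The line search is a standard golden-section
contraction on (a, b) = (1e-6, 0.2) — the lower bound standing in for the
open end of the interval — terminating when the bracket is narrower than
ε = 0.01 and returning the bracket midpoint. Comparison ties break toward
the left subinterval so the search is deterministic. One consequence of
the leave-one-out objective worth noting: duplicating every training row
is *not* neutral for bandwidth selection (each held-out row's identical
twin remains available, pulling the optimum toward 0), although it is
exactly neutral for prediction at fixed σ.

## Preprocessing chain

* **sEMG** (2000 Hz): minimal-order Butterworth band-pass designed from
  the specification pass 20–500 Hz (≤ 3 dB), stop 10/570 Hz (≥ 20 dB),
  realized as second-order sections and applied forward–backward.
  Zero-phase application is chosen because any group delay would
  desynchronize the sEMG features from their angle targets; the cost —
  the magnitude response applies twice — only deepens the stop band.
  There is no separate rectification stage: the RMS feature squares every
  sample, which subsumes it. RMS is taken over non-overlapping 20-sample
  windows, producing the 100 Hz feature clock.
* **Plantar pressure**: 20-sample window means, then wavelet denoising
  (below).
* **Angles**: a least-squares cubic spline with one interior knot per 20
  raw samples (fitting, not interpolation — the raw channel is noisy),
  evaluated on the uniform 100 Hz grid. The spline space contains all
  cubics, so clean polynomial segments are reproduced to rounding, and
  the fit is C2-continuous across block joins.
* **Normalization**: min-max to [0, 1] per channel, fitted on the
  training split only and reused for the test split with clipping, so no
  test-set information leaks into the fit. Predictions are mapped back to
  degrees by the exact algebraic inverse.

## Wavelet denoising

Two operations are provided and must not be confused:

* `wavelet_lowpass` — decompose, zero *all* detail coefficients,
  reconstruct from the deepest approximation. With periodized boundary
  handling this is an orthogonal projection (exact when the length is
  divisible by 2^levels): idempotent and never energy-increasing. Its
  pass band ends at fs/2^(levels+1) — at 100 Hz and level 6 that is
  0.78 Hz, *below* a 1 s gait cycle's fundamental, so this operation is
  an aggressive trend extractor, not a gait-signal cleaner. The requested
  level is reduced (with a logged warning) when the signal is too short
  for a useful decomposition at that depth, following the usual
  filter-length criterion.
* `wavelet_denoise` — coif5 level-6 shrinkage: detail coefficients at
  every scale are thresholded at the universal threshold
  σ̂√(2 ln n), σ̂ estimated from the finest details by MAD. This removes
  wide-band noise and attenuates sudden spikes while leaving the large
  coefficients that carry the ~1 Hz gait content and its harmonics
  untouched. Hard thresholding is the default: on a synthetic knee
  trajectory with noise it gave a lower reconstruction error (RMSE 1.24)
  than soft (1.80) against an unprocessed 1.33, because soft shrinkage
  biases the sharp swing-flexion peak.

The pipeline's pressure-feature cleanup and prediction smoothing use
`wavelet_denoise` (`denoise_method: threshold`, the default);
`lowpass` and `none` are selectable in the config. The choice matters: an
approximation-only level-6 reconstruction at 100 Hz would remove the gait
signal itself along with the noise.

## The synthetic gait generator

All channels are deterministic functions of one latent gait-phase
variable plus seeded noise, so the generator is a pure function of its
parameter set and every cross-channel timing relation is exact by
construction. Defaults describe comfortable level walking: 1.0 s cycles,
60% stance, hip −10…+30°, knee 0…60° with a wide swing-flexion bump
peaking at phase 0.73 (substantial flexion already at toe-off), ankle
−20…+15° with a plantarflexion dip near toe-off. sEMG channels are
activation envelopes (RF biphasic: terminal swing/loading plus a
pre-swing burst; BF and ST late swing/early stance) multiplied by a
band-limited 20–450 Hz unit-RMS noise carrier, with a 0.3 Hz drift term
and white noise floor added so the band-pass stage has real work to do.
Envelopes lead the kinematics by 60 ms by default (the physiological
electromechanical delay), and burst amplitudes are jittered per cycle
with CV 0.25, matching documented stride-to-stride sEMG variability.
Pressure channels are raised-cosine bumps compactly supported inside
stance (heel early, forefoot mid, big toe late) with sparse positive
spikes (probability 2e-3 per sample) so the denoiser is exercised;
swing is exactly silent.

What the generator does *not* emulate — and what passing tests therefore
do not show about real data: musculoskeletal dynamics (kinematics are
kinematic shapes, not the output of a dynamical model), subject-to-subject
variability, electrode/skin impedance physics, motion artifacts,
crosstalk between muscles, asynchronous sensor clocks (all channels share
one clock by construction) and non-stationary cadence. In particular the
deterministic phase→angle mapping makes the prediction task well-posed by
design; real inter-stride kinematic variability is represented only
through additive angle noise (0.5° sd) and sEMG amplitude jitter.

## The prediction task and evaluation

Feature rows pair the time-k inputs (1, 4 or 7 columns depending on the
input ablation) with the time-k+1 angles; the last sample yields no row.
The general lagged formulation (stacking several past steps) is supported
in principle by assembling a wider table, but the default network uses
current-time inputs only, matching the 7-input topology. The split is
chronological at floor(2N/3) — no shuffling, so no temporal leakage.

Metrics per joint: RMSE; MRE with the prediction in the denominator,
excluding samples whose |prediction| falls below 1e-6 of the prediction
range (the count of exclusions is reported — MRE is intrinsically
unstable for zero-crossing angles and is reported for completeness, not
used for decisions); Pearson γ (NaN, not an error, for constant series,
since RMSE/MRE remain meaningful); and mean maximum positive/negative
signed error per gait cycle, using ground-truth phase for cycle
boundaries (partial boundary cycles are kept — a truncated cycle's
extremes are still experienced extremes). The correlation denominator is
the standard product of the two standard deviations.

## Problem sizes and determinism

The shipped study conditions are 30-cycle recordings (60 000 sEMG
samples, ~3 000 feature rows, ~2 000 training patterns); one optimized
full-input fit takes about a second, and the five-seed three-ablation
experiment about a minute on one CPU. All randomness flows from explicit
integer seeds through `numpy.random.SeedSequence` spawns, so recordings,
fits and reports are bit-reproducible; reports serialize with sorted keys
and models round-trip through JSON bit-exactly (timing metadata is
excluded from the canonical report serialization).

## Known limitations

* The GRNN stores its whole training set; prediction cost grows linearly
  in it. Fine at 2 000 patterns, not designed for hours of data.
* A single shared σ treats all normalized input dimensions as equally
  informative; irrelevant input columns dilute the distance metric (this
  is visible in the ablation experiment as a mild penalty when weakly
  informative columns are added).
* MRE should not be compared across joints whose angles cross zero.
* The golden-section search assumes a unimodal leave-one-out objective;
  empirically this holds on the synthetic conditions (checked against a
  dense grid in the tests), but multimodal objectives would return a
  local bracket.
* The baseline-regressor comparison hook (e.g. a small feed-forward
  network) is intentionally generic; no second learner is bundled.
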