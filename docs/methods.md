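# Methods

## Problem and scope

`iaprec` reconstructs intracellular action potentials (iAPs) from
extracellular action potential (eAP) recordings of cardiomyocyte
monolayers on nano-/micro-electrode arrays.  The pipeline is: band-pass
filtering and noise extraction, spike detection and segmentation into
aligned 8000-sample (1.6 s at 5 kHz) window pairs, inclusion filtering
(> 90 dB intracellular S/N, ≥ 0.5 mV amplitude), per-window
normalization, waveform descriptors, and a physics-informed quantile
U-Net that maps a normalized eAP window to the median iAP waveform with
a 0.05–0.95 quantile band.  A boosted-tree regression from eAP shape
descriptors to action-potential durations (APDs) serves as a fast
baseline, and a monitoring workflow tracks drug-induced APD changes
across channels with a one-sided t-test at the population level.

## Preprocessing

Signals are filtered with an acausal (zero-phase, forward–backward)
third-order Butterworth filter: signal band 0.1–2499 Hz, noise band
2499–4000 Hz.  At the 5 kHz dialect the noise band's upper edge is not
below Nyquist, so noise extraction uses the same 2499 Hz edge as a
high-pass — the identical out-of-band region up to Nyquist.  The noise
level is the standard deviation of the noise-band trace.

Peak detection requires a height of 12× the noise level and a
separation of at least 60% of the mean beat period.  The period is
unknown before peaks exist, so detection is two-pass: a height-only
pass estimates the period, one refined pass applies the distance
constraint.  The period estimator is the median of the upper half of
the inter-peak intervals; the plain median is biased downward by
spurious double-detections, which would defeat the constraint the
estimate exists to serve.

Windows are 8000 samples starting 1000 samples (0.2 s) before each
peak; boundary peaks lacking full context are skipped rather than
zero-padded (padding would distort late-repolarization durations).
iAP windows are normalized to `0.1 + 0.9·(v − v₀)/(max − v₀)` — written
as a convex combination so both endpoints are floating-point exact.
eAP windows are mean-centred, divided by 60× the standard deviation of
window indices 1150–1350 (a post-spike segment assumed to be noise),
then anchored so the first sample is zero.  Scale-then-anchor keeps
the output dimensionless; anchoring with a raw-scale value would mix
units.  10 kHz recordings are decimated by 2 onto the 5 kHz grid so the
fixed window always spans 1.6 s.

## Waveform descriptors

Five gradient-change points summarise the eAP: onset (bp1), spike
maximum, spike minimum, end of the post-minimum recovery (bp2), and
the start of the late rise (bp3).  Detection operates on a
moving-average-smoothed copy (window 20).  A sample is "quiet" when the
smoothed derivative is below `max(3× the baseline slope floor, 2% of
the steepest slope)` — the relative term matters because the slow decay
between bp2 and bp3 has a small but nonzero slope that a pure noise
floor would never admit.  bp1 is the last quiet sample before the
steepest upstroke point, bp2 the first quiet sample after the steepest
recovery point (the mirror rule), each refined to the centroid of the
local second-difference magnitude, which lands on the true vertex for
piecewise-linear shapes.  bp3 — the start of the rise toward the
repolarization wave — is located on a heavily smoothed tail as the last
below-mid-rise, quiet-slope sample, then snapped to the nearby local
minimum of the lightly smoothed trace.  Voltage spans are measured on
the raw window at the refined indices because smoothing flattens sharp
extrema.  Monophasic windows (no negative phase) are flagged
`distorted` and return partial features with NaN for the missing
fields.

APDs use the standard width-at-fractional-repolarization construction:
the window is smoothed (moving average, width 20), the dominant peak
measured with `scipy.signal.peak_widths`, and APD_x is the full width
at x% of the peak prominence below the peak, linearly interpolated at
the crossings.  Prominence-relative heights follow the width routine's
own convention; the profile is non-decreasing in the level by
construction.  APD100 depends on where the tail meets its base and is
the least stable member of the profile on windows whose tail has not
fully returned to baseline.

## The modified Aliev–Panfilov model

The two-variable model

    dv/dt = k·v·(1 − v)·(v − a) − v·w
    dw/dt = ε(v, a, x)·(k·v − w)

with the sigmoid-smoothed step
`ε = x·σ(n(a − v)) + (1 − x)·σ(n(v − a))`, n = 1000, is integrated with
classical fixed-step RK4.  There is no stimulus term: action potentials
are elicited by supra-threshold initial conditions (v₀ > a, w₀ = 0).
Eliminating w yields a single second-order residual F_AP that vanishes
on solutions; it is evaluated with central differences (one-sided
second-order stencils at the ends) and an additive guard of 1e-3 at
samples where v or dv/dt are numerically zero.  The guard fires only at
vanishing samples — applying it in a band around zero would put a floor
under the residual and destroy its convergence, which is second order
in dt on simulated trajectories.

## Synthetic paired data

No public recordings are deposited, so a generator produces paired
windows with the structure the method assumes.  Per pair:

* Model parameters are drawn (a ∈ [0.05, 0.25], k ∈ [4, 12],
  x ∈ [0.85, 0.99] — large x makes recovery slow above threshold,
  giving the plateau-plus-phase-3 morphology of cardiac APs), the
  trajectory is simulated, and two time scales map it onto the 5 kHz
  grid: the depolarization always maps to a fast upstroke (3–10 ms,
  the sodium-current physics the phenomenological model
  under-represents), while the repolarization scale is calibrated so
  the window APD90 equals a target drawn from 0.2–1.2 s (the
  drug-modulated range).  Parameter draws are rejected (up to 40
  times) when the full repolarization tail cannot fit the 1.4 s
  post-peak window.  The peak sits at sample 1000; the amplitude is
  drawn in 0.5–10 mV.
* The eAP is junction coupling applied to the clean iAP: a capacitive
  term (weights 5e-4 s and 1e-6 s² on the first and second
  derivatives), broadened by a first-order RC low-pass (60–150 Hz) to
  the ~10 ms spike width of real recordings, plus a repolarization
  wave — the field-potential T-wave analogue — proportional to the
  negative slow derivative with an amplitude drawn at 5–25% of the
  spike, and a first-order 0.2 Hz high-pass.  Slow baseline drift
  (5 µV RMS) and white noise complete the channel; the noise scale is
  set from a drawn max/σ ratio (20–150).
* White noise on the iAP channel hits a drawn S/N of 80–110 dB,
  bracketing the 90 dB inclusion threshold.

The generator reproduces the empirical couplings the reconstruction
relies on: eAP amplitude correlates with iAP spiking velocity at
r ≈ 0.87 across a default dataset, and the boosted-tree baseline
predicts APD30–90 from eAP descriptors with ~10–15% error — the same
regime reported for real recordings.  With `drug_sweep` set, the
dataset emulates one channel over time: a single per-channel baseline
APD with 2% beat-to-beat jitter, multiplied by a ramp that saturates
10% of the stream after onset.  What the generator does not emulate:
beat-to-beat waveform alternans, multi-unit contamination, motion
artefacts, electroporation re-poration transients, and the full
diversity of distorted eAP morphologies (only the monophasic class
appears).  Passing tests therefore demonstrate internal consistency of
the method under the stated couplings, not performance on any
particular laboratory's recordings.

## Reconstruction network

The quantile physics-informed attention U-Net is a 1-D encoder/decoder.
The reference configuration has 5 encoder stages of stride-5
downsampling with ceiling-division lengths (8000 → 1600 → 320 → 64 →
13 → 3), channels 32 → 64 → 96 → 128 capped at 4× the base, kernel
size 11, and 8 squeeze-and-excitation residual blocks — one per
encoder level plus three at the bottleneck.  Residual blocks apply two
convolution–batchnorm–activation blocks (ReLU then sigmoid); the SE
gate is computed from the block input (global average pool, reduction
8, ReLU then sigmoid) and rescales the block output before the
identity is added.  The decoder upsamples by linear interpolation
(nearest-neighbour is available but its staircase blunts the
reconstructed upstroke), gates each skip with additive attention, and
fuses by concatenation plus a CBR block.  Attention sits in the
decoder fusion path; a flag can disable it.  Convolutions use He
normal initialization; output-head biases start at 0.5, the midpoint
of the target range, so early training is not spent learning the
offset.

Three parallel output heads predict the 0.05, 0.5 and 0.95 quantiles;
per-quantile parameter heads (1×1 convolution on the bottleneck,
flatten, two dense layers) estimate (a, k, x), with sigmoids keeping a
and x in (0, 1) and a softplus keeping k positive so the residual
stays well-posed.  The loss is

    L = α·Σ_q L_D,q + β·log(Σ_q L_P,q),   α = 10, β = 0.01

with pinball data terms (under-prediction weighted by q) and physics
terms equal to the mean absolute F_AP of each head's waveform under
its own parameters, computed on interior samples with the sample
period exposed as `phys_dt` (default 1e-3 rescaled time units) and a
sign-preserving clamp at 1e-3 guarding the divisions.  The physics sum
is floored at 1e-12 before the logarithm.  Joint training of the three
heads discourages quantile crossing without an explicit constraint.
The optimizer is Adam at the stated initial learning rate with no
schedule by default for the full configuration; training is
deterministic given the seed.

The engine underneath is a compact reverse-mode autodiff layer over
float32 numpy arrays (`iaprec.autodiff`): strided 1-D convolution as a
sum of shifted thin matrix products, batch normalization with running
statistics, linear/nearest upsampling, the pointwise nonlinearities,
and Adam.  All gradients are verified against central finite
differences in the test suite.

### Desk-scale configuration

Tests and the worked example use a scaled-down network: input 2000
samples (the 8000-sample windows block-mean downsampled by 4, i.e.
1250 Hz), 8 base channels, 3 encoder levels, 4 residual blocks,
training on 500 synthetic pairs for 20 epochs with batch size 16 and
learning rate 1.5e-3.  These sizes keep a full train-and-evaluate
cycle within minutes on one CPU core while exercising every component
of the full architecture.

## Drug-response monitoring

Each channel's stream of windows is normalized, reconstructed, and
summarised per repolarization level by the median-head APD with the
[APD(v₀.₀₅), APD(v₀.₉₅)] envelope as uncertainty.  The median-head
trend is passed through a 3-point median filter before any statistic:
beat-to-beat reconstruction noise would otherwise bias the maximum
upward.  The pre-drug baseline is the mean APD over all windows before
the drug time (channels with fewer than three pre-drug windows are
excluded with a warning); the per-channel effect is the maximum
post-drug deviation from baseline, reported in seconds and percent at
levels {40, 50, 70, 90}, with the mean deviation alongside — the
maximum of a noisy series is positively biased even without an
effect, so calibration against a no-drug stream uses the mean.
One-sided one-sample t-tests ask whether each effect across channels
exceeds zero.

## Numerical choices and degenerate inputs

* Zero-noise windows, flat iAP windows, and zero-σ normalization
  segments raise `DegenerateWindowError` rather than emitting NaN.
* Segment selection is strict on the S/N cut (> 90 dB) and inclusive
  on amplitude (≥ 0.5 mV), idempotent and order-preserving.
* The RK4 integrator raises on non-finite state with a hint to reduce
  dt; (0, 0) is preserved exactly as a fixed point.
* Batches of size 1 are skipped during training (batch normalization
  needs at least two samples).
* APD crossings are linearly interpolated; the moving-average window
  of 20 samples bounds the achievable APD accuracy on step-like
  waveforms to roughly that width.

## Known limitations

* The held-out accuracy of the desk-scale network (normalized MAE just
  under 0.06; mean APD10–100 error of order 15–25%) is limited by the
  short training budget; the mid-range levels APD50–90 recover to
  within ~5–12% while APD10 and APD100 — the narrow peak-region width
  and the tail-base width — dominate the mean error.
* The single-equation residual is verified self-consistently (it
  vanishes on simulated solutions with second-order convergence)
  rather than re-derived symbolically.
* The generator's two-scale time mapping slightly decouples upstroke
  steepness from the model parameters; the physics loss treats the
  estimated (a, k, x) as free per-window parameters, so no
  inconsistency arises, but the estimated parameters should not be
  read as biophysical measurements.
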