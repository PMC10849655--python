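# Methods

This note documents the models, numerical methods, synthetic-data
assumptions, and design choices behind `natcont`, in the spirit of a methods
appendix. Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Encoding models

### Multiplicative adaptation (MA)

Each model neuron is the 4-parameter system

    τ_int dr/dt  = −r + x_s (1 − a_s) I_s(t) + x_p (1 − a_p) I_p(t)
    τ_a   da_m/dt = −a_m + I_m(t),   m ∈ {s, p}

with binary, mutually exclusive song indicators `I_s`, `I_p`. Parameters and
units: integration timescale τ_int (s, > 0), adaptation timescale τ_a (s,
`inf` allowed and treated exactly as "no adaptation"), selectivities x_s,
x_p (dimensionless, ≥ 0, also the response bound: from zero initial state
|r| ≤ max(x_s, x_p) for any binary input). A `polarity` sign (±1) multiplies
the output and stands in for neurons whose recorded signal decreases with
song; the dynamics themselves are unsigned. Both adaptation variables share
one τ_a.

One printed form of the pulse drive gates it with the *sine* adaptation
variable; we implement the mode-consistent gating x_p(1 − a_p)I_p, which is
what the verbal description of the mechanism (each mode's persistence
diminishes *that mode's* efficacy) and all downstream behavior (pulse blocks
plateau) require.

**Exact integration.** On each raster bin the inputs are constant, so both
ODEs are linear with constant coefficients. The adaptation update is the
AR(1) recursion `a ← E_a a + (1 − E_a) I` with `E_a = exp(−dt/τ_a)`; within
a bin the gated drive is `A e^(−t/τ_a)` with `A = Σ x_m (1 − a_m(0)) I_m`
(the active mode's gate relaxes exponentially; quiet contributes nothing),
giving the closed-form activity update `r ← E_int r + c A` with

    c = τ_a/(τ_a − τ_int) (E_a − E_int),            τ_a finite, ≠ τ_int
    c = (dt/τ_int) E_int                             (confluent limit τ_a = τ_int)
    c = 1 − E_int                                    (τ_a = inf)

Both recursions are constant-coefficient linear filters and are evaluated
with `scipy.signal.lfilter`, so a session is simulated in two vectorized
passes per neuron with no per-bin Python loop. The degenerate branch is
taken when |τ_a − τ_int| < 10⁻⁹ τ_int. The test suite verifies the exact
integrator against an independent explicit-Euler oracle at dt = 10⁻⁴ s
(max abs error < 10⁻³ · max(x_s, x_p) over random parameter/raster draws).

The step response from zero state has the closed form
`r(t) = x_m τ_a/(τ_a − τ_int) (e^(−t/τ_a) − e^(−t/τ_int))`
(limits `x_m (t/τ_int) e^(−t/τ_int)` and `x_m (1 − e^(−t/τ_int))` as above),
and a block of length T is the step response followed by pure `e^(−Δ/τ_int)`
decay. These closed forms back the fitting code, so block fits evaluate the
model analytically at the imaging frame midpoints.

### Linear–nonlinear (LN) and the matched construction

The LN neuron is `r = g(h_s * I_s + h_p * I_p)` with signed rectification
`g(z) = polarity · max(polarity · z, 0)`. `ln_from_ma` sets the filter taps
to the per-bin increments of the MA step response,
`h[k] = (S((k+1)Δ) − S(kΔ))/Δ`, so the discrete convolution of a step input
reproduces the MA step response *exactly* on the grid; filters carry the
polarity sign so rectification passes them through. MA and matched LN are
therefore identical on single-mode blocks during stimulation (machine
precision in the tests) and — when τ_a = inf, i.e. the MA model is linear —
identical on arbitrary songs up to grid error.

They differ in two informative places. After block offset the MA activity
decays as `e^(−Δ/τ_int)` from its plateau, while the LN output is the filter
tail `S(t) − S(t − T)`, which for adapting neurons collapses within ~τ_a and
can undershoot into rectification. And on patterned song the MA nonlinearity
acts *before* integration, so gaps re-open the gate and responses
accumulate; the LN nonlinearity acts after the linear stage and cannot do
this. Both differences are what the NC comparison exploits.

## Fitting block responses

Data are trial-averaged sine- and pulse-block traces over a 10 s stimulus
plus 10 s post-stimulus window at 8 Hz (all three configurable via
`BlockStimulusSpec`); the model is evaluated at frame midpoints. Polarity is
set from the sign of the dominant sample across both traces. Because the
selectivities scale the (rectified) unit response linearly, the optimal
non-negative x_s, x_p given the timescales are closed-form projections; the
remaining loss is minimized over (log τ_int, log τ_a) — log-space keeps the
timescales positive and evens out curvature across decades — by L-BFGS-B
from a 4×4 multi-start grid over τ ∈ {0.3, 3, 30, 100} s (the loss has
timescale-separated local minima), followed by a bounded Nelder–Mead polish.
Bounds are τ ∈ [10⁻², 10⁴] s; an effectively non-adapting neuron fits to the
upper τ_a bound. The LN fit uses the same concentrated 2-D scheme with the
LN forward model and adds the MA fit's timescales as a start. Identical zero
traces yield x ≈ 0 with R² defined as 0 (zero-variance convention).

On noiseless synthetic blocks the MA fit recovers all four parameters to
~10⁻¹⁰ relative error; the acceptance-level claim tested is 5% on at least
45/50 fast-adapt/slow-integrate draws. For slow-integrate/fast-adapt ground
truth the LN fit is *structurally* worse (it cannot hold the offset
plateau); across a regime mixture resembling the diversity of measured
block responses the median R² gap between the two fits is small (< 0.05,
typically < 0.01). Note that slow-integrate neurons have block-response
amplitude ~x τ_a/τ_int, so realistic trace noise affects their parameter
recovery much more than fast neurons'.

## The NC scoring pipeline

Artificial recordings: each neuron is simulated from zero state on the
session's song rasterized at 0.01 s; the activity assigned to target time t
is the state at the last raster bin ending at or before t, so predictions
use song strictly up to t (causality is tested). The behavioral target is
walking speed forward-averaged over (t, t + 1 s] at 1 s strides (window and
stride configurable; a 60 s window uses the same code path).

The readout is ridge regression on features standardized with training-row
statistics only, intercept unpenalized. The ridge penalty is chosen by
internal cross-validation over a log grid (10⁻⁴ … 10⁴) on the training rows
unless fixed — the reference analysis does not print its penalty, and CV is
scale-free and reproducible. Scores are variance explained pooled over all
held-out timepoints (per-session averaging is an option), over 30 random
80/20 session-level splits; mean ± SE over splits is reported. Baselines
(timestamp, trailing 2-minute mean bout duration, ridge-learned lagged
filters on the raw song indicators — 60 one-second taps per mode by
default) run through the identical split engine with the same seed, so
comparisons are paired. The song-shuffle control permutes songs across
sessions (derangement preferred), truncating or quiet-padding each song to
the receiving session's duration.

Sweeps reuse the same engine: population size (mean ± sd over random
instantiations), number of neural PCs kept (PCA fit on standardized
training rows; at full rank this is an orthogonal rotation and reproduces
the unprojected score exactly when the penalty is matched), the 3×3
fast/medium/slow τ_int × τ_a regime grid plus a no-adaptation row, and the
heterogeneity comparison (fixed τ_int = 120 s with τ_a ~ U[0.1, 2] s versus
fixed τ_a = 0.5 s with τ_int ~ U[20, 120] s; the fixed values are defaults,
exposed as parameters). A `lowpass_ve` helper scores 30 s moving-average
smoothed target/prediction pairs; it is a convenience only and is not
validated against any published quantity.

## Characterization analyses

**Entropy.** Plug-in entropy of the 16-bin histogram of a neuron's activity
samples, binned over the neuron's own observed [min, max] (a fixed support
is an option; the normalization of published "normalized activity" axes is
not printed). Deterministic encoders have H[r|song] = 0, so this entropy
*is* the mutual information between momentary activity and song. Constant
responses give 0 bits; normalization divides by log2(16).

**Population PCA.** PCA of pooled mean-centered activity; when behavior is
supplied, each component's sign is flipped so its weight in a ridge
regression of walking speed on the PC projections is negative — "more of
any PC predicts slowing" — matching the sign convention of the reference
figures.

**Trajectory distance scaling.** Songs drive the population from zero
state; Euclidean distances between trajectory pairs are measured at matched
elapsed times on a log-spaced lag grid (default 20 points from 0.1 s to 80%
of the song duration, snapped to distinct raster bins), averaged over pairs
(we fit the log of the mean distance, averaging before the log), and γ is
the least-squares slope in log–log; mean ± sd over repetitions of the pair
draw. With finite τ_int the dynamics are bounded and distances saturate —
the late-lag local slope falls toward zero (tested) — so scaling runs use
the effectively-infinite-τ_int population and the lag grid must stay out of
the saturation regime.

Two properties the tests pin down: (i) with no adaptation and τ_int → ∞ the
trajectories are random walks and γ = 0.5 within sampling error; (ii) with
fast adaptation, the drive is *negatively* autocorrelated over ~τ_a
(sustained input closes the gate), which makes the distance curve
sub-diffusive over an intermediate band before the asymptotic √t regime.
The strength of that dip grows with song density: at i.i.d. song density
~0.5 the fitted γ over four decades drops to ~0.40, while at the default
density (~0.23, see below) γ ≈ 0.48–0.50. Bin width matters little
(γ moves by ~0.03 across 0.05–1.0 s bins).

**Accumulation correlations.** For one neuron across many fixed-length song
segments, Pearson correlation (linear trends, hence not rank-based) of the
end-of-segment activity with the segment's song density and transition
rate. Zero-variance features or responses yield NaN (flagged, not raised).
The non-adapting slow integrator correlates ~1 with density; faster
adaptation shifts sensitivity toward transition rate (tested as a monotone
trend over τ_a ∈ {10, 2, 0.5} s).

**Reservoir readouts.** Ridge (α = 10⁻¹⁵, SVD solver) readout of a target
waveform from one song-evoked trajectory, evaluated in-sample — the
question is realizability of the target from the trajectory, not
generalization; cross-song evaluation would be a separate mode.
`reservoir_sweep` tabulates RMSE of unit sine targets across target periods
and songs for MA and matched-LN populations (and optionally the raw song
indicators).

## Synthetic data

The song generator is a ternary semi-Markov chain over {quiet, sine,
pulse}: exponential (or gamma) dwells with per-state means, a zero-diagonal
jump matrix, starting in quiet. Defaults — quiet dwell 10 s, mode dwell
0.6 s, within-bout mode continuation 0.8 — give bouts of ~1–16 s (mean
~3 s), mode dwells ~0.1–2 s, and a long-run song density of ~0.23. These
are order-of-magnitude emulations of courtship song statistics (short
alternating modes in bouts separated by longer quiet gaps), chosen once;
no published dwell distributions exist in numerical form to calibrate
against. What the generator does *not* emulate: within-bout rhythmic
structure, the heavy tails of real gap durations, sender–receiver feedback,
and any dependence of song on female behavior. Passing tests therefore
demonstrate correctness of the pipeline and the qualitative physics of the
code, not quantitative agreement with real courtship data.

I.i.d. songs (for scaling runs) draw every bin independently with marginals
equal to the stationary time fractions of the default generator — i.e. an
i.i.d. song is the marginal-matched scramble of a typical naturalistic
song, the same construction used for scrambled-song controls. Default bin
width is 0.1 s (coarser than the 0.01 s naturalistic raster; γ is
insensitive to this in the integrator limit).

Synthetic studies build sessions whose walking speed is
`max(0, intercept + w · activity + ε)` at 10 Hz, with weights drawn
N(−0.8, 0.4) mm/s per unit activity (slowing-dominated, as song predicts
slowing) and noise ε of configurable sd (default 0.5 mm/s). The intercept
defaults to a floor of 2 mm/s plus the worst-case negative drive bound
Σ min(w_i, 0) max(x_s, x_p)_i — computable from the population alone — so
the noiseless speed never clips and the song → behavior map is exactly
linear at zero noise; with noise the floor can bind occasionally. Sessions
draw per-session song statistics (quiet dwell log-uniform 4–30 s, bout
continuation uniform 0.7–0.9): courtship pairs differ widely in song
amount, and without this across-session heterogeneity all sessions share a
deterministic accumulation trend that a readout can exploit even with
shuffled songs. Seeding is hierarchical (`SeedSequence.spawn`): one stream
per session and one each for the population and weights, so enlarging a
study leaves existing sessions bit-identical.

Synthetic block recordings evaluate each ground-truth neuron's closed-form
block response at the frame midpoints, add i.i.d. Gaussian noise per trial,
and average the configured number of trials.

## Problem sizes and numerical conventions

Times are seconds throughout; intervals and raster bins are half-open
[start, end), which avoids double counting at boundaries. Naturalistic
rasters default to 0.01 s bins (mode durations ~30 ms), i.i.d. scaling runs
to 0.1 s. The packaged scaling analysis uses 57 songs of 25 minutes, 30
repetitions of 100 pairs — a few seconds of compute — and the synthetic
studies in the tests use 4–10 sessions of 60–300 s, sizes at which every
pipeline property asserted (recovery, shuffle collapse, noise floors) is
stable across seeds. Optimizer convergence: `ftol` 10⁻¹⁴ / `gtol` 10⁻¹²,
10⁴ iteration cap; zero-variance targets score 0 by convention everywhere
(R², VE, entropy support).

## Known limitations

- The LN↔MA matching is defined by step-response equality (the testable
  contract); any analytic filter formula beyond that is not reproduced.
- Single-trial fitting, indicator (calcium-sensor) kinetics, sine-offset
  response classes, spiking, and noise inside the encoders are out of
  scope; the encoders are deterministic by design.
- `nc_score` assumes behavior is linearly readable from activity;
  nonlinear readouts are out of scope.
- The entropy estimator is the plug-in histogram estimator; it is biased
  for small samples and is intended for the long aggregated traces used
  here.
- Real-data headline numbers (e.g. scores on the 87-session courtship
  dataset, γ on real 5-minute songs) require datasets that are not
  packaged; the package reproduces the simulation-defined quantities and
  the qualitative structure only.
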