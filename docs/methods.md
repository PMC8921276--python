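# Methods

This note documents the models, estimator conventions, numerical choices
and limitations behind `spiketexture`.  Units throughout: spike times in
ms (relative to texture contact, or to window start after windowing),
scanning speeds in mm/s, firing rates in spikes/s, spatial positions in
mm.

## Analysis window

All analyses operate on a 500-ms steady-state epoch beginning 100 ms
after texture contact, excluding onset/offset transients.  The window is
half-open, `[start, start + duration)`; windowed trains are re-referenced
to the window start.  Duplicate spike times encountered at ingest
(recording artifacts) are collapsed to a single event with a logged
warning, because the metric layer requires strictly increasing times.

## Spike distance

The Victor–Purpura distance is computed by exact dynamic programming:
insertion/deletion cost 1 per spike, shift cost `q·|Δt|` with `q` in 1/s
and `Δt` in seconds (so moving a spike more than `2000/q` ms is never
cheaper than delete+insert).  The nominal temporal resolution of a given
`q` is taken as `1000/q` ms, i.e. `q = 500` ↔ 2 ms.  The alternative
`2/q` convention exists in the literature; this package uses `1000/q`
because it is the pairing quoted with the repeatability analysis
(`q = 500`, "2 ms"), and any `q` can be supplied directly.  At `q = 0`
the distance reduces exactly to the spike-count difference.  The
implementation is validated in the test suite against a brute-force
oracle that enumerates all injective partial matchings on small trains.

## PSTHs and timing similarity

PSTHs are spike counts binned at `min(kernel_sd/2, 1)` ms (floor 0.1 ms),
converted to spikes/s, and convolved with a unit-area Gaussian truncated
at ±4 SD with reflected boundary mass, so the undemeaned PSTH integrates
exactly to the spike count.  Demeaning (subtracting the mean) removes all
overall-rate information; the demeaned PSTH is what timing analyses
consume.  An empty train yields an all-zero PSTH and zero similarity to
anything.

Timing similarity between two demeaned PSTHs is the **maximum of the
zero-mean cross-correlation over lags within ±50 ms** (unnormalized: sum
of lagged products × bin width; a correlation-coefficient mode exists for
sensitivity analyses).  The lag search exists to tolerate small phase
shifts between repeats.  Numerical choice: lags are evaluated
*circularly* (indices wrap at the window edge).  With zero-padded linear
correlation, a demeaned PSTH's constant baseline (−mean everywhere) makes
even a pure phase shift lose ~`lag·mean²` of covariance at the edges — a
percent-level penalty that contradicts the purpose of the lag search.
Under the circular convention a pure shift within the lag bound is
exactly cost-free; wrapped content is at most 10% of the window at the
default bound.  A `mode="linear"` option provides the zero-padded form.

## Synthetic data generator

The generator is the package's test bed; its defaults define the study
conditions under which all recovery and contrast tests run.

* **Textures** are spatial modulation profiles on a 0.01-mm grid:
  Gaussian noise band-passed to 0.1–10 cycles/mm with a random spectral
  tilt (flat to 1/f), exponentiated (log-normal, modulation depth drawn
  from 0.6–1.4) and normalized to mean 1.  The band covers feature scales
  from 0.1 mm to 10 mm, i.e. temporal frequencies of 8–800 Hz at
  80 mm/s — structure at every resolution the decoders sweep.
* **Master patterns.**  Each neuron × texture holds a *master* spike
  pattern drawn once from an inhomogeneous Poisson process whose spatial
  intensity is the texture profile scaled to the neuron's mean rate.  A
  trial keeps each master spike with probability `pattern_strength`,
  jitters it by `Normal(0, temporal_precision)` ms, and tops up with
  homogeneous Poisson spikes at `(1 − pattern_strength) × rate`, so the
  expected trial rate equals the specified rate exactly and
  trial-to-trial temporal variability is governed by a single parameter —
  the same quantity the repeatability analysis estimates.  Jittered
  spikes leaving the window are reflected back.
* **Speed.**  The master lives in spatial coordinates shared by all
  speeds; per-speed patterns are nested thinnings (keep probability ∝
  `speed^(α−1)`), so warped trains align in absolute position across
  speeds while temporal rates scale as `(speed/80)^α`.  Default α = 0.5
  (configurable; 0 disables rate–speed modulation): rates are known to be
  speed-modulated but no quantitative law is established, and a square
  root is a conservative sublinear choice.
* **Rate tuning and submodality.**  Afferent class rate vectors (SA1,
  RA, PC) are built from an exactly orthogonalized common+idiosyncratic
  decomposition, giving pairwise correlations of 0.4 by construction
  (classes related but distinct), with means/SDs of 50/15, 60/18, 45/12
  spikes/s.  A neuron's per-texture rate offsets are
  `rate_tuning_sd × (w·ẑ + noise)` where `w` are its submodality weights
  and `ẑ` the z-scored class vectors (15% residual noise), which makes
  submodality regression recovery well-posed.
* **Population composition** mirrors the recorded proportions: 12
  PC-like (jitter 0.5–2 ms, pattern strength 0.6–0.9), 12 RA-like
  (2–6 ms, 0.4–0.7), 25 SA1-like (10–30 ms, ≤0.2, high rate-tuning SD)
  per 141 neurons, the remainder mixed; scaled designs keep these
  fractions.  Dominant-group submodality weights are drawn in 0.90–0.97
  and dominant-group rate-tuning SDs in 15–25 spikes/s: with 5 repeats
  and 24 shared textures, measurement noise attenuates standardized
  betas by ~5%, and these ranges keep the planted dominance recoverable
  at the 0.8 threshold.  Base rates are uniform in 20–100 spikes/s
  (configurable; recorded rate distributions are not quantitatively
  matched).
* **Determinism**: every random draw is keyed by `(seed, stream-tag,
  indices)` through `numpy.random.default_rng`, so `(config, seed)`
  regenerates bit-identical data.
* **Ratings** are generated linearly from the built predictor features
  (per-subpopulation rate differences and timing correlations) plus
  Gaussian noise (default 25% of the systematic SD), then shifted/scaled
  to nonnegative mean-1 values like normalized psychophysical ratings.
  Because the generative features are the analysis features, coefficient
  recovery is exact at zero noise.

What the generator does **not** emulate: biomechanical skin dynamics,
afferent spike trains (only class mean rates), adaptation or
nonstationarity within a trial, correlated noise across neurons, and
electrode artifacts.  Passing tests therefore demonstrate estimator
correctness and sensitivity under controlled structure, not performance
figures for recorded cortex.

## Precision estimation (repeatability analysis)

For each neuron × texture: measured variability is the mean spike
distance over all unordered repeat pairs at `q = 500`.  Surrogate
variability is computed identically from count-matched jittered copies of
the neuron's own response at each level of a log-spaced 12-level jitter
grid (0.1–200 ms).  The default count-matching policy starts from the
largest-count repeat and removes spikes uniformly at random (ties broken
by lowest repeat index); the converse add policy (smallest-count base,
uniform insertions) is available and statistically indistinguishable on
synthetic neurons (two-sample KS test in the suite).  The estimate is the
mean of the two adjacent grid levels whose surrogate distances bracket
the measured distance; measured values below (above) the whole curve are
censored at the lowest (highest) level and flagged rather than dropped.
If the noisy surrogate curve crosses the measured level more than once,
the first crossing is used and a warning logged.  An alternate readout —
the zero crossing of the rate-normalized difference curve
`(simulated − measured)/rate`, log-interpolated — is provided; the
bracketing average is primary because it is the convention with a printed
worked example (15 between 13 and 21 → 1.5 ms).

## Decoding conventions

Leave-one-out is **block-structured**: the test trial's repeat index
(presentation block) is held out of *every* candidate texture's training
set.  This matches "the mean response across all remaining repeats of
every texture" and keeps every candidate estimated from the same number
of repeats.  The asymmetric alternative (own texture 4 repeats, others 5)
gives the own candidate a variance advantage under the argmax and
measurably inflates the Poisson chance control (to ~2× chance on
synthetic surrogates), so it is not used.

Ties at the argmin are broken uniformly at random from the seeded
generator of the call.  Combined decoding z-scores each neuron's rate and
timing tables over all entries, evaluates weights 0–1 in steps of 0.05
(weight selection on the same leave-one-out accuracies; a nested
selection would be needed for unbiased generalization estimates, but the
in-sample convention is what the combination analyses report), and uses
each neuron's best timing resolution from the sweep (accuracy ties go to
the smallest kernel).  Population decoding averages z-scored tables over
neurons sampled without replacement (1000 iterations by default; fewer in
the scaled test suite) and compares schemes with a one-sided permutation
test on iteration accuracies.  The permutation test is implemented as a
paired sign-swap (iterations are matched by index); a pooled-relabeling
mode is available for unpaired samples.  The p-value is the exact
proportion of shuffles with a difference ≥ observed, without smoothing.

## Speed warping

Warping multiplies spike times by scanning speed (`warp`/`unwarp` are
exact inverses).  For cross-speed analysis, windowed times are first
absolutized to contact (`t + window_start`): the analysis window covers
different spatial segments at different speeds, and only
contact-referenced positions align in absolute position on the surface.
Comparisons are truncated to the spatial region scanned at every speed
(e.g. 12–36 mm for 60 vs 120 mm/s), spatial PSTHs use kernel SDs in mm
(0.16 mm ↔ 2 ms at 80 mm/s) and a ±2-mm lag bound.  Cross-speed
classifiers follow the 4-train/1-test protocol: every test-speed
repetition is scored against every 4-repeat training fold of the training
speed.  Rate classifiers use spikes/s unwarped and spikes/mm warped; the
latter overcompensates the `(speed/80)^0.5` rate modulation, which is why
the package's cross-speed population combination pairs *unwarped* rate
with *warped* timing.

## Submodality profiling and the perceptual link

Submodality regression z-scores the neuron's per-texture mean rates and
each afferent class vector across the shared textures and fits OLS
without intercept (all variables centered), so coefficients are
standardized betas; the label is the class with beta > 0.8, none →
unclassified, two or more → flagged ambiguous rather than labeled.
Rank-deficient predictors raise an error naming the collinear classes.

Perceptual features are built per cell and z-scored across the 78 pairs
before averaging within subpopulation — for rate differences as well as
timing correlations, for symmetry.  Pair-level timing similarity uses
trial-averaged demeaned PSTHs at the cell's best decoding resolution
(per-trial-pair averaging is available as a mode), kept as a similarity
so its fitted sign against dissimilarity is expected negative.
Cross-validated regression is leave-one-pair-out OLS with intercept,
computed exactly via the hat matrix; the reported statistic is the mean
squared error of the held-out predictions over all pairs.

## Problem sizes

The full designs (141 neurons × 59 textures × 5 repeats at 80 mm/s;
49 × 10 × 4 speeds × 5) are implemented and generated by
`simulate_study`.  The statistical tests and the acceptance script run on
scaled versions chosen to keep the default runs fast — e.g. 30 surrogate
neurons for the chance-level controls (binomial tolerance computed at the
realized trial count), a 40-neuron/20-texture study for population
contrasts, 12 cells per group for the submodality contrasts, and a
16-neuron speed study — sizes at which the tested effects are
well-resolved.

## Known limitations

* Synthetic rate distributions and rate–speed scaling are plausible
  defaults, not fits to recorded data; absolute accuracy figures on
  synthetic data are not comparable to recorded-cortex figures.
* The circular cross-correlation convention can, in principle, match
  wrapped structure across the window edge (bounded by the lag fraction
  of the window).
* Precision estimates are grid-quantized (midpoints of adjacent jitter
  levels) and censored at the grid extremes; neurons with near-zero rates
  yield degenerate (zero-distance) estimates that appear as low-censored.
* Weight selection for the combined decoder is in-sample by convention;
  use the per-neuron weight curves if an unbiased comparison is needed.
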