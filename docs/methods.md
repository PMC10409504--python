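# Methods

This note documents the models and numerical choices behind `larvacrawl`:
what the pipeline computes, what the synthetic-data generator emulates and
does not, and where genuinely open design decisions were made.

## Stride segmentation

A stride runs between consecutive mouth-hook unhooking moments.  Published
analyses of this behaviour annotate unhooking manually; the package uses an
automated proxy: the forward (x) velocity of the head landmark is smoothed
with a 5-frame moving average, and an unhooking moment is an upward crossing
of a velocity threshold (default 0.2 mm/s) held for at least 3 frames.
Because centered smoothing advances an onset by up to ~2 frames, the
crossing is refined: first back off on the smoothed trace to half the
threshold, then advance to the first frame whose *raw* velocity exceeds a
noise floor (max of a quarter threshold and 3 robust sds of the raw
velocity over still frames).  On noise-free data this recovers the motion
onset exactly; with realistic tracking noise it stays within about one
frame.  All constants live in `AnalysisConfig`.

The wave onset inside a stride is the first time the A8 denticle has moved
half a segmental length from its previous landing position, with the
crossing linearly interpolated between frames.  The landing position is the
level of the denticle's last stationary plateau (speed below threshold for
≥ 3 frames) before the stride begins; if that plateau extends past the
stride start (a slow sub-threshold drift), only its portion up to the
stride start is used.  Stride length is the difference between consecutive
landing levels.  The segmental length defaults to the mean head-to-A8
distance divided by 11 (three thoracic + eight abdominal segments) and can
be overridden in the config; strides whose displacement never reaches the
half-segment threshold are flagged degenerate and excluded from phase
statistics.  Phase additivity (interwave + wave = stride duration) holds
exactly because the wave phase is defined to end at the next unhooking.
Incomplete first/last strides are discarded: every per-stride metric needs
both boundaries.

Episode speed is total stride length over total stride duration; stride
frequency is the reciprocal of the mean stride duration.

## Contraction events

`detect_contractions` finds local length minima (prominence ≥ 8% of the
trace range — below any realistic contraction, above tracking ripple),
takes the preceding local maximum as the reference length L_ref, and places
the event boundaries at the crossings of L_ref − f·(L_ref − L_min), with
the fraction f = 0.5 by default and sub-frame linear interpolation.  Events
shorter than 2 frames are discarded.  Amplitude is defined as relative
shortening (L_ref − L_min)/L_ref; the source analyses plot "contraction
amplitude" without a formula, and the relative form removes dependence on
animal size.  An event is paired to the stride whose interwave interval it
overlaps most (ties to the earlier stride).

## Correlation, regression, model selection

Pearson correlation and OLS regression are standard (scipy).  Model
selection compares polynomials of degree 2–10 with a continuous two-piece
linear model using BIC = K ln n + n ln σ̂², the least-squares/Gaussian
reduction of K ln n − 2 ln L̂ (the two differ by the model-independent
constant n(ln 2π + 1) and always rank models identically; both are
implemented and the equivalence is tested).  K counts the regression
coefficients for polynomials (degree + 1, σ² not counted, consistent with
the reduced formula's derivation) and K = 4 for the piecewise model (two
slopes, one intercept, and the breakpoint, which is counted because it is
estimated by search).  The breakpoint is grid-searched over 50 interior
x-quantiles, excluding the outer 5% so both pieces stay identifiable; σ̂²
is floored at 1e-12 and flagged as a perfect fit below that.  Ties in BIC
resolve toward smaller K.

## Calcium synchrony

Traces are min-max normalized over the whole recording.  Cycles are aligned
by mapping one anchor ROI's peak to normalized time 0 and a second anchor's
to 1 (the anchor pair is a parameter, default nSyb A4 → A2, since the
source descriptions disagree between A4/A1 and A4/A2), then resampled onto
a 100-point grid by linear interpolation so cycles of unequal duration can
be averaged.  Peaks are local maxima above 20% prominence with a minimum
separation (default 0.5 s).  Time-lagged cross-correlation slides one trace
in one-frame steps and computes the Pearson correlation on the full
overlap; positive lag means the second trace is delayed.  Curves from
several recordings are averaged per lag with the Fisher-z correction,
tanh(mean(atanh r)), with r clipped at ±(1−1e−6); the intersegmental lag is
the argmax of the averaged curve (ties toward zero lag).  Relative peak
times map each target-cell peak onto the [0, 1] axis spanned by consecutive
bracket-cell peaks.  ΔF/F computation from raw fluorescence is provided as
a helper ((F − F₀)/F₀, F₀ = 10th percentile) but the core path consumes
ΔF/F directly.

## Hierarchical bootstrap

Optogenetic experiments repeat trials within animals, so trials are not
independent.  Each of 10,000 (default) resamples draws n animals with
replacement, then for each drawn animal its own number of trials with
replacement; the statistic is the animal-wide mean μ (animals weighted
equally).  The within test forms {μ*_b − μ} and reads the one-sided p as
the fraction of draws at or beyond μ itself; the between test draws
independent pairs (μ_a*, μ_b*), bins them on a 100×100 joint histogram
spanning both marginals and takes the mass on one side of the diagonal
(diagonal bins split evenly).  The binning-free pair fraction
mean(1[μ_a* ≤ μ_b*]) is computed alongside as an internal oracle; the two
agree within 0.01 at the default resolution.  Sidedness is not stated in
the original description; the default is two-sided (2·min of the one-sided
values, capped at 1), with one-sided options exposed.  p-values are floored
at 1/n_boot: finite resampling cannot certify zero.  Significance labels
follow *p<0.05, **p<0.005, ***p<0.0005 with strict inequalities.

## Synthetic data generator

The generator produces landmark tracks, muscle traces, calcium traces and
nested trial tables with ground truth, emulating the statistical structure
of the study conditions: 18 larvae × 3 episodes × 5 strides for the
top view and 9 larvae × 2 episodes × 4 strides for the side view, at 30 Hz,
body length 4 mm.

**Speed is emergent.**  Each episode has a latent drive speed; stride
length follows the kinematic identity length = drive × duration (plus 5%
noise), so the measured episode speed (Σ length / Σ duration) concentrates
at the drive.  Animal drives are stratified over the speed range
(shuffled quantile midpoints, ±0.05–0.06 mm/s episode offsets), emulating
the observed per-episode speed variation (~0.38–1.20 mm/s) without
requiring hundreds of animals for stable range coverage.

**Two kinematic parameterizations.**  The side-view model is additive:
interwave = max(floor, a_i + b_i·v + ε_i) and wave = max(floor, a_w +
b_w·v + κ·ε_i + ε_w), with episode- and stride-level noise components.
The top-view model is parameterized directly in (duty factor, stride
duration) space — duty = clip(a_D + b_D·v + ε_D, 0, 0.9), duration =
max(floor, a_T + b_T·v + ε_T) with ε_T partially coupled to ε_D, and
interwave = duty·duration — because the joint pattern of the published
top-view statistics (duty-factor r² on speed essentially equal to the
squared interwave–speed correlation) is unattainable when duty factor is a
derived ratio of two independently noisy phases: the ratio accumulates
wave-phase noise that the interwave alone does not carry.  The duty-noise
sd additionally scales with the local mean duty level (a power-law
exponent, default ≈1.7), reproducing the observed funnel: large duty
scatter at slow speeds, pinching to zero at fast speeds.  Both models give
duty → 0 at the fastest speeds.

**LT2 coupling.**  The planned LT2 contraction duration is
max(floor, 0.8·interwave + small loads on the wave-phase noise and on
episode/stride contraction noise); the 0.8 factor keeps contractions inside
the interwave (Pearson correlations are unaffected by the scale), and the
wave-noise load supplies the weak contraction–wave correlation that a pure
interwave coupling cannot.  Muscle shortening is a raised-cosine pulse
whose half-depth width equals the planned duration, so threshold crossings
at f = 0.5 are closed-form; LT2 pulses are synchronous across A2–A7 and
centered in the interwave, longitudinal muscles (VL4/DO1) contract
sequentially posterior→anterior during the wave with a configurable
intersegmental lag, and the posterior-most segments (A6–A7) also contract
during the interwave.

**Calcium.**  Fictive cycles (default period 10 s) convolve event times
with a fast-rise/exponential-decay kernel (rise 0.2 s, decay 0.8 s),
shifted so the kernel peak lands at the configured peak time.  nSyb-like
ROIs peak sequentially with a configurable per-segment lag plus synchronous
posterior activity between waves; A31c/A26f-like ROIs burst synchronously
across segments, the A26f burst midway between consecutive A31c bursts.

**Optogenetic trials.**  value = baseline + animal effect (sd σ_a) + trial
noise (sd σ_w) + condition effect δ, two groups with the true δ returned.

**Variance-matched sampling.**  The published statistics come from fixed,
modest sample sizes (~270 and ~72 strides), at which i.i.d. noise makes an
emergent correlation fluctuate by ±0.05 or more between seeds.  Calibrated
profiles therefore use variance-matched streams: stride-level noise is
projected to zero episode mean and orthonormalized against the speed design
and the other streams; episode-level streams are orthonormalized across
episodes.  Marginal structure is preserved while the emergent statistics
concentrate (cross-seed sd ≤ ~0.015), so a dataset of the study's size
behaves like a typical rather than an arbitrary draw.  This is a
variance-reduction device, not a claim about real data: real recordings
would scatter more between cohorts of this size, and passing recovery tests
on matched draws demonstrates pipeline correctness at the calibrated
operating point, not cohort-to-cohort reproducibility.  Plain i.i.d.
sampling is available (`moment_matching: false`) and is used in tests of
the distributional machinery.

**Calibration.**  `calibrate_profile` maps each target statistic to exactly
one profile parameter and solves them sequentially by damped secant sweeps
on the simulated estimate (averaged over ≥3 seeds).  The shipped
`fig1_topview`/`fig1_sideview` profiles were calibrated with the same
one-parameter-per-statistic mappings against the full pipeline — generator
→ segmentation → event detection → statistics — over seeds 1–5, so the
frozen parameters already absorb the pipeline's small systematic
measurement effects (frame quantization, onset refinement).  Re-running the
pipeline on fresh seeds reproduces each calibrated statistic within ±0.05
(±0.07 for the two weakest side-view correlations).

## Limitations

The generator reproduces the *statistical couplings* of crawling, not
biomechanics: no hydrostatics or forces, head trajectory is a stylized
smooth advance, landmark noise is white rather than tracking-correlated,
and muscle pulses are symmetric.  The automated unhooking rule is a stated
proxy for manual annotation, not a validated equivalent.  Calcium traces
use generic indicator kinetics without bleaching or motion artifacts.
Bootstrap problem sizes in the test suite (e.g. 200 null datasets at 2,000
resamples) are chosen to give stable calibration estimates at interactive
runtimes; the defaults used for analysis remain 10,000 resamples.
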