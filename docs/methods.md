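# Methods

This note records the scientific and numerical choices behind the
pipeline: the generative and inferential models, the defaults and their
units, what the synthetic data do and do not emulate, and the places
where the design was genuinely open and a decision had to be made.

## Montage geometry

The default montage is an idealized extended 10-20 arrangement of 65
electrodes (the 64 cap channels plus the online reference FCz) on a unit
sphere. Spherical coordinates follow the convention: polar angle θ
measured from the vertex, azimuth φ from the right-lateral axis rotating
toward the nasion, so the Cartesian model covariates are
(ML, AP, IS) = (sin θ cos φ, sin θ sin φ, cos θ) with +ML at the right
ear, +AP at the nasion, +IS at the vertex, each confined to [−1, 1].
Positions are constructed programmatically: the outer ring sits at
θ = 72° in 18° azimuth steps, the sagittal midline in 18° steps, the
interior rows are spaced evenly along great-circle arcs between midline
and ring sites, and the 9/10 electrodes (FT9/10, TP9/10, PO9/10) lie on
the equator. Commercial caps use a realistic head rather than a sphere;
this idealization keeps Cz exactly at (0, 0, 1), makes the layout
deterministic without any data file, and is adequate because the models
consume the coordinates only as smooth spatial regressors. Nearest
neighbors for Laplacian interpolation use great-circle distance with
k = 4 by default (the classical Hjorth scheme), ties broken by label
order.

## Synthetic cohorts

The generative model for log10 alpha power (units: log10 µV² per
0.5-Hz bin) is

    y = b0 + b_group·G + (b_sleep + b_int·G)·S + b_eyes·E
        + g_ml·ML + g_ap·AP + g_is·IS + u_participant + ε

with G = 1 for the non-abstinent group, E = 1 for eyes open, S the 0–10
sleep rating, u ~ N(0, σ_p²), ε ~ N(0, σ_n²). Defaults:

| parameter | default | rationale |
|---|---|---|
| b0 | 1.30 | places the abstinent-group mean alpha near 0.2 at typical sleep (≈ 6) |
| b_group | −0.36 | group contrast of the assumed magnitude |
| b_sleep | −0.19 | abstinent-group sleep slope (the regime the recovery tests probe) |
| b_int | +0.14 | yields a non-abstinent slope of −0.05 |
| b_eyes | −0.40 | eyes-open alpha suppression, typical reactivity |
| g_ml, g_ap, g_is | +0.10, −0.30, +0.20 | posterior/right/superior alpha gradient |
| σ_p | 0.50 | between-participant SD consistent with a group contrast of this uncertainty at n = 32 |
| σ_n | 0.30 | residual electrode-level scatter |

Sleep quality is a discretized normal (mean 6, SD 2) truncated to the
integers 0–10; both groups share the distribution, matching the design
assumption that sleep quality itself does not differ by group.
Days-since-use is uniform on 30–104 days (abstinent) or 1–13 days
(non-abstinent). Arbitrary extra interaction terms (e.g.
`"Sleep:Group:AP"`) can be added to the predictor for studying
higher-order moderation.

**Waveform mode.** Scalp potentials are simulated at all 65 sites and
the recording emits the 64 cap channels referenced to FCz, so average
re-referencing genuinely recovers the reference — as with real data.
Alpha content is a comb of equal-power sinusoids at the 11 alpha-band
bin frequencies (8–13 Hz in 0.5-Hz steps), phase randomized per 2-s
block and channel. A comb rather than a single 10-Hz carrier is
essential under the band statistic used here (mean of *log* bin power):
with a lone carrier the other ten bins sit at the numerical floor and
the statistic cannot be matched to an arbitrary target. Because every
comb frequency is a multiple of 0.5 Hz, a stationary variant
(`block_random_phase=False`) repeats seamlessly across blocks and makes
the two recording halves identical — the exact-reliability limit.

Two small biases of the measurement chain are pre-compensated so the
measured band power equals the tabular linear predictor: the average
reference mixes a 1/65 share of every channel into each other channel
(inverted with a rank-one correction of the per-channel power targets),
and a tapered window is not orthogonal across FFT bins, so comb lines
leak slightly into neighboring band bins (inverted by solving the
11×11 expected-gain system computed with the pipeline's own estimator).
With background and observation noise disabled, the pipeline-measured
log alpha power matches the tabular value to < 0.02 at every electrode;
residual error is random phase interaction, not bias.

The 1/f background (amplitude spectrum ∝ f^{-1/2}, i.e. power ∝ 1/f,
exponent configurable) is scaled to the channel's alpha RMS
(`background_ratio`, default 1). Artifacts are raised-cosine transients
(default 200 µV peak, 200 ms) injected at random (channel, 2-s-block)
sites. Not emulated: realistic blink/EMG morphology, ICA-separable
source structure, alpha peak-frequency variation, nonstationary drowsiness
effects, or volume-conduction correlation between channels. Passing
tests therefore certify the pipeline's arithmetic and decision rules on
signals with known truth, not robustness to every pathology of real
recordings.

The online acquisition band-pass (0.1–100 Hz) is emulated only as a
band limit of the generated content; the alpha band is two decades from
either edge.

## Preprocessing

Fixed order: average re-reference → 2-s segmentation (trailing
remainder discarded) → artifact detection → channel rule → segment
rule. The artifact criterion is a conventional amplitude screen —
|sample| > 100 µV or |sample-to-sample step| > 50 µV within an epoch —
both configurable, standing in for the visual inspection a human rater
would perform. Both retention rules use strict inequalities ("more
than" 40% / 10%). The channel rule runs first and clears the flags of
channels it interpolates, which maximizes retained data; interpolation
uses inverse-angular-distance weights over the k nearest neighbors,
excluding neighbors flagged in that epoch. In the rare epoch where a
to-be-interpolated channel has no usable neighbor, the original samples
and flag are kept so the segment rule can reject that epoch — a
graceful-degradation path rather than a hard failure. Degenerate inputs
(every channel over the fraction, every epoch rejected, recordings
shorter than one window) raise labeled errors.

An EOG-regression utility (per-channel affine least-squares projection
on an EOG trace) is provided as a lightweight stand-in for
component-based ocular correction; it is not part of the default chain.

## Spectral estimation

Per-epoch one-sided periodograms at 0.5 Hz resolution are averaged
across epochs, each epoch mean-centred and tapered by a split
cosine-bell covering 10% of the samples (5% raised-cosine ramp per
edge; fraction 1 gives a full Hann window, 0 rectangular). Taper power
loss is compensated by the squared window mean (the coherent gain):
this keeps the power of an on-bin oscillatory line — the quantity the
alpha statistic aggregates — invariant to the taper choice, at the cost
of a few-percent inflation of broadband noise power under tapering
(Parseval is exact for the rectangular window). The alternative
mean-square normalization would do the reverse, preserving noise power
but attenuating a 10%-tapered line by ≈ 3.7%.

Alpha power is the mean of log10 bin power over 8–13 Hz inclusive
(11 bins), computed on the epoch-averaged spectrum. Log-before-mean on
the band, and averaging epochs before the log, are the defaults; both
orders are exposed (`log_before_band_mean`, `log_each_epoch`) since
either reading of "log-transformed before average power was calculated"
is defensible. Empty bins would make the log diverge; they raise unless
a configurable floor (default 10⁻²⁰ µV²) is supplied.

## Reliability

Retained epochs are split by temporal order into the first ⌈m/2⌉ and
last ⌊m/2⌋ (halving the *recording*, not odd/even interleaving), band
power is computed per half, and Pearson's r is taken across
participants per electrode × condition — the only construal under which
a per-electrode r exists. Electrodes with r < 0.7 are flagged.

## Bayesian mixed models

Formulas are expanded so every interaction carries all non-redundant
lower-order constituents; treatment coding uses abstinent and
eyes-closed as reference levels, and sleep enters uncentered on its 0–10
scale so that slope × observed-range arithmetic is interpretable
directly. Priors: N(0, 10²) on every fixed effect including the
intercept; inverse-gamma(0.001, 0.001) on the residual and
random-intercept variances.

The sampler is a blocked Gibbs scheme over the conjugate full
conditionals, with one structural refinement: the fixed effects are
drawn with the random intercepts integrated out (via the Woodbury
identity per participant, exploiting the block structure of the
marginal covariance). The naive b | u draw leaves the intercept-like
columns and the participant means strongly coupled and R-hat stalls
near 1.5–2; the collapsed draw removes the coupling and yields
effectively independent draws (R-hat ≈ 1.000, ESS ≈ the draw count) at
identical per-iteration cost. Defaults: 4 chains × 2000 iterations,
1000 warmup, all chains seeded from one master seed; R-hat above 1.01
or ESS below 400 should be treated as a warning. Special modes used by
the test oracles: known residual SD, random effects pinned to zero
(closed-form Gaussian posterior), and prior-only sampling.

Summaries report the median and central 95% credible interval,
PP = max(P(b>0), P(b<0)) in percent, and its verbal stratum; stratum
boundaries are resolved by rounding PP to the nearest integer percent
(so 99.4 → very strong, 99.5 → extreme). Split-chain R-hat and a
Geyer-truncated (initial positive sequence, enforced monotone)
autocorrelation ESS are computed per coefficient.

Marginal sleep slopes are computed draw-wise as ∂E[y]/∂Sleep at a
covariate point: the sum of every Sleep-involved coefficient times its
co-factors' values. Axis strata evaluate the moderator at the 15th,
50th and 85th percentiles of the electrode coordinate (labelled e.g.
Left/Midline/Right); eyes strata at closed/open; moderators absent from
a model leave the slope constant across strata by construction. Δ over
range multiplies each slope draw by (max − min) observed sleep and
takes the median. Posterior predictive checks simulate replicate
response vectors from randomly selected posterior draws and report tail
probabilities of the observed mean and SD.

## Pipeline, determinism and problem sizes

The orchestrator validates the YAML config (unknown keys rejected)
before any computation, runs the stages in order, and writes TSV/JSON
outputs plus a manifest carrying a config hash (excluding the output
directory), stage row counts and retained seconds. Every stochastic
stage derives its seed from the master seed, so two runs with the same
config are bit-identical.

Test and acceptance workloads are sized to exercise each claim at the
smallest scale that is still informative: study-scale cohorts (15 + 17)
for recovery and calibration with 4 × 1500 (recovery) or 2 × 700
(calibration across 50 replicates) MCMC draws — sufficient because the
collapsed sampler's draws are nearly independent — and cohorts of 6–10
participants for waveform-mode checks, whose per-recording cost is
dominated by synthesizing 90 s × 65 channels of comb oscillations.

## Known limitations

* The spherical montage is idealized; coordinates are not those of a
  digitized head, so spatial-gradient magnitudes are not comparable to
  fits on measured electrode positions.
* The artifact screen is amplitude-based only; no spectral or
  correlation-based bad-channel detection.
* Interpolated channels carry their neighbors' field, not an estimate
  of their own true signal; their band power is biased toward the local
  average (visible in `examples/waveform_preprocessing.py`).
* The half-t variance-prior alternative common in regression software
  is not implemented; the inverse-gamma default is near-flat over the
  relevant scale but not identical.
* Single-channel transients that contaminate fewer than 10% of sensors
  in a segment survive the retention rules by design; they inflate that
  channel's epoch-averaged power slightly.
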