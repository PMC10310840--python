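# Methods

`microstim` implements the analysis computations of a chronic two-photon
calcium-imaging study of learning under cortical optical microstimulation:
mice discriminate the number of LED pulses (0–9, 5 ms at 20 Hz, randomly
placed among 9 time bins) delivered over an opsin-expressing patch of
cortex, and the pipeline quantifies evoked responses, behavioral learning,
choice-related activity, representational stability, per-neuron stimulus
decoding, and the light field produced by the stimulation LED.  A synthetic
generator supplies trial-structured recordings with the statistical
structure these analyses assume, so every stage is testable end to end
without recorded data.

## Data model and conventions

An `Experiment` holds one `SessionRecording` per training day: a dense
ΔF/F matrix (neurons × frames, ~7 Hz), a trial table, and per-neuron
metadata keyed by ids stable across days.  Frame indices are 0-based with
half-open windows; the frame at `shutter_open_frame` is the first
post-reopen frame.  Times are seconds from shutter closure; `session_day`
is 1-based.  Opsin classification from red-channel statistics uses dual
thresholds on mean demixed redness and supra-noise pixel fraction: above
both upper thresholds → expressing, at-or-below both lower thresholds →
non-expressing, otherwise ambiguous.  Ambiguous neurons are kept in files
but excluded from every analysis.  The demixing (bleed) coefficient is a
config scalar; no estimation procedure is implied.

## Evoked responses and responsiveness

The evoked ΔF/F of a trial is the mean of the two frames immediately after
shutter reopening (the window precedes any lick).  The per-neuron baseline
distribution pools the 39 pre-closure frames of every trial.  A neuron is
responsive on a trial when its evoked value strictly exceeds the 97.5th or
falls strictly below the 2.5th percentile of that distribution (linear-
interpolation percentiles; ties at the bound are not responsive).  Z-scored
evoked ΔF/F uses the baseline pool's mean and SD.

**Baseline sampling.**  Because the evoked statistic is a 2-frame mean, a
baseline pool of raw single frames has a wider marginal distribution under
any independent noise, which would push the null exceedance rate far below
the nominal 5% (about 0.6% for iid gaussian noise).  The default pool
therefore consists of sliding 2-frame means over each trial's baseline
window — the same statistic as the evoked value — which pins the two-tailed
null rate at 5% for *any* stationary noise distribution.  `per_frame` and
`per_trial_mean` pools remain available as config options.

Highly responsive ("top responder") neurons are those whose per-session
mean z over 9-pulse trials strictly exceeds the 95th (or 99th) percentile
of that session's across-neuron distribution on at least one session; the
selected set is then held fixed across early/middle/late training bins
(defaults: days 1–3, 8–10, last 3).

Spontaneous activity is measured on frames outside the window from 1 s
before to 5 s after each photostimulation, with a matched-filter +
5×MAD-threshold event detector.  This detector is a deliberately simple
stand-in — it is *not* the template-matching algorithm used on the original
recordings — and is validated only for recovering inserted high-SNR
transients (±15%).  Whisking encoding scores fit a lagged linear encoder of
ΔF/F on whisker angle (frames within 1 s of shutter closure excluded,
split-half cross-fitting); the score is the Pearson r between held-out
prediction and data, with membership at r > 0.15.

## Behavior

Performance is tracked with a centered sliding 61-trial window.  Percent
correct and d′ = z(hit) − z(false alarm) are computed over included trials
(hits: right responses on 7/9-pulse trials; false alarms: right responses
on 0/1/3-pulse trials).  Rates are clipped to [1/(2n), 1 − 1/(2n)] per
class before the quantile, bounding |d′| by 2·z(1 − 1/(2n)).  Ignore trials
and 5-pulse trials (no defined correct side) are excluded from both
metrics.  Sessions shorter than the window use the single full-session
window.  A subject is a learner iff at least two consecutive sessions reach
peak windowed d′ ≥ 1.5 within the first 8 sessions *and* the 8th (or last
available) session still meets the criterion; an `--any-two` variant
relaxes the consecutiveness clause, since both readings of the criterion
are defensible.  Psychometric curves report P(lick right) per pulse count
with Wilson intervals.

## Choice analysis

For each pulse count, trials split by directional choice; trials whose
first lick precedes the end of the evoked window are dropped.  Per-neuron
right-vs-left contrasts use Welch's two-sided t-test (the variance
assumption is left free on purpose), classifying neurons as choice-
predictive at all, some, or no counts.  At the population level, each
subject contributes the mean evoked ΔF/F of its strongly responsive
neurons (session-wide response probability > 0.25) per (count, choice),
normalized by the subject's maximum of the across-choice mean curve —
across-choice rather than per-choice normalization keeps left and right
comparable.  The across-subject test is a paired two-sided t-test of the
right vs left curve means.

## Representational stability

Within a session, each 9-pulse trial yields a population vector of evoked
ΔF/F over included neurons (default inclusion: responsive on ≥ 1 trial of
the session); the summary is the mean strict upper triangle of the
trial-pair Pearson matrix.  Across sessions, per-day mean evoked vectors
(inclusion: responsive in ≥ 1 session) form a day-pair Pearson matrix using
pairwise-complete neurons with a minimum overlap of 10; a neuron absent on
a day contributes to no pair involving that day.  "Days until R² < 0.5" is
the smallest forward lag at which the squared Pearson correlation drops
below one half — R² is the squared correlation between the two vectors, not
a regression through the origin — and is censored (never coerced to a
number) when no lag crosses.  Lags count recorded sessions by default, with
a calendar-day option, since training days may skip calendar days.  Group
comparisons average within subject over the common-day windows (within-day:
days 1–8; days-until: start days 1–3) and use unpaired two-sided t-tests;
for days-until, only start days at which every subject is uncensored enter,
mirroring the common-support restriction of the study design.

## Stimulus decoding

Trials partition into high (7, 9) and low (0, 1, 3) pulse counts, excluding
5-pulse trials.  The per-neuron ideal-observer AUC is the area under the
ROC traced by sliding a criterion through the evoked values; it is computed
through the rank (Mann–Whitney) identity AUC = P(high > low) + ½P(tie),
which the tests verify against a brute-force pairwise count.  AUC is
reported un-folded with the orientation "more activity ⇒ high" (responses
increase with pulse count); folding is available behind a flag.  Session
summaries per opsin class: the mean AUC of the top ⌈0.05·n⌉ neurons (never
empty; flagged below 20 neurons) and the fraction of neurons with AUC
strictly > 0.75.  Training-course comparisons use paired early-vs-late
t-tests within group and unpaired tests across groups per window.

## Light propagation model

The LED is an 8 × 8 grid of point sources in water above the cranial
window, each carrying an equal share of the face power (measured in mW).
For a target point in the brain, each source contributes
`P/64 · T₁ · T₂ · exp(−L/λ) / (2πr²)`, where T₁, T₂ are unpolarized
Fresnel transmittances at the water→glass and glass→brain interfaces
(incidence angle from the straight-line ray's inclination; total internal
reflection gives 0), L is the in-brain path length, λ an empirical
scattering length constant, and r the source–target distance (half-sphere
spreading).  Contributions are averaged across sources.  Rays are straight
lines — Fresnel factors scale power but do not bend the path — a documented
simplification.  The default λ = 200 µm at 590 nm is a placeholder order of
magnitude, *not* an empirical value; it is a required input for
quantitative use.  Water n = 1.33, glass n = 1.52, brain n = 1.36 by
default.

## Synthetic generator

ΔF/F is built as gaussian frame noise plus single-exponential calcium
transients (τ = 1.5 s, GCaMP6s-like, sampled at 7 Hz) placed at shutter
reopening.  A transient on trial t for neuron i occurs with probability
qᵢ·g(p) and has amplitude aᵢ(d)·f(p)·jitterᵢₜ·gainₜ, where f and g are
saturating curves of pulse count p with f(0) = g(0) = 0 (half-saturation 4
and 2.5 pulses), gainₜ is a shared mean-1 lognormal per-trial gain, and
jitter is private mean-1 lognormal noise.  Opsin-expressing neurons are
stronger and more reliable (amplitude 0.6 vs 0.3 ΔF/F at 9 pulses; response
probability 0.75 vs 0.45) with lognormal across-neuron amplitude spread
(log-SD 1.0).  The shared gain scales only the evoked signal, not the
additive noise, so increasing its spread lowers effective SNR on low-gain
trials and with it the mean trial-pair correlation, while leaving any given
correlation matrix invariant to per-trial rescaling.

**Drift.**  Each opsin class has one instability scale s driving three
proportional components: (i) a stationary AR(1) day-level multiplier
exp(s·zᵢ(d) − s²/2) with day-to-day autocorrelation ρ = 0.9 (mean-
reverting rather than a pure random walk, so the multiplier's day-lag
correlation is exactly ρ^Δ and the cross-day half-life has an analytic
target); (ii) per-trial jitter with log-SD 1.0·s; (iii) per-day turnover
re-drawing a neuron's base amplitude with probability 0.3·s.  A single
knob therefore moves within-day correlation, cross-day half-life and
decoding together, which is what the learner/non-learner designs
manipulate.  Optional sparsification decays amplitudes at a rate
proportional to each neuron's amplitude percentile, concentrating declines
in the most responsive neurons.

**Behavior and choice.**  Choices follow a logistic model on signed
stimulus strength (p − 4.5)/4.5 with a per-session sensitivity trajectory
(saturating exponential toward a target d′), plus a coupling term β on the
standardized pooled activity of strongly driven non-expressing neurons
(ground-truth response probability > 0.25).  The pooled drive excludes the
shared per-trial gain: the coupling locus is deliberately the
non-expressing-specific fluctuation, so the expressing population stays
null by construction — the dissociation the choice analyses are designed to
detect.  5-pulse trials are rewarded on a uniformly drawn side.  First
licks are drawn after the response cue (1.2–2.0 s), so the pre-first-lick
restriction never truncates the evoked window unless an early-lick flag is
set.  1- and 9-pulse trials are presented up to 8× more often than
intermediate counts in late task stages.

**What the generator does not emulate** — and hence what passing tests do
not certify about real recordings: photon/imaging noise structure beyond
stationary frame noise, neuropil contamination, registration or
segmentation errors, slow baseline drift within a session, bursting or
multi-event transients, the masking flash, and any biophysical network
dynamics.  Drift magnitudes are calibrated only to reproduce qualitative
orderings; no quantitative drift parameters exist to match.

## Study-scale configurations

Cohort analyses use desk-scale conditions chosen once: 6 learners vs 5
non-learners, 14 detection-stage sessions of 44 trials, 30 expressing + 120
non-expressing (+4 ambiguous) neurons per subject, amplitude log-SD 0.6 and
non-expressing response probability 0.7; the regimes differ only in the
non-expressing instability scale (0.3 vs 1.2, a 4× difference), with the
expressing scale 0.5 in both.  The reliability and spread choices matter
for the cross-day metric: heavy response-failure noise attenuates day-pair
correlations toward the R² = 0.5 boundary at lag 1, while very heavy-tailed
amplitude distributions let a single surviving neuron pin the correlation
near 1 (censoring); the chosen regime keeps days-until-R²<0.5 well defined
at a few days for slow drift and about one day for fast drift, as in the
study populations it emulates.  Choice cohorts use 6 subjects with
a single 200-trial final-stage session and β = 1.5 (or 0 for null
calibration).  Half-life recovery uses 300 homogeneous, deterministic
responders over 12 sessions with pure AR(1) drift (s = 0.25,
ρ ∈ {0.95, 0.9, 0.8}), where days-until-R²<0.5 has the analytic target
⌈ln 0.5 / (2 ln ρ)⌉.  Null calibration uses 2,000 neurons × 200 trials ×
10 seeds.  These sizes keep the full suite and the reproduction script
within desk-scale runtimes while leaving the group statistics
well-powered.

## Numerical choices and degenerate inputs

Percentiles use numpy's linear interpolation; exceedance is strict on both
tails.  Zero baseline SD excludes a neuron from z-based summaries (NaN,
with a warning).  Zero-variance population vectors yield NaN correlations
excluded from means.  Welch t-tests return p = 1 on exact constant ties.
Degenerate group sizes (< 2 subjects) yield descriptive results flagged
`insufficient_n`; days-until comparisons with no commonly supported start
day return a `no_common_support` flag rather than a number.  Truncated
trials (fewer than 2 post-reopen frames) are dropped with a warning;
truncated baselines are used as available and flagged.  All randomness
flows from explicit seeds; identical config + seed reproduces experiments
bit-for-bit and CSV outputs byte-for-byte.

## Known limitations

Calcium-transient tails cross trial boundaries at the default inter-trial
spacing, slightly inflating baseline percentiles on strongly driven
neurons (a property shared by the real measurement); exact closed-form
checks therefore use configurations with long inter-trial gaps.  The event
detector and whisking encoder are simplified stand-ins.  The light model
ignores refraction bending, multiple scattering and heating.  The adapter
for the study's deposited raw-data archive is an interface contract only —
the archive's internal layout is undocumented — so the package analyzes
synthetic or user-converted data, not the original recordings.
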