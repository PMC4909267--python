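# Methods

This note documents the models, algorithms and design choices behind
`apnealab`: what each stage computes, which parameters matter, what the
synthetic generator does and does not emulate, and the numerical conventions
adopted where the problem is genuinely open.

## Problem setting

Premature infants with apnea of prematurity show repeated breathing pauses;
long pauses trigger a cascade — heart rate slows within seconds (bradycardia),
and oxygen saturation falls after a longer lag (intermittent hypoxia, IH).  In
a 24-h crossover design an intervention alternates in 6-h ON/OFF blocks
(order randomised by coin flip), giving 12 h per condition, and the analysis
asks whether per-subject event burden is lower during ON.  The package
implements the three detection problems, the block bookkeeping, and the paired
statistics, plus a simulator that generates data with exactly this structure.

## Breath and pause detection

The respiratory effort signal (thoraco-abdominal movement, arbitrary units)
is band-passed at 0.3–2.5 Hz (4th-order Butterworth, zero-phase), covering
neonatal breathing rates of roughly 20–150 breaths/min.  Candidate breaths
are local maxima of the filtered trace with a minimum spacing of 0.8 of the
fastest cycle.  Because a sharp apnea edge makes the filter ring into the
silent interval, candidate amplitude is *not* taken from the filtered trace:
each candidate is scored by the peak-to-trough excursion of the raw detrended
signal within half a breath cycle, and kept only if that excursion is at
least `amp_frac` (default 0.3) of the rolling median amplitude over 60
neighbouring breaths.  The rolling median makes the threshold adaptive to
slow amplitude drift; the raw-signal excursion makes silence truly silent.

A pause is defined on the inter-breath-onset intervals: with median breath
period `T`, an interval `I` contributes a pause of duration `d = I − T`
(clipped at 0) at onset `last breath + T` — the silent time beyond one
expected cycle.  A raw-interval definition would count slow breaths as
pauses; the median-subtraction definition is switchable but is the default.
Pauses with 3 < d ≤ 5 s are short, d > 5 s long: the two classes partition
d > 3 with no overlap, and a boundary value of exactly 5 s is short.

## SpO2 and heart-rate episode scoring

Pulse oximeters report a trailing average (8 s for the study devices);
`smooth_spo2` reproduces this as a causal moving average over the valid
samples of the last `round(window·rate)` samples including the current one.
With a step input the output first equals the new level exactly one window
after the last pre-step sample, ramping linearly in between.  Monitor SpO2
channels normally arrive already device-averaged, so the pipeline applies no
second smoothing by default (`DetectionConfig.smooth_spo2 = False`).

IH and bradycardia episodes are maximal runs of valid samples *strictly*
below the threshold ("fell below 90 %" reads as < 90, so a sample equal to
the threshold ends the run), scored independently per threshold — 90/88/85 %
with a 5-s minimum for IH, 110/100 bpm for bradycardia.  Runs separated by
any recovery sample are distinct episodes; a `gap_merge` parameter (default
0 s) can join runs across brief recoveries.  Bradycardia has a configurable
1-s minimum duration to suppress single-sample artifacts.  Invalid samples
break runs; no episode is ever scored inside masked time.  Total
below-threshold *duration* is monotone across nested thresholds by
construction; episode *counts* need not be (noise can split a deep run into
several), which is why the invariant is stated on durations.

When no heart-rate channel exists, HR is derived from ECG: rectified signal
against an adaptive threshold (half the median of 2-s block maxima) with a
0.2-s refractory period; instantaneous HR = 60/RR at each beat, RR outside
[0.2, 3] s masked implausible, resampled to 1 Hz by previous-value hold that
expires 3 s after the last accepted beat.

## Blocks and summaries

Events belong to the block containing their onset and are never split; hence
ON + OFF counts and durations conserve the totals exactly, and permuting the
block order relabels but never changes totals.  Artifact-free monitored time
per condition is carried through (a second counts when every channel is valid)
so unequal artifact burden between conditions is visible; totals remain the
primary outcome, with rates derivable from the reported valid time.

## Paired statistics

Each outcome is tested with a paired t-test on transformed per-subject totals.
ln(x+1) is the default transform (variance-stabilising for counts including
zeros); sqrt and log10(x+1) are available, and the normality screen
(Shapiro–Wilk plus Lilliefors-corrected Kolmogorov–Smirnov — the Lilliefors
form is what SPSS's KS normality table computes) is reported for the
transformed differences rather than used to auto-select a transform, because
"optimal normality" has no canonical operationalisation.  MD, condition means
and SEs are raw-scale; MD = OFF − ON so positive means reduction, while the
per-subject percent-change table uses 100·(ON − OFF)/OFF (negative =
reduction), with OFF = 0 reported missing rather than infinite.  p values are
two-sided at α = 0.05 and no multiple-testing correction is applied (the
report carries a note).  Degenerate cases are explicit: identical conditions
give t = 0, p = 1; constant non-zero transformed differences are flagged
rather than raising.  Constant vectors make the normality statistics NaN with
a degenerate flag, and the Lilliefors statistic needs at least 4 differences.

## Synthetic data

The generator is phenomenological, not mechanistic: it reproduces the
*structure* the analysis relies on.

**Pause process.**  Apnea onsets follow a renewal process: successive gaps
are `min_separation` (30 s, so events never overlap and ground truth is
unambiguous) plus the mean pause duration plus an exponential whose mean is
set so the realised event rate equals the nominal rate of the current block
(`apnea_rate_off`, multiplied by `stim_rate_ratio` during ON).  A hard-core
thinning of a Poisson process was considered and rejected: thinning removes
proportionally more events from the higher-rate condition and so biases the
realised ON/OFF ratio toward 1; the rate-matched renewal preserves it (the
acceptance run recovers a programmed ratio of 0.6 to within ±0.01 over 200
simulated days).  Pause durations are log-normal (median 5 s, log-sd 0.6),
so roughly half of pauses are long, matching a cohort dominated by periodic
breathing.  Parameters implying more separation-plus-pause time than block
time raise an error.

**Waveforms.**  Breaths are a regular grid at `breath_rate` (55/min) with
optional jitter; breaths inside pause windows are deleted, the effort trace
is a train of Hann-shaped bumps at the remaining breath times with ±20 % slow
amplitude modulation plus white noise.  Ground-truth pause durations are the
*realised* silent time between flanking breaths minus one median period —
i.e. the quantity the detector estimates — because the inserted window edge
generally falls between breaths and the nominal draw is not what the signal
contains.

**Cascade.**  Each pause of realised duration `p` produces a trapezoidal
deflection in clean SpO2 (onset + 8 s lag, 10-s fall to a depth of 0.8 %·p
capped at a 75 % floor, hold for `p`, 15-s recovery) and in clean HR (onset +
4 s lag — bradycardia precedes the desaturation — 5-s fall, depth 6 bpm·p
capped at a 70 bpm floor, 10-s recovery); overlapping deflections combine by
maximum depth.  With these defaults a 13-s pause drives HR below 80 bpm and
SpO2 below 90 % for ~25 s, the canonical severe-event profile.  Clean SpO2 is
passed through the oximeter model (8-s trailing average) before noise, since
real monitors emit averaged saturation.  The ECG channel is a Gaussian-spike
train whose beat times integrate the clean HR curve.  Ground-truth IH and
bradycardia episodes are the threshold runs of the clean (noise-free)
channels, so a detector run on a noise-free recording must recover ground
truth exactly — and does, which the test suite asserts for 24-h recordings.

**Cohort tables.**  `generate_cohort` has two modes.  `signals` simulates and
detects per subject end to end.  `counts` draws per-subject, per-condition
totals directly: a log-normal subject severity (log-sd 0.8, matching the
heavy skew of real per-subject totals) scales all outcome baselines; each
12-h period gets an independent symmetric log-normal multiplier (log-sd
0.177, i.e. 0.25/√2 on the within-pair log-ratio) representing state/sleep
variability between halves of the study; stimulation multiplies ON means by
a per-outcome ratio; counts are Poisson and total durations Gamma sums of
per-episode durations.  The default baselines and ratios describe a severely
affected cohort (e.g. 282 long pauses per 12 h OFF, ratio 0.61; bradycardia
ratio 1/3) — the regime the paired design is meant to resolve — and the
within-pair variability is set so the expected paired t on long-pause counts
is ≈ 7–8 at n = 15, the magnitude typical of such cohorts.  Because the
period effect is symmetric under the null, a ratio of 1 makes the conditions
exchangeable, and the measured type-I error of the full pipeline is ~0.05
(asserted to lie in [0.03, 0.07] over 1000 replicates).

**What the simulator does not model** — and hence what passing tests do not
show about real data: obstructive vs central apnea, sleep states and
arousals, caffeine or oxygen-supplementation effects, movement artifact
(masks are supported but not generated), oximeter quantisation, baseline
drift in HR/SpO2, and any pause-duration change under stimulation (the
stimulation effect is purely a rate effect per outcome; per-episode durations
are condition-independent, so simulated duration effects track count effects).

## Problem sizes and numerical conventions

Tests and the acceptance script simulate at 50 Hz effort / 5 Hz trend
channels and 2–24-h durations with 20–1000 replicates, sizes chosen so the
full suite runs in well under a minute while keeping Monte-Carlo standard
errors far below the asserted tolerances; the generator's defaults (250 Hz,
24 h) match the original acquisition and remain the package defaults.  Time
is float seconds from recording start; events are half-open intervals scored
at sample resolution; EDF output is 16-bit with trend channels upsampled by
sample-and-hold to the top rate (interpolating EDF readers would otherwise
distort step-like trends).  All randomness flows from one seeded
`numpy.random.Generator`; per-subject and per-replicate streams are spawned
sub-seeds, so every output is bit-reproducible given the seed.

## Known limitations

The pause detector assumes a quasi-periodic effort signal; highly irregular
breathing inflates the median period estimate and shifts the short/long
boundary cases.  Episode counts near thresholds are noise-sensitive (splits),
though durations are stable.  The crossover analysis ignores period and
sequence effects (as the paired design does); a mixed-model extension is out
of scope.  Exact reproduction of a specific study's numbers requires that
study's per-participant table, which is not redistributed here.
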