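# Methods

This note documents the models and procedural choices behind `actisync`:
what each stage assumes, which parameters matter, and what the synthetic
generator does and does not emulate.

## The measurement problem

Two devices record the same person minute by minute: a research-grade
waist accelerometer exporting vector-magnitude (VM) counts and steps, and a
consumer wrist tracker exporting steps, METs and its own 0–3 intensity
code. The tracker's internal algorithms are proprietary, so the analysis
treats its stream as a black box and asks only how its outputs disagree
with count-based research scoring on identical minutes.

## Registration and the minute convention

A record labelled 10:07 covers [10:07:00, 10:08:00) — label-at-start,
half-open. Timestamps are local clock time with no time-zone arithmetic;
the devices are assumed synchronised at setup, which is how concurrent-wear
protocols are run. Readers sort rows by timestamp (duplicate timestamps are
an error), sum sub-minute epochs into clock minutes (partial minutes are
dropped and logged), and zero-fill interior gaps so the nonwear rule can
see them: a research gap becomes counts = 0, a consumer gap becomes
steps = 0 / intensity = 0 / METs = 1.0 (resting). Registration intersects
the two spans; it never resamples or imputes.

## Nonwear, joint exclusion, valid days

Nonwear is a maximal window of ≥ `zero_run_minutes` (default 60) zero
minutes, where a minute is flagged if it lies inside *any* qualifying
window — the implementation is a linear two-pointer sweep proven equivalent
to an exhaustive window scan in the tests. The research rule optionally
admits up to 2 interior minutes below 100 counts (the Troiano-style spike
allowance); the strict zero-run rule is the default. The consumer stream
has no counts, so "zero" defaults to steps = 0 AND intensity = 0; a
steps-only variant is available because neither channel is canonically
"the" zero signal. Minutes are analysed only when both devices are worn
(joint wear), and a calendar day enters the day-level analysis iff its
joint-wear minutes reach 480 (8 h, boundary inclusive). Runs may span
midnight; days are sliced after masking.

A known consequence of the steps-and-intensity zero rule: a genuinely
sedentary hour (no steps, code 0) on a worn consumer device is
indistinguishable from nonwear and gets excluded. This preferentially
removes sedentary time from joint wear and lowers the day-level sedentary
share relative to a wear-time share computed from the research device
alone — a real artefact of zero-run rules on step-based channels, worth
remembering when comparing share denominators across reports.

## Intensity and METs

Adult VM cut points: sedentary 0–199, light 200–2690, moderate 2691–6166,
vigorous ≥ 6167 counts/min; the research device's separate very-vigorous
class is folded into vigorous so both devices share one 0–3 scale.
Sedentary *behaviour* requires < 200 counts AND zero steps — a strictly
tighter condition than code 0. METs are `max(floor, intercept +
slope·counts)` with the published adult VM regression (slope 0.000863,
intercept 0.668876, floor 1.0 MET) as the default; coefficients are
configuration, not logic.

Day-level summaries are means over joint-wear minutes of valid days: total
steps, MET rate (mean METs/min — the wear-minute mean is the only
denominator consistent with a 1.0-MET resting floor), and four intensity
shares in % of joint-wear time. Under the default steps-aware sedentary
rule, code-0 minutes *with* steps are assigned to the light share so the
four shares always partition 100 %; a code-only variant is provided because
either convention is defensible and they differ exactly by those stepping
sub-threshold minutes.

## Bout validation

Journals report up to 4 daily bouts with start/end clock times. The match
tolerance is ±5 minutes per boundary, searched independently. A candidate
window must be entirely joint-wear and ≥ 80 % non-sedentary (research code
≥ 1). Among qualifying candidates the package maximises the **number** of
active minutes, with ties broken by higher active fraction, then smaller
total boundary shift, then earlier start. Maximising the *fraction*
instead was tried first and rejected: it rewards shrinking the window onto
an all-active core, clipping true bout minutes (observed worst-case
true-window coverage 0.55 on synthetic cohorts); the count criterion
recovers full bouts — on generator data with jitter up to the full 5
minutes and no confusion noise, recall is 100 % and every validated window
covers its true window completely (tested). Overlapping validated bouts in
a participant-day are merged (keeping the longer constituent's category)
so pooled bout minutes are never double-counted. Rejected entries carry a
reason and are reported, never dropped silently.

Exercise labels map to six categories by ordered keyword matching —
machine keywords first, so "running on a treadmill" is cardio-machine, not
running; unmatched labels become `other`. Per-type tables are restricted to
walk, run-or-sports and cardio-machine, the three most homogeneous
categories.

## Paired statistics

For n pairs, diff = consumer − research: t = mean(diff)/(SD(diff)/√n) with
n−1 df and two-sided p; paired Cohen's d = mean(diff)/SD(diff) (n−1
denominator); Pearson r across pairs. When diffs are constant, d is
undefined and flagged, and t is ±∞ with p = 0 unless the constant is 0.
From summary moments, d = (m₂ − m₁)/√(s₁² + s₂² − 2 r s₁ s₂), which agrees
with the paired form exactly on moment-matched data. Day-level comparisons
use participants (mean over valid days) as units; bout-level comparisons
use bouts. No multiple-testing correction is applied (nominal α = .05);
the effect sizes are the primary quantities. GLMM-style nesting of days in
participants is out of scope.

## The synthetic world

The generator's defaults state one concrete free-living world, calibrated
once against the structure such cohorts report and then left alone:

- 19 participants × 14 days; wake 07:00–23:00 (960 min); sleep minutes are
  zero on both devices.
- Wake minutes follow a semi-Markov chain over {nonwear, sedentary, light,
  moderate, vigorous} with geometric dwell (means 90/30/12/7/3.5 min). The
  dwell-weighted stationary worn-time shares are ≈ 68/27/4/1 % — a mostly
  sedentary young-adult profile.
- Counts per worn minute are lognormal truncated exactly to the state's
  cut-point band (sedentary median 40, light 700, moderate 3900, vigorous
  7800 counts; σ_log 1.2/0.9/0.45/0.35), so classifying truth is exact by
  construction. Nothing in the free-living literature pins these shapes;
  they are declared defaults, not estimates.
- Steps are Poisson with mean 0.02·counts, zero below a 200-count
  ambulation threshold (sub-threshold movement is fidgeting, not
  stepping), capped at 220/min. This yields ≈ 9–10 k steps/day and keeps
  the steps-aware sedentary rule consistent with count bands on truth.
- Bouts arrive at 6.34 per 14 participant-days, durations ≈ N(55, 25²)
  clipped to [15, 130] min, placed non-overlapping inside wake with
  category-specific state mixes that are ≥ 95 % non-sedentary. Journals
  shift each boundary by an integer uniform on [−jitter, +jitter]
  (default 2, max 5) and truncate to 4 rows/day, dropping shortest bouts
  first and the earliest among equal lengths.
- The consumer distortion is explicit: METs multiplied by `met_multiplier`
  (default 1.44), intensity passed through a row-stochastic confusion
  matrix (default: 55 % of light minutes read sedentary, active codes
  smear upward), Gaussian step noise (SD 8/min), and a 2 % chance a worn
  minute reads zero on one device. True METs follow the research MET model
  exactly, so with the identity bias the two streams agree minute for
  minute, and an injected multiplier is recoverable from the bout-level
  consumer/research MET ratio (within 2 % at ≥ 50 bouts, tested through
  the CSV dialects).

Randomness: one root seed; participant i's stream comes from a fixed
spawn key, so adding participants never perturbs earlier ones; identical
(config, bias, seed) reproduce identical output.

What the generator does **not** emulate: raw tri-axial waveforms,
heart-rate or sleep structure, device placement effects (wrist vs waist
mechanics), speed-dependent step error, or the consumer firmware's actual
decision rules. A green recovery test therefore establishes that the
pipeline inverts the *declared* distortion on data with the *declared*
structure — not that any real tracker behaves like the surrogate.

## Numerical choices and degenerate inputs

- Consumer MET export integers are divided by `met_scale` (default 10, the
  dominant minute-file dialect); the scale is configurable, not asserted.
- In-memory consumer METs are exact; quantisation to 0.1 MET happens only
  at CSV write, so identity-bias equality is exact in memory and round
  trips are exact to the dialect's precision.
- Shares are validated to sum to 100 ± 0.01 percentage points.
- Zero-length bouts, empty series, negative counts, codes outside 0–3,
  non-row-stochastic matrices, and jitter above the 5-minute match
  tolerance all raise typed errors (`ParseError`, `ConfigurationError`,
  `DomainError`, `RegistrationError`).
- Paired comparisons require n ≥ 2; categories with < 2 bouts are omitted
  from tables with a logged reason.

## Known limitations

- The day-level sedentary share depends visibly on the consumer zero rule
  and on joint exclusion (see above); both rule variants are exposed
  because neither can be asserted as canonical.
- Bout matching assumes the journal is roughly right; it cannot discover
  unreported exercise, and merged overlapping reports inherit the longer
  constituent's category.
- The paired design ignores day-to-day correlation within participant at
  the bout level; bouts from one participant are treated as independent
  units, as simple paired analyses do.
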