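# Methods

This note documents the models and procedures the package implements, the
parameters that matter, what the synthetic-data generator does and does not
emulate, and the numerical and design choices made where the standard
methodology leaves room.

## Study design being analysed

A two-period crossover validation: participants wear an accelerometer for 14
consecutive days and answer one version of the GPAQ after day 7 and the
other version after day 14, in an order randomised by group ("with-cards
first" vs "without-cards first", balanced ±1). Each questionnaire is
validated against the accelerometer summary of its own week, so every
analysed participant contributes exactly one with-cards and one
without-cards comparison. Weeks are days 1–7 and 8–14 counted from the first
recorded calendar day.

## Accelerometer processing

*Reintegration.* Cut-points are defined on counts per minute, so 30-s epochs
are summed pairwise into minutes before classification; a trailing partial
minute is dropped. Only the vertical axis is used (the Freedson cut-points
are vertical-axis thresholds); extra axes in triaxial exports are parsed and
ignored.

*Classification.* Inclusive bands 0–99 / 100–1951 / 1952–5724 / >5724 CPM
(sedentary, light, moderate, vigorous). The band table is a parameter
(`CutPoints`), but only the Freedson adult table is validated by the test
suite; alternative cut-point families would change the category totals.

*Non-wear.* A minute is non-wear iff it lies in a window of ≥ 60 minutes
consisting of zero-CPM minutes and tolerated interruption runs — each run at
most 2 consecutive minutes, every interrupted minute 1–100 CPM. Any minute
above 100 CPM, or a nonzero run longer than 2 minutes, terminates a window;
windows begin and end on zero minutes. Choices made where the rule is
commonly stated loosely:

- the number of tolerated interruption runs per window is unlimited by
  default (the widespread Troiano-style implementation), configurable via
  `max_interruption_runs_per_window`;
- interruption minutes inside a qualifying window count as non-wear and are
  excluded from the category totals — they belong to the detected window;
- detection runs over the whole recording before the day split, so windows
  may span midnight.

The implementation is a vectorised run-length algorithm; its contract is
pinned by a brute-force all-windows oracle over random sequences, including
the 59/60-minute and 2-/3-minute interruption boundaries.

*Validity.* Wear time ≥ 600 min makes a day valid; ≥ 3 valid days make a
week usable. Daily averages divide by the number of valid days (reading
"recorded days" in the usual phrasing as the valid days being averaged, the
natural reading of the adjacent "of valid days" qualifier). Partial first or
last calendar days are processed as-is and face the same 10-h rule.

## GPAQ scoring

Five domain-intensity blocks (vigorous/moderate work, transport,
vigorous/moderate leisure) each carry engagement, days/week and min/day.
Daily minutes: vigorous = (work-vig + leisure-vig weekly minutes)/7;
moderate = (work-mod + transport + leisure-mod)/7; the sedentary item passes
through. Transport never contributes to vigorous.

The cleaning rules implement the analysis-guide conventions: block
consistency (engagement without days/minutes, or days and minutes
disagreeing about zero), a 16 h/day cap per block, and a 24 h/day total
plausibility check (mean daily activity plus sedentary time). Each rule is
individually toggleable; any firing rule marks the response unclean, and
unclean participants are dropped listwise from paired analyses (per-outcome
salvage is not attempted). Durations given as "h:mm" text are normalised at
parse time; anything ambiguous is rejected rather than guessed. MET-minute
totals and WHO-recommendation categories are out of scope.

## Agreement statistics

All tests are two-sided at α = 0.05, without multiplicity adjustment.

*Bias and Bland–Altman.* bias = mean(q − a) (which equals mean(q) − mean(a)
identically); SD uses the n−1 denominator; limits of agreement are
bias ± 1.96·SD. The plot abscissa is the accelerometer value — treating
accelerometry as the reference method — with the classical mean-of-methods
abscissa available (`abscissa="mean"`). Confidence intervals for the limits
are not computed.

*Wilcoxon signed-rank.* Zero differences are excluded before ranking (the
common statistical-package default; Pratt handling available). For n ≤ 15
nonzero differences the exact two-sided sign-flip p is computed by dynamic
programming on doubled midranks (so ties are handled exactly). Above that,
a normal approximation with tie-corrected variance Σr²/4, a 0.5 continuity
correction and a one-term Edgeworth kurtosis correction
(γ₂ = −2Σr⁴/(Σr²)²) is used; the extra term keeps the approximation within
about 0.016 of the exact p down to n = 5, where the plain corrected normal
can be off by 0.03. Its type-I error at n = 54 is 0.051 over 10⁴ null
simulations. All differences zero raises a degenerate-data error rather
than silently returning p = 1.

*Version comparison.* Per-participant errors e⁺ = q⁺ − a(week of q⁺) and
e⁻ = q⁻ − a(week of q⁻) are joined on participant id and compared by the
same Wilcoxon test.

*Spearman.* Midrank-based ρ (scipy), with interpretation bands on |ρ|. The
conventional printed bands leave sub-0.01 gaps (e.g. between 0.09 and 0.10);
the implementation closes them with half-open intervals: [0, 0.10) none,
[0.10, 0.30) poor, [0.30, 0.60) fair, [0.60, 0.80) moderately strong,
[0.80, 1) very strong, 1 perfect. Negative ρ is banded by magnitude with the
sign reported separately. Zero variance in either variable raises an error.

*Baseline tests.* Pearson χ² without continuity correction on the
sex-by-group table, and asymptotic tie-corrected Mann–Whitney U without
continuity correction on age and BMI — the conventions of the major
commercial statistics packages.

## Synthetic-data generator

The generator is the package's study stand-in and defines the default
conditions: 14 days, 30-s epochs, vigorous activity over-reported with
factor 3.0, moderate under-reported with factor 0.8, lognormal mean-one
recall noise with CV 0.3, one scheduled non-wear block per day, no
show-card effect, and demographics centred on a young adult cohort (~57%
female, age ~ truncated normal(28.3, 12.2) ≥ 18, BMI ~ normal(23.2, 3.1)).
Daily activity targets centre on accelerometer-typical values (sedentary
~440, light ~330, moderate ~110, vigorous ~13 min/day); these were chosen
once as realistic values for such a cohort.

Mechanics that the tests rely on:

- every emitted minute's CPM is drawn uniformly inside its state's cut-point
  band; sedentary minutes are a 60/40 mixture of exact zeros and 1–99 CPM so
  the non-wear logic is exercised;
- scheduled non-wear blocks are pure zero runs ≥ 60 min, flanked by > 100
  CPM minutes, and zero-bounded low-count (≤ 100 CPM) runs inside wear time
  are capped at 45 minutes (enforced by swapping minutes, preserving per-day
  category totals), so the non-wear detector recovers exactly the scheduled
  blocks and the recorded per-day state minutes equal the classifier output;
- 30-s series are built by randomly splitting each minute's CPM into two
  epochs, so reintegration recovers the minute series exactly;
- self-reports apply the bias factor and noise to the week's true daily
  mean, then decompose the weekly total into days/week × min/day items
  (~45-min sessions, ≥ 10 min per bout, totals under 10 min/week dropped);
  with zero noise the scored report returns truth × factor exactly;
- the show-card effect is an additive shift applied to both report factors
  for the with-cards version only; 0 yields a true null for the version
  comparison;
- dropout (insufficient wear) is simulated uninformatively: a Bernoulli
  draw per participant selects a week in which five days get ~420 wear
  minutes, making that week unusable;
- one RNG stream per participant, derived from (seed, participant id), so
  enlarging a cohort never reshuffles existing participants; identical
  configurations are byte-identical.

What the generator does **not** emulate: raw 30 Hz waveforms, bout
structure or diurnal rhythm within wear time (states are shuffled
per-minute), correlated multi-axis counts, informative dropout (in real
cohorts excluded participants can differ systematically, e.g. by sex), and
social-desirability mechanisms beyond a multiplicative bias. Passing tests
therefore demonstrate the correctness of the processing and inference
chain under known truth, not the field behaviour of any questionnaire.

## Problem sizes and determinism

Calibration suites run at the sizes they state: the non-wear oracle on
1000 random sequences of ≤ 300 minutes; Wilcoxon type-I error on 10⁴ null
samples of n = 54; parameter recovery on one n = 200 study (within 3
Monte-Carlo SEs of truth × (factor − 1)); null uniformity of the
version-comparison p over 200 seeded n = 200 studies (Kolmogorov–Smirnov,
α = 0.01). Replicate studies use 60-s epochs directly: by construction the
30-s split reintegrates to the identical minute series, so nothing is lost.
The acceptance script's default study uses 71 recruited participants with
dropout fraction 0.24, mirroring a realistic recruit-to-analysis flow, at
30-s epochs.

## Known limitations and documented ambiguities

- Whether commercial processing software counts tolerated interruption
  minutes toward wear time, and how it handles partial device days, is not
  standardised; both behaviours here are explicit choices (interruptions
  are non-wear; partial days are processed) and configurable.
- Published summaries of this design sometimes disagree internally: a pair
  of version labels for the sedentary mean differences can appear swapped
  between table and text, and some printed differences differ from the
  difference of the printed arm means by 0.1 (per-pair rounding). The
  arithmetic identity bias = mean(q) − mean(a) is what the implementation
  and its tests guarantee.
- The cleaning-rule set is guide-derived; real studies rarely enumerate
  which rule excluded whom, so the exclusion taxonomy here cannot be
  validated against a published breakdown.
- Epoch loading supports the common ActiGraph CSV layouts (10-line device
  header, counts-only or timestamped rows), not the binary AGD/GT3X
  formats.
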