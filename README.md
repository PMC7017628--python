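# paq-agree

Criterion-validity analysis for self-reported physical activity: compare
questionnaire estimates (WHO Global Physical Activity Questionnaire, GPAQ)
against waist-worn accelerometer counts in a two-period crossover design,
where each participant answers two questionnaire versions (with and without
illustrative "show cards"), one after each week of continuous accelerometry.

The package is aimed at physical-activity measurement researchers who need a
reproducible version of the standard validation pipeline — and a synthetic
cohort generator with known ground truth to test it against.

## What it computes

**Accelerometer processing.** 30-s epoch counts are reintegrated to counts
per minute (CPM) and each minute classified by the Freedson adult cut-points

| CPM | category |
|---|---|
| 0–99 | sedentary |
| 100–1951 | light |
| 1952–5724 | moderate |
| > 5724 | vigorous |

Non-wear time is any window of ≥ 60 consecutive zero-CPM minutes, tolerating
interruptions of ≤ 2 consecutive minutes at 1–100 CPM. A day is valid with
≥ 10 h wear; a week is usable with ≥ 3 valid days; outcomes are daily
averages (min/day) over valid days, per week.

**GPAQ scoring.** Work, transport and leisure items are combined into daily
minutes of moderate activity (transport counts as moderate), vigorous
activity, and sedentary time: e.g. vigorous = Σ(days/week × min/day)/7 over
the vigorous blocks. Responses failing the cleaning rules (inconsistent
blocks, > 16 h/day in one block, > 24 h day total) are excluded.

**Agreement.** For each outcome and questionnaire version, with q the
questionnaire and a the matched same-week accelerometer value per subject:

- bias = mean(q − a), with SD of the differences;
- Bland–Altman limits of agreement, bias ± 1.96 · SD(q − a), plotted against
  the accelerometer value (reference-method abscissa; the classical
  mean-of-methods abscissa is available);
- Wilcoxon signed-rank tests (exact sign-flip distribution for n ≤ 15,
  Edgeworth-corrected normal approximation otherwise), including the
  crossover comparison of the two versions' errors e⁺ = q⁺ − a vs
  e⁻ = q⁻ − a;
- Spearman ρ with the usual interpretation bands
  (none < 0.10 ≤ poor < 0.30 ≤ fair < 0.60 ≤ moderately strong < 0.80 ≤
  very strong < 1 = perfect);
- baseline group homogeneity (Pearson χ², Mann–Whitney U) and a
  CONSORT-style exclusion account.

**Synthetic studies.** `simulate_study` builds a full cohort with known
per-day activity minutes, scheduled non-wear blocks, and GPAQ responses with
a configurable bias pattern (default: vigorous over-reported ×3, moderate
under-reported ×0.8, lognormal recall noise with CV 0.3), so the entire
chain is testable without any raw data.

## Worked example

```python
from paq_agree import (AnalysisParams, Participant, SimulationConfig,
                       run_study, simulate_study)

config = SimulationConfig(n_participants=30, epoch_seconds=60, seed=99,
                          dropout_fraction=0.2)
data = simulate_study(config)
roster = [Participant(p.participant_id, p.sex, p.age, p.bmi, p.group)
          for p in data.roster]
report = run_study(roster, data.epochs, data.responses, AnalysisParams())
```

This prints (see `examples/05_full_pipeline.py`):

```
recruited 30, analyzed 26, excluded 4
  1x insufficient valid accelerometer days in week 1 (2 < 3)
  3x insufficient valid accelerometer days in week 2 (2 < 3)

version-error comparison (bias = questionnaire - accelerometer):
  moderate  with-cards   -13.0 without-cards   -19.8 min/day, p = 0.62
  vigorous  with-cards   +24.8 without-cards   +29.2 min/day, p = 0.26
  sedentary with-cards   +33.1 without-cards   -33.5 min/day, p = 0.09
```

Reading: four participants were dropped because one of their weeks had fewer
than three valid wear days. Both questionnaire versions over-report vigorous
activity by ~25–30 min/day and under-report moderate activity, and no
version-vs-version difference in those errors reaches p < 0.05 — the
questionnaires err alike, which is exactly the null pattern the generator
was configured with (`showcard_effect=0`).

The `examples/` directory has one short script per capability (simulation,
accelerometer processing, GPAQ scoring, agreement statistics, full
pipeline). A thin CLI wraps the same stages:

```bash
paq-agree simulate --n 54 --seed 1 --out study/
paq-agree process-accel --epochs study/epochs --out weeks.csv
paq-agree score-gpaq --responses study/gpaq_responses.csv --out gpaq.csv
paq-agree run --n 54 --seed 1 --out report/
```

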