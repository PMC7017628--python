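"""Process one epoch count series into daily and weekly activity summaries.

The chain: reintegrate 30-s epochs to counts per minute (CPM), classify each
minute by the Freedson adult cut-points (0-99 sedentary, 100-1951 light,
1952-5724 moderate, >5724 vigorous), mark non-wear (>= 60 min of zeros,
tolerating <= 2-min interruptions of 1-100 CPM), and keep days with >= 10 h
wear; weeks need >= 3 valid days to be usable.
"""

from paq_agree import SimulationConfig, simulate_study, process_series

data = simulate_study(SimulationConfig(n_participants=2, epoch_seconds=30, seed=7))
pid = data.roster[0].participant_id
series = data.epochs[pid]
print(f"{pid}: {len(series)} epochs of {series.epoch_seconds} s")

days, weeks = process_series(series)
d = days[0]
print(f"\nday 1: wear {d.wear_minutes} min, non-wear {d.nonwear_minutes} min, "
      f"valid={d.valid}")
print(f"  sedentary {d.sedentary_minutes}, light {d.light_minutes}, "
      f"moderate {d.moderate_minutes}, vigorous {d.vigorous_minutes} min")
# category minutes always sum to wear minutes; wear + non-wear = recorded

for w in weeks:
    print(f"week {w.week_index}: {w.n_valid_days}/7 valid days, usable={w.usable}, "
          f"moderate {w.moderate_min_per_day:.1f}, vigorous {w.vigorous_min_per_day:.1f}, "
          f"sedentary {w.sedentary_min_per_day:.1f} min/day")
# These daily averages over valid days are what the questionnaire is
# validated against, week by week.
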