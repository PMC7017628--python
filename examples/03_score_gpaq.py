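"""Clean and score a GPAQ response to daily minutes per intensity.

Scoring combines work, transport and leisure activity; transport always
counts as moderate intensity.  Cleaning flags internally inconsistent item
blocks, durations above 16 h/day, and day totals above 24 h; flagged
responses are excluded from analysis.
"""

from paq_agree import ActivityBlock, GpaqResponse, clean_response, daily_minutes, score_response

r = GpaqResponse(
    participant_id="P001",
    version="with_cards",
    work_vigorous=ActivityBlock(engages=True, days_per_week=3, minutes_per_day=60),
    transport=ActivityBlock(engages=True, days_per_week=5, minutes_per_day=20),
    leisure_moderate=ActivityBlock(engages=True, days_per_week=2, minutes_per_day=30),
    sedentary_minutes_per_day=420,
)
_, reasons = clean_response(r)
print("exclusion reasons:", reasons or "none (clean)")

s = daily_minutes(r)
print(f"vigorous: {s.vigorous_min_per_day:.2f} min/day   # 3x60 / 7")
print(f"moderate: {s.moderate_min_per_day:.2f} min/day   # (5x20 + 2x30) / 7")
print(f"sedentary: {s.sedentary_min_per_day:.0f} min/day")

bad = GpaqResponse(
    participant_id="P002", version="without_cards",
    work_moderate=ActivityBlock(engages=True, days_per_week=3, minutes_per_day=1200),
    sedentary_minutes_per_day=300,
)
flagged = score_response(bad)
print(f"\nimplausible respondent clean={flagged.clean}: {flagged.exclusion_reasons}")
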