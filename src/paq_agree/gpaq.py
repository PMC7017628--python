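"""GPAQ (Global Physical Activity Questionnaire) cleaning and scoring.

The GPAQ asks, for five domain-intensity blocks (vigorous and moderate work,
transport, vigorous and moderate leisure activity), whether the respondent
engages in the activity, on how many days per typical week, and for how long
per day, plus a single sedentary-time item.  Scoring reduces a response to
daily minutes of moderate activity, vigorous activity and sedentary
behaviour; transport always counts as moderate intensity.  Cleaning follows
the analysis-guide conventions: internally inconsistent blocks, implausible
per-block durations (> 16 h/day) and implausible day totals (> 24 h) mark a
response unclean and excluded from analysis.
"""

from __future__ import annotations

import csv
import json
import re
from dataclasses import dataclass, field
from pathlib import Path

__all__ = [
    "ActivityBlock",
    "GpaqResponse",
    "GpaqSummary",
    "CleaningRules",
    "clean_response",
    "daily_minutes",
    "score_response",
    "parse_duration_minutes",
    "read_responses_csv",
    "write_responses_csv",
    "read_responses_json",
    "write_responses_json",
]

BLOCKS = ("work_vigorous", "work_moderate", "transport", "leisure_vigorous", "leisure_moderate")
VIGOROUS_BLOCKS = ("work_vigorous", "leisure_vigorous")
MODERATE_BLOCKS = ("work_moderate", "transport", "leisure_moderate")
VERSIONS = ("with_cards", "without_cards")


@dataclass
class ActivityBlock:
    """One domain-intensity item triple: engagement, days/week, min/day."""

    engages: bool = False
    days_per_week: float | None = None
    minutes_per_day: float | None = None

    def weekly_minutes(self) -> float:
        if not self.engages or self.days_per_week is None or self.minutes_per_day is None:
            return 0.0
        return float(self.days_per_week) * float(self.minutes_per_day)


def _empty_block() -> ActivityBlock:
    return ActivityBlock()


@dataclass
class GpaqResponse:
    participant_id: str
    version: str  # with_cards | without_cards
    administration_day: int = 7
    work_vigorous: ActivityBlock = field(default_factory=_empty_block)
    work_moderate: ActivityBlock = field(default_factory=_empty_block)
    transport: ActivityBlock = field(default_factory=_empty_block)
    leisure_vigorous: ActivityBlock = field(default_factory=_empty_block)
    leisure_moderate: ActivityBlock = field(default_factory=_empty_block)
    sedentary_minutes_per_day: float | None = None

    def __post_init__(self) -> None:
        if not self.participant_id:
            raise ValueError("missing participant_id")
        if self.version not in VERSIONS:
            raise ValueError(f"unknown GPAQ version {self.version!r}")

    def block(self, name: str) -> ActivityBlock:
        return getattr(self, name)


@dataclass
class GpaqSummary:
    """Scored response: daily minutes by intensity plus cleaning status."""

    participant_id: str
    version: str
    moderate_min_per_day: float
    vigorous_min_per_day: float
    sedentary_min_per_day: float
    clean: bool = True
    exclusion_reasons: list[str] = field(default_factory=list)


@dataclass(frozen=True)
class CleaningRules:
    """Which analysis-guide cleaning rules to apply.

    check_consistency: engagement, days and minutes of a block must agree;
    max_block_minutes: per-block daily duration cap (default 960 = 16 h);
    check_daily_total: reported activity plus sedentary time must fit in 24 h.
    """

    check_consistency: bool = True
    max_block_minutes: float | None = 960.0
    check_daily_total: bool = True


def clean_response(
    r: GpaqResponse, rules: CleaningRules = CleaningRules()
) -> tuple[GpaqResponse, list[str]]:
    """Apply the cleaning rules; returns the response and any exclusion reasons.

    A response with one or more reasons is unclean and is dropped listwise
    from paired analyses.
    """
    reasons: list[str] = []
    for name in BLOCKS:
        b = r.block(name)
        if rules.check_consistency:
            if b.engages and (b.days_per_week is None or b.minutes_per_day is None):
                reasons.append(f"inconsistent block: {name} (engages without days/minutes)")
            elif b.engages and b.days_per_week is not None and b.minutes_per_day is not None:
                if (b.days_per_week > 0) != (b.minutes_per_day > 0):
                    reasons.append(f"inconsistent block: {name} (days/minutes disagree)")
            elif not b.engages and (b.days_per_week or b.minutes_per_day):
                reasons.append(f"inconsistent block: {name} (values despite engages=no)")
            if b.days_per_week is not None and not 0 <= b.days_per_week <= 7:
                reasons.append(f"inconsistent block: {name} (days outside 0-7)")
        if (
            rules.max_block_minutes is not None
            and b.minutes_per_day is not None
            and b.minutes_per_day > rules.max_block_minutes
        ):
            reasons.append(f"duration > 16 h: {name}")
    if rules.check_daily_total:
        activity_daily = sum(r.block(n).weekly_minutes() for n in BLOCKS) / 7.0
        sed = r.sedentary_minutes_per_day or 0.0
        if activity_daily + sed > 1440.0:
            reasons.append("daily total > 24 h")
    return r, reasons


def daily_minutes(r: GpaqResponse, rules: CleaningRules = CleaningRules()) -> GpaqSummary:
    """Score a clean response to daily minutes per intensity.

    vigorous = (vigorous work + vigorous leisure weekly minutes) / 7;
    moderate = (moderate work + transport + moderate leisure) / 7;
    sedentary is passed through.  Raises if the response is unclean.
    """
    _, reasons = clean_response(r, rules)
    if reasons:
        raise ValueError(f"unclean response for {r.participant_id}: {reasons}")
    vig = sum(r.block(n).weekly_minutes() for n in VIGOROUS_BLOCKS) / 7.0
    mod = sum(r.block(n).weekly_minutes() for n in MODERATE_BLOCKS) / 7.0
    return GpaqSummary(
        participant_id=r.participant_id,
        version=r.version,
        moderate_min_per_day=mod,
        vigorous_min_per_day=vig,
        sedentary_min_per_day=float(r.sedentary_minutes_per_day or 0.0),
    )


def score_response(r: GpaqResponse, rules: CleaningRules = CleaningRules()) -> GpaqSummary:
    """Clean then score; unclean responses come back flagged with NaN minutes."""
    _, reasons = clean_response(r, rules)
    if reasons:
        nan = float("nan")
        return GpaqSummary(r.participant_id, r.version, nan, nan, nan, clean=False,
                           exclusion_reasons=reasons)
    return daily_minutes(r, rules)


_DURATION_RE = re.compile(r"^(\d{1,2}):([0-5]\d)$")


def parse_duration_minutes(text: str | float | int | None) -> float | None:
    """Normalise a duration cell to minutes.

    Accepts plain minutes ("45", 45) or hours:minutes text ("1:30" -> 90).
    Empty cells are missing; anything else is rejected rather than guessed.
    """
    if text is None:
        return None
    if isinstance(text, (int, float)):
        return float(text)
    text = text.strip()
    if not text:
        return None
    m = _DURATION_RE.match(text)
    if m:
        return int(m.group(1)) * 60.0 + int(m.group(2))
    try:
        return float(text)
    except ValueError:
        raise ValueError(f"ambiguous duration entry {text!r}")


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

_FIELDNAMES = ["participant_id", "version", "administration_day"] + [
    f"{b}_{suffix}" for b in BLOCKS for suffix in ("engages", "days", "minutes")
] + ["sedentary_minutes"]


def _block_to_cells(b: ActivityBlock) -> list[str]:
    return [
        "yes" if b.engages else "no",
        "" if b.days_per_week is None else f"{b.days_per_week:g}",
        "" if b.minutes_per_day is None else f"{b.minutes_per_day:g}",
    ]


def _cells_to_block(engages: str, days: str, minutes: str) -> ActivityBlock:
    return ActivityBlock(
        engages=engages.strip().lower() in ("yes", "1", "true", "y"),
        days_per_week=float(days) if days.strip() else None,
        minutes_per_day=parse_duration_minutes(minutes),
    )


def write_responses_csv(responses: list[GpaqResponse], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(_FIELDNAMES)
        for r in responses:
            row = [r.participant_id, r.version, str(r.administration_day)]
            for b in BLOCKS:
                row += _block_to_cells(r.block(b))
            row.append("" if r.sedentary_minutes_per_day is None else f"{r.sedentary_minutes_per_day:g}")
            writer.writerow(row)


def read_responses_csv(path: str | Path) -> list[GpaqResponse]:
    out: list[GpaqResponse] = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            kwargs = {
                b: _cells_to_block(row[f"{b}_engages"], row[f"{b}_days"], row[f"{b}_minutes"])
                for b in BLOCKS
            }
            sed = row.get("sedentary_minutes", "")
            out.append(
                GpaqResponse(
                    participant_id=row["participant_id"],
                    version=row["version"],
                    administration_day=int(row.get("administration_day") or 7),
                    sedentary_minutes_per_day=parse_duration_minutes(sed),
                    **kwargs,
                )
            )
    return out


def _response_to_dict(r: GpaqResponse) -> dict:
    d = {
        "participant_id": r.participant_id,
        "version": r.version,
        "administration_day": r.administration_day,
        "sedentary_minutes_per_day": r.sedentary_minutes_per_day,
    }
    for b in BLOCKS:
        blk = r.block(b)
        d[b] = {
            "engages": blk.engages,
            "days_per_week": blk.days_per_week,
            "minutes_per_day": blk.minutes_per_day,
        }
    return d


def write_responses_json(responses: list[GpaqResponse], path: str | Path) -> None:
    Path(path).write_text(
        json.dumps([_response_to_dict(r) for r in responses], indent=1, sort_keys=True)
    )


def read_responses_json(path: str | Path) -> list[GpaqResponse]:
    raw = json.loads(Path(path).read_text())
    out = []
    for d in raw:
        kwargs = {b: ActivityBlock(**d[b]) for b in BLOCKS}
        out.append(
            GpaqResponse(
                participant_id=d["participant_id"],
                version=d["version"],
                administration_day=d.get("administration_day", 7),
                sedentary_minutes_per_day=d.get("sedentary_minutes_per_day"),
                **kwargs,
            )
        )
    return out
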