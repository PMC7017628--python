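"""Epoch-level accelerometer count processing.

Turns ActiGraph-style epoch count exports into per-day and per-week summaries
of sedentary, light, moderate and vigorous minutes:

1. reintegration of 30-s epochs to counts per minute (CPM),
2. intensity classification by Freedson adult cut-points,
3. non-wear detection (sustained zero-count windows with a short-interruption
   tolerance in the style of Troiano et al.),
4. wear-time validity filtering (>= 10 h wear per day, >= 3 valid days per
   week) and daily averaging over valid days.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "CutPoints",
    "FREEDSON_ADULT",
    "NonwearParams",
    "EpochSeries",
    "DayMetrics",
    "WeekSummary",
    "INTENSITY_CATEGORIES",
    "load_epochs",
    "write_epochs",
    "reintegrate",
    "classify_intensity",
    "classify_intensity_array",
    "detect_nonwear",
    "split_days",
    "summarize_day",
    "weekly_summary",
    "process_series",
]

INTENSITY_CATEGORIES = ("sedentary", "light", "moderate", "vigorous")


class FormatError(ValueError):
    """Raised when an epoch file cannot be parsed."""


@dataclass(frozen=True)
class CutPoints:
    """Inclusive CPM upper bounds for sedentary / light / moderate intensity.

    Everything above ``moderate_max`` is vigorous.  Defaults are the Freedson
    adult vertical-axis cut-points (sedentary 0-99, light 100-1951, moderate
    1952-5724, vigorous > 5724 CPM).
    """

    sedentary_max: int = 99
    light_max: int = 1951
    moderate_max: int = 5724

    def __post_init__(self) -> None:
        if not (0 <= self.sedentary_max < self.light_max < self.moderate_max):
            raise ValueError("cut-points must be nonnegative and strictly increasing")

    @property
    def bounds(self) -> np.ndarray:
        return np.array([self.sedentary_max, self.light_max, self.moderate_max])


FREEDSON_ADULT = CutPoints()


@dataclass(frozen=True)
class NonwearParams:
    """Parameters of the zero-count non-wear rule.

    A non-wear window is >= ``min_window_minutes`` of consecutive zero CPM,
    tolerating interruptions of at most ``interruption_max_run_minutes``
    consecutive minutes with 1..``interruption_max_cpm`` CPM.
    ``max_interruption_runs_per_window`` caps how many tolerated interruption
    runs one window may contain (``None`` = unlimited).
    """

    min_window_minutes: int = 60
    interruption_max_cpm: int = 100
    interruption_max_run_minutes: int = 2
    max_interruption_runs_per_window: int | None = None

    def __post_init__(self) -> None:
        if self.min_window_minutes <= 0 or self.interruption_max_cpm <= 0:
            raise ValueError("non-wear parameters must be positive")
        if self.interruption_max_run_minutes <= 0:
            raise ValueError("non-wear parameters must be positive")
        if (
            self.max_interruption_runs_per_window is not None
            and self.max_interruption_runs_per_window < 0
        ):
            raise ValueError("max_interruption_runs_per_window must be >= 0 or None")


@dataclass
class EpochSeries:
    """An ordered series of activity counts for one participant.

    ``counts`` holds vertical-axis (axis 1) counts per epoch; extra axes from
    triaxial exports are parsed but not carried (the Freedson cut-points are
    defined on the vertical axis).
    """

    participant_id: str
    start_timestamp: dt.datetime
    epoch_seconds: int
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.epoch_seconds not in (30, 60):
            raise ValueError("epoch_seconds must be 30 or 60")
        if self.counts.ndim != 1 or len(self.counts) == 0:
            raise ValueError("counts must be a nonempty 1-D sequence")
        if (self.counts < 0).any():
            raise ValueError("counts must be nonnegative")

    def __len__(self) -> int:
        return len(self.counts)

    def timestamps(self) -> np.ndarray:
        """Epoch start times as a numpy datetime64 array."""
        start = np.datetime64(self.start_timestamp, "s")
        step = np.timedelta64(self.epoch_seconds, "s")
        return start + step * np.arange(len(self.counts))


@dataclass
class DayMetrics:
    """Wear time and per-intensity minutes for one calendar day."""

    participant_id: str
    date: dt.date
    recorded_minutes: int
    wear_minutes: int
    nonwear_minutes: int
    sedentary_minutes: int
    light_minutes: int
    moderate_minutes: int
    vigorous_minutes: int
    valid: bool


@dataclass
class WeekSummary:
    """Daily averages over the valid days of one study week."""

    participant_id: str
    week_index: int
    n_days: int
    n_valid_days: int
    sedentary_min_per_day: float
    light_min_per_day: float
    moderate_min_per_day: float
    vigorous_min_per_day: float
    usable: bool


# ---------------------------------------------------------------------------
# I/O: ActiGraph-style epoch CSV
# ---------------------------------------------------------------------------

_HEADER_LINES = 10


def _parse_header(lines: Sequence[str], path: str) -> tuple[dt.datetime, int]:
    start_time = start_date = epoch = None
    for i, line in enumerate(lines):
        low = line.lower()
        if low.startswith("start time"):
            start_time = line.split()[-1]
        elif low.startswith("start date"):
            start_date = line.split()[-1]
        elif low.startswith("epoch period"):
            epoch = line.split()[-1]
    if start_time is None or start_date is None or epoch is None:
        raise FormatError(f"{path}: device header missing start date/time or epoch period")
    try:
        h, m, s = (int(x) for x in epoch.split(":"))
        epoch_seconds = h * 3600 + m * 60 + s
        month, day, year = (int(x) for x in start_date.split("/"))
        hh, mm, ss = (int(x) for x in start_time.split(":"))
        start = dt.datetime(year, month, day, hh, mm, ss)
    except ValueError as exc:
        raise FormatError(f"{path}: unparseable device header: {exc}") from exc
    return start, epoch_seconds


def load_epochs(
    path: str | Path,
    participant_id: str | None = None,
    epoch_seconds: int = 60,
    start_timestamp: dt.datetime | None = None,
) -> EpochSeries:
    """Read an ActiGraph-style epoch CSV.

    The file may start with the usual 10-line device header (parsed for start
    date/time and epoch period) or be headerless, in which case
    ``epoch_seconds`` and ``start_timestamp`` supply the metadata.  Data rows
    are ``axis1[,axis2,axis3]`` or ``timestamp,axis1[,...]``.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    if not lines:
        raise FormatError(f"{path}: empty file")

    first_data = 0
    if lines[0].startswith("---"):
        start, epoch_seconds = _parse_header(lines[:_HEADER_LINES], str(path))
        start_timestamp = start
        first_data = _HEADER_LINES
    if start_timestamp is None:
        start_timestamp = dt.datetime(2000, 1, 1)

    counts: list[int] = []
    for lineno, line in enumerate(lines[first_data:], start=first_data + 1):
        line = line.strip()
        if not line or line.lower().startswith(("axis", "date,", "timestamp")):
            continue
        fields = line.split(",")
        # timestamped rows carry the timestamp in column 0
        col = 1 if (":" in fields[0] or "-" in fields[0] or "/" in fields[0]) else 0
        try:
            value = int(float(fields[col]))
        except (ValueError, IndexError) as exc:
            raise FormatError(f"{path}:{lineno}: unparseable count row {line!r}") from exc
        if value < 0:
            raise ValueError(f"{path}:{lineno}: negative count {value}")
        counts.append(value)
    if not counts:
        raise FormatError(f"{path}: no data rows")

    return EpochSeries(
        participant_id=participant_id or path.stem,
        start_timestamp=start_timestamp,
        epoch_seconds=epoch_seconds,
        counts=np.asarray(counts),
    )


def write_epochs(series: EpochSeries, path: str | Path, header: bool = True) -> None:
    """Write an epoch series in the ActiGraph export layout load_epochs reads."""
    path = Path(path)
    out: list[str] = []
    if header:
        start = series.start_timestamp
        epoch = dt.timedelta(seconds=series.epoch_seconds)
        out += [
            "------------ Data File Created By ActiGraph GT3X+ ActiLife v6.10.2 ------------",
            f"Serial Number: SYN-{series.participant_id}",
            f"Start Time {start:%H:%M:%S}",
            f"Start Date {start.month:02d}/{start.day:02d}/{start.year}",
            f"Epoch Period (hh:mm:ss) {str(epoch).rjust(8, '0')}",
            "Download Time 00:00:00",
            "Download Date 01/01/2000",
            "Current Memory Address: 0",
            "Current Battery Voltage: 4.07     Mode = 0",
            "--------------------------------------------------",
        ]
    out.extend(str(int(c)) for c in series.counts)
    path.write_text("\n".join(out) + "\n")


# ---------------------------------------------------------------------------
# Reintegration and classification
# ---------------------------------------------------------------------------

def reintegrate(series: EpochSeries, target_seconds: int = 60) -> EpochSeries:
    """Sum consecutive epochs into ``target_seconds`` epochs (e.g. 30 s -> CPM).

    A trailing partial epoch is dropped; total counts are conserved up to that
    remainder.
    """
    if target_seconds < series.epoch_seconds:
        raise ValueError("target epoch must not be shorter than the source epoch")
    if target_seconds % series.epoch_seconds:
        raise ValueError("target epoch must be a multiple of the source epoch")
    k = target_seconds // series.epoch_seconds
    if k == 1:
        return replace(series, counts=series.counts.copy())
    n = (len(series.counts) // k) * k
    summed = series.counts[:n].reshape(-1, k).sum(axis=1)
    return EpochSeries(
        participant_id=series.participant_id,
        start_timestamp=series.start_timestamp,
        epoch_seconds=target_seconds,
        counts=summed,
    )


def classify_intensity(cpm: int, cuts: CutPoints = FREEDSON_ADULT) -> str:
    """Map one CPM value to its intensity category (inclusive band bounds)."""
    if cpm < 0:
        raise ValueError("CPM must be nonnegative")
    return INTENSITY_CATEGORIES[int(np.searchsorted(cuts.bounds, cpm, side="left"))]


def classify_intensity_array(cpm: np.ndarray, cuts: CutPoints = FREEDSON_ADULT) -> np.ndarray:
    """Vectorised classification: integer codes 0..3 indexing INTENSITY_CATEGORIES."""
    cpm = np.asarray(cpm)
    if (cpm < 0).any():
        raise ValueError("CPM must be nonnegative")
    return np.searchsorted(cuts.bounds, cpm, side="left")


# ---------------------------------------------------------------------------
# Non-wear detection
# ---------------------------------------------------------------------------

def _runs(mask: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Start and inclusive end indices of maximal True runs."""
    starts = np.flatnonzero(mask & ~np.r_[False, mask[:-1]])
    ends = np.flatnonzero(mask & ~np.r_[mask[1:], False])
    return starts, ends


def _mark_ranges(n: int, starts: np.ndarray, ends: np.ndarray) -> np.ndarray:
    delta = np.zeros(n + 1, dtype=np.int64)
    np.add.at(delta, starts, 1)
    np.add.at(delta, ends + 1, -1)
    return np.cumsum(delta[:-1]) > 0


def detect_nonwear(series: EpochSeries, params: NonwearParams = NonwearParams()) -> np.ndarray:
    """Boolean per-minute mask, True where the device was judged not worn.

    A minute is non-wear iff it lies in a window of >= ``min_window_minutes``
    made of zero-CPM minutes and tolerated interruption runs (each run at most
    ``interruption_max_run_minutes`` consecutive minutes, every interrupted
    minute 1..``interruption_max_cpm`` CPM).  Any minute above the interruption
    cap, or a nonzero run longer than the tolerance, terminates a window;
    windows start and end on zero minutes, and interruption minutes inside a
    qualifying window count as non-wear.
    """
    if series.epoch_seconds != 60:
        raise ValueError("detect_nonwear requires a per-minute series; reintegrate first")
    cpm = series.counts
    n = len(cpm)
    zero = cpm == 0
    if params.max_interruption_runs_per_window is not None:
        return _detect_nonwear_capped(cpm, params)

    # breaker runs: maximal nonzero runs that can never be tolerated
    starts, ends = _runs(~zero)
    if len(starts):
        over = np.r_[0, np.cumsum(cpm > params.interruption_max_cpm)]
        bad = (ends - starts + 1 > params.interruption_max_run_minutes) | (
            over[ends + 1] - over[starts] > 0
        )
        breaker = _mark_ranges(n, starts[bad], ends[bad])
    else:
        breaker = np.zeros(n, dtype=bool)

    # candidate segments between breakers, trimmed to their first/last zero
    seg_starts, seg_ends = _runs(~breaker)
    zidx = np.flatnonzero(zero)
    lo = np.searchsorted(zidx, seg_starts, side="left")
    hi = np.searchsorted(zidx, seg_ends, side="right") - 1
    has_zero = hi >= lo
    wstart = zidx[lo[has_zero]]
    wend = zidx[hi[has_zero]]
    long_enough = wend - wstart + 1 >= params.min_window_minutes
    return _mark_ranges(n, wstart[long_enough], wend[long_enough])


def _detect_nonwear_capped(cpm: np.ndarray, params: NonwearParams) -> np.ndarray:
    """Run-list path honouring a finite cap on interruption runs per window.

    A minute is non-wear iff some zero-bounded window of sufficient length
    contains it while using at most the allowed number of interruption runs.
    """
    n = len(cpm)
    mask = np.zeros(n, dtype=bool)
    # run-length encode into (kind, start, end): kind 0 zero, 1 interruptible, 2 breaker
    boundaries = np.flatnonzero(np.r_[True, np.diff(cpm != 0) != 0, True])
    runs = []
    for s, e in zip(boundaries[:-1], boundaries[1:] - 1):
        if cpm[s] == 0:
            runs.append((0, s, e))
        elif (e - s + 1) <= params.interruption_max_run_minutes and (
            cpm[s : e + 1] <= params.interruption_max_cpm
        ).all():
            runs.append((1, s, e))
        else:
            runs.append((2, s, e))
    zero_runs = [i for i, r in enumerate(runs) if r[0] == 0]
    for a_pos, i in enumerate(zero_runs):
        # widest window starting at zero run i, ending on a zero run,
        # crossing no breaker and <= cap interruption runs
        interruptions = 0
        j = i
        best_end = runs[i][2]
        while j + 1 < len(runs):
            j += 1
            kind = runs[j][0]
            if kind == 2:
                break
            if kind == 1:
                interruptions += 1
                if interruptions > params.max_interruption_runs_per_window:
                    break
            else:
                best_end = runs[j][2]
        start = runs[i][1]
        if best_end - start + 1 >= params.min_window_minutes:
            mask[start : best_end + 1] = True
            # interior interruption minutes between start and best_end are covered
    return mask


# ---------------------------------------------------------------------------
# Daily and weekly summaries
# ---------------------------------------------------------------------------

def split_days(series: EpochSeries) -> list[tuple[dt.date, np.ndarray]]:
    """Index ranges of each local calendar day in a per-minute series.

    Returns (date, epoch-index array) pairs in chronological order; partial
    first/last days are returned as-is.
    """
    if series.epoch_seconds != 60:
        raise ValueError("split_days requires a per-minute series")
    days = series.timestamps().astype("datetime64[D]")
    out = []
    for day in np.unique(days):
        idx = np.flatnonzero(days == day)
        out.append((day.astype(dt.date), idx))
    return out


def summarize_day(
    series: EpochSeries,
    nonwear_mask: np.ndarray,
    cuts: CutPoints = FREEDSON_ADULT,
    min_wear_minutes: int = 600,
    date: dt.date | None = None,
) -> DayMetrics:
    """Wear time and per-category minutes for one calendar day of minutes.

    Non-wear minutes are excluded from category counts; the day is valid when
    wear time reaches ``min_wear_minutes`` (default 10 h).
    """
    if series.epoch_seconds != 60:
        raise ValueError("summarize_day requires a per-minute series")
    if len(series.counts) == 0:
        raise ValueError("empty day")
    if len(nonwear_mask) != len(series.counts):
        raise ValueError("mask length must match series length")
    wear = ~np.asarray(nonwear_mask, dtype=bool)
    codes = classify_intensity_array(series.counts[wear], cuts)
    cat_minutes = np.bincount(codes, minlength=4)
    wear_minutes = int(wear.sum())
    return DayMetrics(
        participant_id=series.participant_id,
        date=date if date is not None else series.start_timestamp.date(),
        recorded_minutes=len(series.counts),
        wear_minutes=wear_minutes,
        nonwear_minutes=len(series.counts) - wear_minutes,
        sedentary_minutes=int(cat_minutes[0]),
        light_minutes=int(cat_minutes[1]),
        moderate_minutes=int(cat_minutes[2]),
        vigorous_minutes=int(cat_minutes[3]),
        valid=wear_minutes >= min_wear_minutes,
    )


def weekly_summary(days: Iterable[DayMetrics], week_index: int, min_valid_days: int = 3) -> WeekSummary:
    """Daily averages (min/day) over valid days of one study week.

    The averages divide by the number of valid days; a week is usable only
    when it has at least ``min_valid_days`` valid days (unusable weeks still
    report averages, flagged).  Zero valid days yield NaN averages.
    """
    days = list(days)
    if not days:
        raise ValueError("weekly_summary needs at least one day")
    if len(days) > 7:
        raise ValueError("a study week has at most 7 days")
    valid = [d for d in days if d.valid]
    nv = len(valid)

    def avg(attr: str) -> float:
        if nv == 0:
            return float("nan")
        return float(np.mean([getattr(d, attr) for d in valid]))

    return WeekSummary(
        participant_id=days[0].participant_id,
        week_index=week_index,
        n_days=len(days),
        n_valid_days=nv,
        sedentary_min_per_day=avg("sedentary_minutes"),
        light_min_per_day=avg("light_minutes"),
        moderate_min_per_day=avg("moderate_minutes"),
        vigorous_min_per_day=avg("vigorous_minutes"),
        usable=nv >= min_valid_days,
    )


def process_series(
    series: EpochSeries,
    cuts: CutPoints = FREEDSON_ADULT,
    nonwear: NonwearParams = NonwearParams(),
    min_wear_minutes: int = 600,
    min_valid_days: int = 3,
) -> tuple[list[DayMetrics], list[WeekSummary]]:
    """Full processing of one participant's recording.

    Reintegrates to CPM, detects non-wear over the whole series (windows may
    span midnight), summarises each calendar day, and splits days into study
    weeks 1 (days 1-7) and 2 (days 8-14) counted from the first recorded
    calendar day.
    """
    minutes = reintegrate(series, 60)
    mask = detect_nonwear(minutes, nonwear)
    day_metrics: list[DayMetrics] = []
    for date, idx in split_days(minutes):
        day_series = EpochSeries(
            participant_id=minutes.participant_id,
            start_timestamp=minutes.start_timestamp,
            epoch_seconds=60,
            counts=minutes.counts[idx],
        )
        day_metrics.append(
            summarize_day(day_series, mask[idx], cuts, min_wear_minutes, date=date)
        )
    first = day_metrics[0].date
    weeks: list[WeekSummary] = []
    for wi in (1, 2):
        in_week = [
            d for d in day_metrics if 7 * (wi - 1) <= (d.date - first).days < 7 * wi
        ]
        if in_week:
            weeks.append(weekly_summary(in_week, wi, min_valid_days))
    return day_metrics, weeks
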