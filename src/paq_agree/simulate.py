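"""Synthetic crossover validation study generator.

Builds a complete two-week questionnaire-vs-accelerometer study with known
ground truth: a participant roster with balanced crossover group assignment,
per-participant epoch count series with scheduled non-wear blocks and
intensity structure, and paired GPAQ self-reports with a configurable bias
pattern (over-reported vigorous, under-reported moderate activity).

Construction guarantees, relied on by tests downstream:

* every emitted epoch's CPM lies inside its generating state's cut-point band;
* the non-wear detector recovers exactly the scheduled non-wear minutes —
  scheduled blocks are pure zero runs >= 60 min flanked by >100 CPM minutes,
  and wear time contains no zero-bounded low-count (<=100 CPM) window long
  enough to qualify;
* per-day state minute counts are recorded as ground truth and equal the
  classifier's output on wear time.
"""

from __future__ import annotations

import datetime as dt
import json
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .accel import CutPoints, FREEDSON_ADULT, EpochSeries, write_epochs
from .gpaq import ActivityBlock, GpaqResponse, write_responses_csv

__all__ = [
    "SimulationConfig",
    "TruthProfile",
    "StudyData",
    "generate_roster",
    "simulate_epoch_series",
    "simulate_gpaq_response",
    "simulate_study",
    "write_study",
]

STATES = ("sedentary", "light", "moderate", "vigorous")
_NONWEAR = 4  # label for scheduled non-wear minutes

GROUP_PLUS_FIRST = "with_cards_first"
GROUP_MINUS_FIRST = "without_cards_first"


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the generator.

    Defaults emulate the validation-study design: 14 days of wear, 30-s
    device epochs, roughly three-fold over-reporting of vigorous and 20%
    under-reporting of moderate activity, lognormal recall noise with CV 0.3,
    one long scheduled non-wear (sleep/charging) block per day, and no
    additive show-card effect on reporting accuracy.
    """

    n_participants: int = 54
    n_days: int = 14
    epoch_seconds: int = 30
    seed: int = 0
    vigorous_report_factor: float = 3.0
    moderate_report_factor: float = 0.8
    report_noise_cv: float = 0.3
    showcard_effect: float = 0.0
    nonwear_blocks_per_day: int = 1
    dropout_fraction: float = 0.0
    start_date: dt.date = dt.date(2017, 5, 15)

    def __post_init__(self) -> None:
        if self.n_participants < 2:
            raise ValueError("n_participants must be >= 2")
        if self.n_days < 1:
            raise ValueError("n_days must be >= 1")
        if self.epoch_seconds not in (30, 60):
            raise ValueError("epoch_seconds must be 30 or 60")
        if self.vigorous_report_factor <= 0 or self.moderate_report_factor <= 0:
            raise ValueError("report factors must be positive")
        if self.report_noise_cv < 0:
            raise ValueError("report_noise_cv must be nonnegative")
        if self.nonwear_blocks_per_day < 0:
            raise ValueError("nonwear_blocks_per_day must be nonnegative")
        if not 0 <= self.dropout_fraction <= 1:
            raise ValueError("dropout_fraction must be in [0, 1]")


@dataclass
class TruthProfile:
    """Ground-truth activity profile and demographics for one participant."""

    participant_id: str
    sex: str  # female | male
    age: float
    bmi: float
    group: str  # with_cards_first | without_cards_first
    target_minutes: dict[str, float]  # daily sedentary/light/moderate/vigorous
    dropout_week: int | None = None  # week with insufficient valid days

    def __post_init__(self) -> None:
        total = sum(self.target_minutes.values())
        if total > 1440:
            raise ValueError(f"daily target minutes sum to {total} > 1440")


@dataclass
class StudyData:
    """Everything one simulated study produces, in memory."""

    config: SimulationConfig
    roster: list[TruthProfile]
    epochs: dict[str, EpochSeries]
    responses: list  # GpaqResponse, ordered by participant then administration
    truth_day_minutes: dict[str, list[dict[str, int]]]  # per participant per day
    truth_week_means: dict[str, dict[int, dict[str, float]]]


def _participant_rng(config: SimulationConfig, pid: str, *extra: int) -> np.random.Generator:
    # one stream per participant so adding participants does not reshuffle others
    return np.random.default_rng([config.seed, zlib.crc32(pid.encode()), *extra])


def generate_roster(config: SimulationConfig) -> list[TruthProfile]:
    """Roster with alternating (balanced +/-1) crossover group assignment.

    Demographics follow the study sample: ~57% female, age from a truncated
    normal(28.3, 12.2) floored at 18 years, BMI ~ normal(23.2, 3.1).  Daily
    activity targets centre on accelerometer-typical values (sedentary ~440,
    light ~330, moderate ~110, vigorous ~13 min/day).
    """
    roster: list[TruthProfile] = []
    width = max(3, len(str(config.n_participants)))
    for i in range(config.n_participants):
        pid = f"P{i + 1:0{width}d}"
        rng = _participant_rng(config, pid)
        sex = "female" if rng.random() < 0.574 else "male"
        age = 0.0
        while (age := rng.normal(28.3, 12.2)) < 18:
            pass
        bmi = float(np.clip(rng.normal(23.2, 3.1), 16.0, 40.0))
        targets = {
            "sedentary": float(np.clip(rng.normal(440, 70), 240, 700)),
            "light": float(np.clip(rng.normal(330, 60), 60, 600)),
            "moderate": float(np.clip(rng.normal(110, 30), 20, 240)),
            "vigorous": float(np.clip(rng.lognormal(np.log(12.0), 0.6), 2, 60)),
        }
        reserve = max(1, config.nonwear_blocks_per_day) * 60
        wear = sum(targets.values())
        if wear > 1440 - reserve:  # keep room for scheduled non-wear
            targets["light"] = max(60.0, targets["light"] - (wear - (1440 - reserve)))
        if config.nonwear_blocks_per_day == 0:
            targets["light"] = 1440 - (
                targets["sedentary"] + targets["moderate"] + targets["vigorous"]
            )
        dropout = rng.random() < config.dropout_fraction
        roster.append(
            TruthProfile(
                participant_id=pid,
                sex=sex,
                age=float(age),
                bmi=bmi,
                group=GROUP_PLUS_FIRST if i % 2 == 0 else GROUP_MINUS_FIRST,
                target_minutes=targets,
                dropout_week=int(rng.integers(1, 3)) if dropout else None,
            )
        )
    return roster


def _day_state_labels(
    profile: TruthProfile, config: SimulationConfig, day: int, rng: np.random.Generator
) -> np.ndarray:
    """Minute state labels (0-3 intensity, 4 scheduled non-wear) for one day."""
    minutes = {}
    for k, s in enumerate(STATES):
        t = profile.target_minutes[s]
        minutes[k] = max(1 if k > 0 else 0, int(round(t + rng.normal(0, 0.1 * t))))
    week = 1 + day // 7
    if profile.dropout_week == week and (day % 7) < 5:
        # insufficient-wear day: shrink every state so wear < 600 min
        wear = sum(minutes.values())
        scale = 420.0 / wear
        minutes = {k: int(round(v * scale)) for k, v in minutes.items()}
    wear = sum(minutes.values())
    if sum(profile.target_minutes.values()) > 1440:
        raise ValueError("daily target minutes exceed 1440")
    if wear > 1440:  # day-to-day jitter overshoot: rescale to fit the day
        scale = 1440.0 / wear
        minutes = {k: int(v * scale) for k, v in minutes.items()}
        wear = sum(minutes.values())
    nonwear_total = 1440 - wear

    labels = np.repeat(np.arange(4), [minutes[k] for k in range(4)])
    labels = rng.permutation(labels)

    k_blocks = config.nonwear_blocks_per_day
    # remainders too short for a detectable (>= 60 min) block become light wear
    if k_blocks == 0 or nonwear_total < 60:
        if nonwear_total:
            labels = np.concatenate([labels, np.full(nonwear_total, 1)])
            labels = rng.permutation(labels)
        return labels
    k_blocks = min(k_blocks, nonwear_total // 60)
    block_lengths = [nonwear_total - 60 * (k_blocks - 1)] + [60] * (k_blocks - 1)
    offsets = np.sort(rng.integers(0, len(labels) + 1, size=k_blocks))
    parts = []
    prev = 0
    for off, blen in zip(offsets, block_lengths):
        parts.append(labels[prev:off])
        parts.append(np.full(blen, _NONWEAR))
        prev = off
    parts.append(labels[prev:])
    return np.concatenate(parts)


_BAND_LOW = np.array([0, 100, 1952, 5725])
_BAND_HIGH = np.array([99, 1951, 5724, 9999])  # inclusive


def _emit_counts(labels: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Draw one CPM per minute, uniform within the minute's state band.

    Sedentary minutes are a mixture of exact zeros (p=0.6) and 1-99 CPM so the
    non-wear logic is exercised; scheduled non-wear is all-zero.
    """
    cpm = np.zeros(len(labels), dtype=np.int64)
    for state in range(4):
        mask = labels == state
        n = int(mask.sum())
        if not n:
            continue
        draws = rng.integers(_BAND_LOW[state], _BAND_HIGH[state] + 1, size=n)
        if state == 0:
            draws = np.where(rng.random(n) < 0.6, 0, rng.integers(1, 100, size=n))
        cpm[mask] = draws
    return cpm


def _enforce_unambiguous_nonwear(
    cpm: np.ndarray, labels: np.ndarray, rng: np.random.Generator, max_low_run: int = 45
) -> None:
    """Make detected non-wear coincide exactly with scheduled non-wear.

    In place: (a) the minute on each side of a scheduled block is swapped, if
    needed, with a nearby wear minute above 100 CPM, terminating any candidate
    window at the block edge; (b) zero-bounded runs of <=100 CPM wear minutes
    are capped at ``max_low_run`` minutes by the same swap, so no wear-time
    window can reach the 60-min rule.
    """
    nw = labels == _NONWEAR
    # breaker minutes placed here are protected so later swaps cannot steal them
    protected = np.zeros(len(cpm), dtype=bool)

    def swap_with_high(i: int) -> None:
        eligible = np.flatnonzero(~nw & ~protected & (cpm > 100))
        if len(eligible) == 0:
            raise ValueError(
                "not enough >100 CPM wear minutes to keep non-wear structure unambiguous"
            )
        j = int(eligible[np.argmin(np.abs(eligible - i))])
        cpm[i], cpm[j] = cpm[j], cpm[i]
        labels[i], labels[j] = labels[j], labels[i]
        protected[i] = True

    for _ in range(16):
        swapped = False
        # flank every scheduled block with a breaker minute
        for e in np.flatnonzero(np.diff(nw.astype(np.int8))):
            i = e if not nw[e] else e + 1  # the wear minute at the boundary
            if cpm[i] <= 100:
                swap_with_high(i)
                swapped = True
            protected[i] = True
        # cap low-count wear runs (rarely triggered; probabilistic runs are short)
        low = (cpm <= 100) & ~nw
        padded = np.r_[False, low, False].astype(np.int8)
        starts = np.flatnonzero(np.diff(padded) == 1)
        ends = np.flatnonzero(np.diff(padded) == -1)
        for ri in np.flatnonzero(ends - starts > max_low_run):
            for i in range(starts[ri] + max_low_run, ends[ri], max_low_run):
                swap_with_high(int(i))
                swapped = True
        if not swapped:
            return
    raise RuntimeError("could not make non-wear structure unambiguous")


def simulate_epoch_series(
    profile: TruthProfile, config: SimulationConfig
) -> tuple[EpochSeries, list[dict[str, int]]]:
    """Epoch count series for one participant's whole recording.

    Returns the series (at ``config.epoch_seconds``) and per-day ground-truth
    state minutes including scheduled non-wear.
    """
    rng = _participant_rng(config, profile.participant_id, 11)
    day_labels = [
        _day_state_labels(profile, config, d, rng) for d in range(config.n_days)
    ]
    labels = np.concatenate(day_labels)
    cpm = _emit_counts(labels, rng)
    _enforce_unambiguous_nonwear(cpm, labels, rng)

    truth: list[dict[str, int]] = []
    for d in range(config.n_days):
        counts = np.bincount(labels[d * 1440 : (d + 1) * 1440], minlength=5)
        truth.append(
            {**{s: int(counts[k]) for k, s in enumerate(STATES)}, "nonwear": int(counts[4])}
        )

    if config.epoch_seconds == 30:
        first = rng.integers(0, cpm + 1)
        counts_30 = np.empty(2 * len(cpm), dtype=np.int64)
        counts_30[0::2] = first
        counts_30[1::2] = cpm - first
        out_counts = counts_30
    else:
        out_counts = cpm
    series = EpochSeries(
        participant_id=profile.participant_id,
        start_timestamp=dt.datetime.combine(config.start_date, dt.time(0, 0)),
        epoch_seconds=config.epoch_seconds,
        counts=out_counts,
    )
    return series, truth


def _decompose_weekly(weekly_minutes: float) -> ActivityBlock:
    """Split biased weekly minutes into a plausible days/week x min/day item.

    Sessions target ~45 min; per GPAQ convention reported bouts are >= 10
    minutes, and totals below 10 min/week are dropped (engages = no).
    """
    if weekly_minutes < 10:
        return ActivityBlock(engages=False)
    days = int(np.clip(round(weekly_minutes / 45.0), 1, 7))
    minutes = weekly_minutes / days
    if minutes < 10:
        days = max(1, int(weekly_minutes // 10))
        minutes = weekly_minutes / days
    return ActivityBlock(engages=True, days_per_week=float(days), minutes_per_day=minutes)


def simulate_gpaq_response(
    profile: TruthProfile,
    version: str,
    week_truth: dict[str, float],
    config: SimulationConfig,
    administration_day: int = 7,
) -> GpaqResponse:
    """A biased, noisy self-report of one week's true activity.

    Reported vigorous minutes are truth x vigorous_report_factor x lognormal
    noise (mean-1, CV ``report_noise_cv``); moderate uses
    moderate_report_factor; sedentary gets noise only.  For the with-cards
    version ``showcard_effect`` shifts both report factors additively.
    """
    rng = _participant_rng(
        config, profile.participant_id, 23, 1 if version == "with_cards" else 2, administration_day
    )
    fv = config.vigorous_report_factor
    fm = config.moderate_report_factor
    if version == "with_cards":
        fv = max(fv + config.showcard_effect, 1e-9)
        fm = max(fm + config.showcard_effect, 1e-9)

    def noise() -> float:
        cv = config.report_noise_cv
        if cv == 0:
            return 1.0
        sigma = np.sqrt(np.log1p(cv**2))
        return float(rng.lognormal(-sigma**2 / 2.0, sigma))

    weekly_vig = week_truth["vigorous"] * fv * noise() * 7.0
    weekly_mod = week_truth["moderate"] * fm * noise() * 7.0
    sed_daily = week_truth["sedentary"] * noise()

    mod_domain = ("work_moderate", "transport", "leisure_moderate")[int(rng.integers(0, 3))]
    vig_domain = ("work_vigorous", "leisure_vigorous")[int(rng.integers(0, 2))]
    blocks = {b: ActivityBlock(engages=False) for b in
              ("work_vigorous", "work_moderate", "transport",
               "leisure_vigorous", "leisure_moderate")}
    blocks[vig_domain] = _decompose_weekly(weekly_vig)
    blocks[mod_domain] = _decompose_weekly(weekly_mod)
    return GpaqResponse(
        participant_id=profile.participant_id,
        version=version,
        administration_day=administration_day,
        sedentary_minutes_per_day=sed_daily,
        **blocks,
    )


def simulate_study(config: SimulationConfig) -> StudyData:
    """Generate the full crossover study: roster, epoch series, GPAQ responses.

    Each participant answers both questionnaire versions, one after each study
    week, in the order fixed by their crossover group; the report covers that
    week's true activity.
    """
    roster = generate_roster(config)
    epochs: dict[str, EpochSeries] = {}
    truth_days: dict[str, list[dict[str, int]]] = {}
    week_means: dict[str, dict[int, dict[str, float]]] = {}
    responses = []
    for profile in roster:
        series, truth = simulate_epoch_series(profile, config)
        epochs[profile.participant_id] = series
        truth_days[profile.participant_id] = truth
        wm: dict[int, dict[str, float]] = {}
        for wi in (1, 2):
            days = truth[(wi - 1) * 7 : wi * 7]
            if not days:
                continue
            wm[wi] = {s: float(np.mean([d[s] for d in days])) for s in STATES}
        week_means[profile.participant_id] = wm

        first_version = "with_cards" if profile.group == GROUP_PLUS_FIRST else "without_cards"
        second_version = "without_cards" if first_version == "with_cards" else "with_cards"
        for wi, version in ((1, first_version), (2, second_version)):
            if wi not in wm:
                continue
            responses.append(
                simulate_gpaq_response(profile, version, wm[wi], config,
                                       administration_day=7 * wi)
            )
    return StudyData(
        config=config,
        roster=roster,
        epochs=epochs,
        responses=responses,
        truth_day_minutes=truth_days,
        truth_week_means=week_means,
    )


def write_study(data: StudyData, out_dir: str | Path) -> dict[str, str]:
    """Write roster CSV, per-participant epoch CSVs, GPAQ CSV and truth JSON."""
    out = Path(out_dir)
    (out / "epochs").mkdir(parents=True, exist_ok=True)
    roster_lines = ["participant_id,sex,age,bmi,group"]
    for p in data.roster:
        roster_lines.append(
            f"{p.participant_id},{p.sex},{p.age:.6f},{p.bmi:.6f},{p.group}"
        )
    (out / "roster.csv").write_text("\n".join(roster_lines) + "\n")
    for pid, series in data.epochs.items():
        write_epochs(series, out / "epochs" / f"{pid}.csv")
    write_responses_csv(data.responses, out / "gpaq_responses.csv")
    truth = {
        "config": {**asdict(data.config), "start_date": data.config.start_date.isoformat()},
        "day_minutes": data.truth_day_minutes,
        "week_means": {
            pid: {str(k): v for k, v in wm.items()} for pid, wm in data.truth_week_means.items()
        },
        "dropout_week": {p.participant_id: p.dropout_week for p in data.roster},
    }
    (out / "ground_truth.json").write_text(json.dumps(truth, indent=1, sort_keys=True))
    return {
        "roster": str(out / "roster.csv"),
        "epochs": str(out / "epochs"),
        "responses": str(out / "gpaq_responses.csv"),
        "truth": str(out / "ground_truth.json"),
    }
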