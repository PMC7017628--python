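"""End-to-end crossover study analysis.

Pairs each questionnaire administration with its own week's accelerometer
summary via the crossover schedule, applies participant-level exclusion
(accelerometer validity in both weeks, clean questionnaires for both
versions), and produces the full report: sample description with baseline
tests, per-version validity comparisons, version-error comparison, rank
correlations with interpretation bands, Bland-Altman statistics, and a
CONSORT-style exclusion log.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import hashlib
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np

from . import agreement
from .accel import (
    CutPoints,
    FREEDSON_ADULT,
    NonwearParams,
    EpochSeries,
    WeekSummary,
    load_epochs,
    process_series,
)
from .agreement import (
    DegenerateDataError,
    PairedSample,
    baseline_tests,
    bland_altman,
    compare_version_errors,
    mean_difference,
    spearman,
    wilcoxon_signed_rank,
)
from .gpaq import CleaningRules, GpaqResponse, GpaqSummary, clean_response, score_response

__all__ = [
    "Participant",
    "AnalysisParams",
    "CrossoverSchedule",
    "StudyReport",
    "run_study",
    "make_report",
]

OUTCOMES = ("moderate", "vigorous", "sedentary")
VERSIONS = ("with_cards", "without_cards")

_WEEK_ATTR = {
    "moderate": "moderate_min_per_day",
    "vigorous": "vigorous_min_per_day",
    "sedentary": "sedentary_min_per_day",
}
_GPAQ_ATTR = _WEEK_ATTR


@dataclass
class Participant:
    participant_id: str
    sex: str
    age: float
    bmi: float
    group: str


@dataclass(frozen=True)
class CrossoverSchedule:
    """Which questionnaire version each group answers after each week."""

    schedule: dict = field(
        default_factory=lambda: {
            "with_cards_first": {1: "with_cards", 2: "without_cards"},
            "without_cards_first": {1: "without_cards", 2: "with_cards"},
        }
    )

    def __post_init__(self) -> None:
        for group, weeks in self.schedule.items():
            if set(weeks) != {1, 2} or set(weeks.values()) != set(VERSIONS):
                raise ValueError(
                    f"group {group!r} must get each version exactly once across the two weeks"
                )

    def week_of(self, group: str, version: str) -> int:
        weeks = self.schedule[group]
        for week, v in weeks.items():
            if v == version:
                return week
        raise KeyError(version)


@dataclass(frozen=True)
class AnalysisParams:
    cuts: CutPoints = FREEDSON_ADULT
    nonwear: NonwearParams = NonwearParams()
    min_wear_minutes: int = 600
    min_valid_days: int = 3
    cleaning: CleaningRules = CleaningRules()
    alpha: float = 0.05
    ba_abscissa: str = "accelerometer"
    schedule: CrossoverSchedule = field(default_factory=CrossoverSchedule)


@dataclass
class StudyReport:
    """Complete analysis output; all tables as plain dict rows for easy I/O."""

    recruited_n: int
    analyzed_n: int
    exclusions: list[dict]  # {participant_id, reason}
    exclusion_counts: dict[str, int]
    sample_table: list[dict]
    baseline: list[dict]
    validity_table: list[dict]  # per version x outcome: means, SDs, paired p
    version_comparison: list[dict]  # per outcome: error means/SDs, paired p
    correlations: list[dict]
    bland_altman_stats: list[dict]
    bland_altman_points: dict[str, list[dict]]  # "outcome/version" -> coordinates
    analyzed_ids: list[str]
    params: dict

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), sort_keys=True, indent=1, **kwargs)

    @classmethod
    def from_json(cls, text: str) -> "StudyReport":
        return cls(**json.loads(text))


def _round(x: float, nd: int = 6) -> float:
    if x is None or (isinstance(x, float) and math.isnan(x)):
        return float("nan")
    return round(float(x), nd)


def _summaries_by_participant(
    epochs: dict[str, EpochSeries], params: AnalysisParams
) -> dict[str, dict[int, WeekSummary]]:
    out: dict[str, dict[int, WeekSummary]] = {}
    for pid, series in epochs.items():
        _, weeks = process_series(
            series,
            cuts=params.cuts,
            nonwear=params.nonwear,
            min_wear_minutes=params.min_wear_minutes,
            min_valid_days=params.min_valid_days,
        )
        out[pid] = {w.week_index: w for w in weeks}
    return out


def run_study(
    roster: list[Participant],
    epochs: dict[str, EpochSeries],
    responses: list[GpaqResponse],
    params: AnalysisParams = AnalysisParams(),
) -> StudyReport:
    """Run the full crossover analysis.

    Exclusion is participant-level: anyone lacking a usable accelerometer week
    (>= ``min_valid_days`` valid days of >= 10 h wear) in either week, or a
    clean questionnaire for either version, is dropped from all analyses with
    a logged reason; recruited = analyzed + excluded always holds.
    """
    roster = [
        p if isinstance(p, Participant) else Participant(
            p.participant_id, p.sex, p.age, p.bmi, p.group
        )
        for p in roster
    ]
    week_summaries = _summaries_by_participant(epochs, params)
    scored: dict[tuple[str, str], GpaqSummary] = {}
    for r in responses:
        scored[(r.participant_id, r.version)] = score_response(r, params.cleaning)

    exclusions: list[dict] = []
    analyzed: list[Participant] = []
    for p in roster:
        reasons = []
        weeks = week_summaries.get(p.participant_id, {})
        for wi in (1, 2):
            if wi not in weeks:
                reasons.append(f"no accelerometer data for week {wi}")
            elif not weeks[wi].usable:
                reasons.append(
                    f"insufficient valid accelerometer days in week {wi} "
                    f"({weeks[wi].n_valid_days} < {params.min_valid_days})"
                )
        for version in VERSIONS:
            s = scored.get((p.participant_id, version))
            if s is None:
                reasons.append(f"missing GPAQ response ({version})")
            elif not s.clean:
                reasons.append(f"unclean GPAQ response ({version}): " + "; ".join(s.exclusion_reasons))
        if reasons:
            exclusions.append({"participant_id": p.participant_id, "reason": "; ".join(reasons)})
        else:
            analyzed.append(p)
    if not analyzed:
        raise ValueError("no participant survives exclusion")

    # paired samples per outcome x version, each questionnaire against its own week
    samples: dict[tuple[str, str], PairedSample] = {}
    for version in VERSIONS:
        for outcome in OUTCOMES:
            ids, qv, av = [], [], []
            for p in analyzed:
                week = params.schedule.week_of(p.group, version)
                q = getattr(scored[(p.participant_id, version)], _GPAQ_ATTR[outcome])
                a = getattr(week_summaries[p.participant_id][week], _WEEK_ATTR[outcome])
                ids.append(p.participant_id)
                qv.append(q)
                av.append(a)
            samples[(outcome, version)] = PairedSample(
                outcome=outcome, version=version, participant_ids=ids,
                questionnaire=np.array(qv), accelerometer=np.array(av),
            )

    def _safe_wilcoxon(x, y) -> tuple[float, float]:
        try:
            res = wilcoxon_signed_rank(x, y)
            return res.statistic, res.p_value
        except DegenerateDataError:
            return float("nan"), float("nan")

    validity_rows = []
    for version in VERSIONS:
        for outcome in OUTCOMES:
            s = samples[(outcome, version)]
            stat, p = _safe_wilcoxon(s.questionnaire, s.accelerometer)
            validity_rows.append({
                "version": version,
                "outcome": outcome,
                "n": len(s),
                "gpaq_mean": _round(np.mean(s.questionnaire)),
                "gpaq_sd": _round(np.std(s.questionnaire, ddof=1)),
                "accel_mean": _round(np.mean(s.accelerometer)),
                "accel_sd": _round(np.std(s.accelerometer, ddof=1)),
                "wilcoxon_p": _round(p, 8),
            })

    comparison_rows = []
    for outcome in OUTCOMES:
        s_plus = samples[(outcome, "with_cards")]
        s_minus = samples[(outcome, "without_cards")]
        bias_p, sd_p = mean_difference(s_plus)
        bias_m, sd_m = mean_difference(s_minus)
        try:
            res = compare_version_errors(s_plus, s_minus)
            stat, p = res.statistic, res.p_value
        except DegenerateDataError:
            stat, p = float("nan"), float("nan")
        comparison_rows.append({
            "outcome": outcome,
            "n": len(s_plus),
            "with_cards_bias": _round(bias_p),
            "with_cards_sd": _round(sd_p),
            "without_cards_bias": _round(bias_m),
            "without_cards_sd": _round(sd_m),
            "wilcoxon_p": _round(p, 8),
        })

    correlation_rows = []
    ba_rows = []
    ba_points: dict[str, list[dict]] = {}
    for version in VERSIONS:
        for outcome in OUTCOMES:
            s = samples[(outcome, version)]
            try:
                c = spearman(s)
                correlation_rows.append({
                    "version": version, "outcome": outcome, "n": c.n,
                    "rho": _round(c.rho), "p": _round(c.p_value, 8), "band": c.band,
                })
            except (DegenerateDataError, agreement.InsufficientDataError):
                correlation_rows.append({
                    "version": version, "outcome": outcome, "n": len(s),
                    "rho": float("nan"), "p": float("nan"), "band": "undefined",
                })
            ba = bland_altman(s, abscissa=params.ba_abscissa)
            ba_rows.append({
                "version": version, "outcome": outcome, "n": ba.n,
                "bias": _round(ba.bias), "sd_diff": _round(ba.sd_diff),
                "loa_lower": _round(ba.loa_lower), "loa_upper": _round(ba.loa_upper),
                "abscissa": ba.abscissa,
            })
            ba_points[f"{outcome}/{version}"] = [
                {"participant_id": pid, "x": _round(x), "y": _round(y)}
                for pid, x, y in zip(s.participant_ids, ba.x, ba.y)
            ]

    # sample description and baseline homogeneity on the analyzed sample
    groups = sorted({p.group for p in analyzed})
    sample_rows = []
    for label, members in [("total", analyzed)] + [
        (g, [p for p in analyzed if p.group == g]) for g in groups
    ]:
        ages = [p.age for p in members]
        bmis = [p.bmi for p in members]
        n_female = sum(p.sex == "female" for p in members)
        sample_rows.append({
            "group": label,
            "n": len(members),
            "female_n": n_female,
            "female_pct": _round(100.0 * n_female / len(members), 1),
            "age_mean": _round(np.mean(ages), 1),
            "age_sd": _round(np.std(ages, ddof=1), 1) if len(members) > 1 else float("nan"),
            "bmi_mean": _round(np.mean(bmis), 1),
            "bmi_sd": _round(np.std(bmis, ddof=1), 1) if len(members) > 1 else float("nan"),
        })
    baseline_rows = []
    if len(groups) == 2 and all(
        sum(p.group == g for p in analyzed) >= 2 for g in groups
    ):
        tests = baseline_tests(
            [p.sex for p in analyzed],
            [p.group for p in analyzed],
            {"age": [p.age for p in analyzed], "bmi": [p.bmi for p in analyzed]},
        )
        baseline_rows = [
            {"test": t.method, "statistic": _round(t.statistic),
             "p": _round(t.p_value, 8), "n": t.n_used}
            for t in tests
        ]

    reason_counts: dict[str, int] = {}
    for e in exclusions:
        key = e["reason"].split(";")[0].strip()
        reason_counts[key] = reason_counts.get(key, 0) + 1

    return StudyReport(
        recruited_n=len(roster),
        analyzed_n=len(analyzed),
        exclusions=exclusions,
        exclusion_counts=reason_counts,
        sample_table=sample_rows,
        baseline=baseline_rows,
        validity_table=validity_rows,
        version_comparison=comparison_rows,
        correlations=correlation_rows,
        bland_altman_stats=ba_rows,
        bland_altman_points=ba_points,
        analyzed_ids=[p.participant_id for p in analyzed],
        params={
            "min_wear_minutes": params.min_wear_minutes,
            "min_valid_days": params.min_valid_days,
            "alpha": params.alpha,
            "ba_abscissa": params.ba_abscissa,
            "cut_points": dataclasses.asdict(params.cuts),
            "nonwear": dataclasses.asdict(params.nonwear),
        },
    )


# ---------------------------------------------------------------------------
# Report rendering
# ---------------------------------------------------------------------------

def _write_csv(path: Path, rows: list[dict]) -> None:
    if not rows:
        path.write_text("")
        return
    cols = list(rows[0].keys())
    lines = [",".join(cols)]
    for row in rows:
        cells = []
        for c in cols:
            v = row[c]
            if isinstance(v, float):
                cells.append("" if math.isnan(v) else f"{v:g}")
            else:
                cells.append(str(v))
        lines.append(",".join(cells))
    path.write_text("\n".join(lines) + "\n")


def make_report(report: StudyReport, out_dir: str | Path, figures: bool = False) -> dict[str, str]:
    """Write the report as CSV tables + JSON, with a checksum manifest.

    Bland-Altman data are emitted as coordinate tables (one CSV per
    outcome-version pair, with bias and limits of agreement in the stats
    table); ``figures=True`` additionally renders PNG plots.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    files: dict[str, str] = {}

    def emit_csv(name: str, rows: list[dict]) -> None:
        _write_csv(out / name, rows)
        files[name] = str(out / name)

    emit_csv("table1_sample.csv", report.sample_table)
    emit_csv("baseline_tests.csv", report.baseline)
    emit_csv("table2_validity.csv", report.validity_table)
    emit_csv("table3_version_differences.csv", report.version_comparison)
    emit_csv("correlations.csv", report.correlations)
    emit_csv("bland_altman_stats.csv", report.bland_altman_stats)
    for key, points in report.bland_altman_points.items():
        name = "bland_altman_" + key.replace("/", "_") + ".csv"
        emit_csv(name, points)
    (out / "exclusions.jsonl").write_text(
        "\n".join(json.dumps(e, sort_keys=True) for e in report.exclusions) + "\n"
        if report.exclusions else ""
    )
    files["exclusions.jsonl"] = str(out / "exclusions.jsonl")
    (out / "report.json").write_text(report.to_json())
    files["report.json"] = str(out / "report.json")

    if figures:
        _render_figures(report, out, files)

    manifest = {
        name: hashlib.sha256(Path(p).read_bytes()).hexdigest() for name, p in files.items()
    }
    (out / "manifest.json").write_text(json.dumps(manifest, sort_keys=True, indent=1))
    files["manifest.json"] = str(out / "manifest.json")
    return files


def _render_figures(report: StudyReport, out: Path, files: dict[str, str]) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    stats_by_key = {
        f"{r['outcome']}/{r['version']}": r for r in report.bland_altman_stats
    }
    for key, points in report.bland_altman_points.items():
        st = stats_by_key[key]
        fig, ax = plt.subplots(figsize=(5, 4))
        ax.scatter([p["x"] for p in points], [p["y"] for p in points], s=18, alpha=0.8)
        for yv, style in ((st["bias"], "-"), (st["loa_lower"], "--"), (st["loa_upper"], "--")):
            ax.axhline(yv, linestyle=style, color="grey")
        ax.set_xlabel(
            "accelerometer (min/day)" if st["abscissa"] == "accelerometer"
            else "mean of methods (min/day)"
        )
        ax.set_ylabel("questionnaire - accelerometer (min/day)")
        ax.set_title(key)
        name = "bland_altman_" + key.replace("/", "_") + ".png"
        fig.tight_layout()
        fig.savefig(out / name, dpi=100)
        plt.close(fig)
        files[name] = str(out / name)
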