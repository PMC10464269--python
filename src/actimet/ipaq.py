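"""IPAQ short-form scoring.

Scores International Physical Activity Questionnaire (short form) responses
— days/week and minutes/day of walking, moderate PA (MPA) and vigorous PA
(VPA), plus daily sitting minutes — into weekly and daily MET minutes,
applies the protocol's validity rules, and classifies overall activity as
low / moderate / high.

MET values (IPAQ scoring protocol): walking 3.3, MPA 4.0, VPA 8.0.

Validity: a response is invalid if sitting + walking + MPA + VPA minutes/day
exceed 1440, or walking + MPA + VPA minutes/day exceed 960. Responses with
missing category fields are ``incomplete``; a partial-inclusion mode scores
them from the categories that are present.

Levels (evaluated high -> moderate -> low):

* high — (1) >= 3 days of VPA and >= 1500 total MET min/week, or
  (2) >= 7 days of any combination of walking/MPA/VPA and >= 3000 total
  MET min/week;
* moderate — (1) >= 3 days of VPA of >= 20 min/day, or (2) >= 5 days of MPA
  and/or walking of >= 30 min/day, or (3) >= 5 days of any combination and
  >= 600 total MET min/week;
* low — anything else.

The number of "days of any combination" sums the per-category day counts,
capped at 7 (one week) since a calendar week cannot hold more.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import pandas as pd

__all__ = [
    "MET_VALUES",
    "IPAQ_CATEGORIES",
    "IPAQResponse",
    "IPAQScore",
    "Validity",
    "Level",
    "validate_response",
    "score_met_minutes",
    "classify_level",
    "score_response",
    "score_table",
]

IPAQ_CATEGORIES = ("walking", "mpa", "vpa")
MET_VALUES = {"walking": 3.3, "mpa": 4.0, "vpa": 8.0}

MAX_TOTAL_MINUTES = 1440.0  # sitting + walking + MPA + VPA per day
MAX_ACTIVE_MINUTES = 960.0  # walking + MPA + VPA per day


class Validity(str, Enum):
    VALID = "valid"
    INVALID = "invalid"
    INCOMPLETE = "incomplete"


class Level(str, Enum):
    LOW = "low"
    MODERATE = "moderate"
    HIGH = "high"


@dataclass(frozen=True)
class IPAQResponse:
    """One short-form administration.

    ``days_*`` in 0–7; ``minutes_*`` are minutes/day on active days and may
    be ``None`` (missing). ``administration`` tags the occasion (e.g.
    ``"examination"`` or ``"post_monitoring"``).
    """

    participant_id: str
    days_walking: int | None
    minutes_walking: float | None
    days_mpa: int | None
    minutes_mpa: float | None
    days_vpa: int | None
    minutes_vpa: float | None
    sitting_minutes: float | None = None
    administration: str = "examination"

    def __post_init__(self) -> None:
        for cat in IPAQ_CATEGORIES:
            d = getattr(self, f"days_{cat}")
            m = getattr(self, f"minutes_{cat}")
            if d is not None and not (0 <= d <= 7):
                raise ValueError(f"days_{cat} must be in 0..7, got {d}")
            if m is not None and m < 0:
                raise ValueError(f"minutes_{cat} must be non-negative, got {m}")
        if self.sitting_minutes is not None and self.sitting_minutes < 0:
            raise ValueError("sitting_minutes must be non-negative")

    def category(self, cat: str) -> tuple[int | None, float | None]:
        return getattr(self, f"days_{cat}"), getattr(self, f"minutes_{cat}")

    def is_complete(self) -> bool:
        for cat in IPAQ_CATEGORIES:
            d, m = self.category(cat)
            if d is None or (d > 0 and m is None):
                return False
        return True


@dataclass
class IPAQScore:
    participant_id: str
    weekly_met: dict[str, float]
    total_weekly_met: float
    daily_met: dict[str, float]
    validity: Validity
    level: Level | None
    administration: str = "examination"

    def to_record(self) -> dict:
        rec = {
            "participant_id": self.participant_id,
            "administration": self.administration,
            "validity": self.validity.value,
            "level": self.level.value if self.level is not None else "",
            "total_weekly_met": self.total_weekly_met,
        }
        for cat in IPAQ_CATEGORIES:
            rec[f"weekly_met_{cat}"] = self.weekly_met.get(cat, float("nan"))
            rec[f"daily_met_{cat}"] = self.daily_met.get(cat, float("nan"))
        return rec


def _minutes_per_day(r: IPAQResponse, cat: str) -> float:
    """Minutes/day for the validity sums; missing or zero-day fields count 0."""
    d, m = r.category(cat)
    if m is None or d == 0:
        return 0.0
    return float(m)


def validate_response(r: IPAQResponse) -> Validity:
    """Apply the protocol's plausibility rules, then completeness."""
    active = sum(_minutes_per_day(r, c) for c in IPAQ_CATEGORIES)
    sitting = float(r.sitting_minutes or 0.0)
    if sitting + active > MAX_TOTAL_MINUTES or active > MAX_ACTIVE_MINUTES:
        return Validity.INVALID
    if not r.is_complete():
        return Validity.INCOMPLETE
    return Validity.VALID


def score_met_minutes(r: IPAQResponse, partial: bool = False) -> IPAQScore:
    """Weekly and daily MET minutes per category.

    weekly MET minutes = MET x days/week x minutes/day; daily = weekly / 7
    (the instrument natively yields weekly volumes). ``partial`` scores
    incomplete responses from the categories that are present.

    Raises
    ------
    ValueError
        For invalid responses (excluded, not truncated) and — unless
        ``partial`` — for incomplete ones.
    """
    validity = validate_response(r)
    if validity is Validity.INVALID:
        raise ValueError(
            f"response for {r.participant_id!r} fails the IPAQ plausibility rules "
            f"(> {MAX_ACTIVE_MINUTES:.0f} active or > {MAX_TOTAL_MINUTES:.0f} total minutes/day)"
        )
    if validity is Validity.INCOMPLETE and not partial:
        raise ValueError(
            f"response for {r.participant_id!r} is incomplete; "
            "use partial=True to score the available categories"
        )
    weekly: dict[str, float] = {}
    for cat in IPAQ_CATEGORIES:
        d, m = r.category(cat)
        if d is None or (d > 0 and m is None):
            weekly[cat] = float("nan") if not partial else 0.0
        else:
            weekly[cat] = MET_VALUES[cat] * float(d) * float(m or 0.0)
    total = float(sum(v for v in weekly.values() if v == v))
    score = IPAQScore(
        participant_id=r.participant_id,
        weekly_met=weekly,
        total_weekly_met=total,
        daily_met={c: v / 7.0 for c, v in weekly.items()},
        validity=validity,
        level=None,
        administration=r.administration,
    )
    return score


def classify_level(score: IPAQScore, r: IPAQResponse, day_cap: int = 7) -> Level:
    """Low / moderate / high classification per the scoring-protocol criteria.

    ``day_cap`` caps the summed "days of any combination" at one week.
    """
    if score.validity is Validity.INVALID:
        raise ValueError("cannot classify an invalid response")
    days = {c: int(r.category(c)[0] or 0) for c in IPAQ_CATEGORIES}
    mins = {c: float(r.category(c)[1] or 0.0) for c in IPAQ_CATEGORIES}
    total = score.total_weekly_met
    combo_days = min(sum(days.values()), day_cap)

    if days["vpa"] >= 3 and total >= 1500:
        return Level.HIGH
    if combo_days >= 7 and total >= 3000:
        return Level.HIGH

    if days["vpa"] >= 3 and mins["vpa"] >= 20:
        return Level.MODERATE
    mod_walk_days = (days["mpa"] if mins["mpa"] >= 30 else 0) + (
        days["walking"] if mins["walking"] >= 30 else 0
    )
    if mod_walk_days >= 5:
        return Level.MODERATE
    if combo_days >= 5 and total >= 600:
        return Level.MODERATE
    return Level.LOW


def score_response(r: IPAQResponse, partial: bool = False) -> IPAQScore:
    """Validate, score and classify one response in a single call."""
    score = score_met_minutes(r, partial=partial)
    score.level = classify_level(score, r)
    return score


# ---------------------------------------------------------------------------
# Table interface
# ---------------------------------------------------------------------------

_COLUMNS = [
    "participant_id",
    "administration",
    "days_walking",
    "minutes_walking",
    "days_mpa",
    "minutes_mpa",
    "days_vpa",
    "minutes_vpa",
    "sitting_minutes",
]


def _opt(v, as_int=False):
    if v is None or (isinstance(v, float) and v != v) or (isinstance(v, str) and v == ""):
        return None
    return int(v) if as_int else float(v)


def response_from_row(row: pd.Series) -> IPAQResponse:
    return IPAQResponse(
        participant_id=str(row["participant_id"]),
        days_walking=_opt(row.get("days_walking"), as_int=True),
        minutes_walking=_opt(row.get("minutes_walking")),
        days_mpa=_opt(row.get("days_mpa"), as_int=True),
        minutes_mpa=_opt(row.get("minutes_mpa")),
        days_vpa=_opt(row.get("days_vpa"), as_int=True),
        minutes_vpa=_opt(row.get("minutes_vpa")),
        sitting_minutes=_opt(row.get("sitting_minutes")),
        administration=str(row.get("administration", "examination")),
    )


def score_table(responses: pd.DataFrame, partial: bool = False) -> pd.DataFrame:
    """Score a response table; invalid/unscorable rows are kept with their
    validity tag and NaN scores (excluded from analysis, not truncated)."""
    records = []
    for _, row in responses.iterrows():
        r = response_from_row(row)
        validity = validate_response(r)
        if validity is Validity.INVALID or (validity is Validity.INCOMPLETE and not partial):
            records.append(
                {
                    "participant_id": r.participant_id,
                    "administration": r.administration,
                    "validity": validity.value,
                    "level": "",
                    "total_weekly_met": float("nan"),
                    **{f"weekly_met_{c}": float("nan") for c in IPAQ_CATEGORIES},
                    **{f"daily_met_{c}": float("nan") for c in IPAQ_CATEGORIES},
                }
            )
            continue
        records.append(score_response(r, partial=partial).to_record())
    return pd.DataFrame.from_records(records)
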