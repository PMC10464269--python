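"""Accelerometer epoch post-processing and MET-minute summaries.

Turns streams of 5-second posture/activity labels (the output granularity of
thigh/back accelerometer classifiers) into valid monitoring days, daily and
weekly minutes and MET minutes per activity and activity category, and a
guideline-compliance flag.

Processing chain
----------------
1. :func:`majority_vote_minutes` — per-minute majority vote over the 12
   five-second epochs of each clock minute (noise removal).
2. :func:`trim_first_last_day` — the first and last calendar day of
   monitoring are discarded (attachment/return days are unrepresentative).
3. :func:`daily_minutes` — per-day label minute totals (each complete day
   sums to 1440 minutes, non-wear included).
4. :func:`apply_nonwear_exclusion` — from the first day with more than 60
   minutes of non-wear, that day and all later days are dropped.
5. :func:`check_inclusion` — a participant needs at least one valid weekday
   and one valid weekend day (or, under the strict rule, three weekdays and
   one weekend day).
6. :func:`summarize_participant` — daily-average minutes and MET minutes per
   label and per category, weekly values (7 x daily), guideline compliance.

Activity categories
-------------------
sedentary       = lying + sitting
on_feet         = standing + walking + running + cycling
on_the_move     = walking + running + cycling
running_cycling = running + cycling

Guideline compliance uses the MET-minute equivalent of the WHO adult
recommendation (150 min/week moderate PA at 4.0 MET, or 75 min/week vigorous
PA at 8.0 MET, both 600 MET minutes/week): a daily average of at least
600/7 = 85.7 MET minutes of running/cycling.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "ACTIVITY_LABELS",
    "NONWEAR",
    "ALL_LABELS",
    "CATEGORY_MEMBERS",
    "WHO_WEEKLY_MET_TARGET",
    "who_daily_threshold",
    "METTable",
    "EpochStream",
    "MinuteSeries",
    "RaggedMinuteError",
    "majority_vote_minutes",
    "trim_first_last_day",
    "daily_minutes",
    "apply_nonwear_exclusion",
    "check_inclusion",
    "InclusionDecision",
    "ParticipantPASummary",
    "summarize_participant",
    "who_compliance",
    "process_stream",
]

ACTIVITY_LABELS: tuple[str, ...] = ("lying", "sitting", "standing", "walking", "running", "cycling")
NONWEAR = "nonwear"
ALL_LABELS: tuple[str, ...] = ACTIVITY_LABELS + (NONWEAR,)
_CODE = {lab: i for i, lab in enumerate(ALL_LABELS)}
NONWEAR_CODE = _CODE[NONWEAR]

EPOCH_SECONDS = 5
EPOCHS_PER_MINUTE = 12
MINUTES_PER_DAY = 1440
EPOCHS_PER_DAY = MINUTES_PER_DAY * EPOCHS_PER_MINUTE  # 17280

CATEGORY_MEMBERS: dict[str, tuple[str, ...]] = {
    "sedentary": ("lying", "sitting"),
    "on_feet": ("standing", "walking", "running", "cycling"),
    "on_the_move": ("walking", "running", "cycling"),
    "running_cycling": ("running", "cycling"),
}

#: MET-minute equivalent of the WHO weekly adult PA recommendation.
WHO_WEEKLY_MET_TARGET = 600.0

#: Non-wear minutes strictly above this trigger exclusion of the day onward.
NONWEAR_EXCLUSION_MINUTES = 60.0


def who_daily_threshold(weekly_target: float = WHO_WEEKLY_MET_TARGET) -> float:
    """Daily MET-minute threshold equivalent to the weekly guideline target."""
    return weekly_target / 7.0


# ---------------------------------------------------------------------------
# MET table
# ---------------------------------------------------------------------------

_DEFAULT_METS = {
    "lying": 1.0,
    "sitting": 1.3,
    "standing": 1.8,
    "walking": 2.8,
    "running": 7.0,
    "cycling": 4.0,
}

#: Walking MET from the IPAQ scoring protocol (self-report walking is bouts
#: of >= 10 min, which are brisker than all-day incidental walking).
IPAQ_WALKING_MET = 3.3


@dataclass(frozen=True)
class METTable:
    """MET value per activity label.

    Defaults follow compendium-based estimates for device-classified
    postures and activities: lying 1.0, sitting 1.3, standing 1.8,
    walking 2.8, running 7.0, cycling 4.0. ``default(walking_met=3.3)``
    selects the IPAQ-protocol walking value as a sensitivity variant.
    """

    values: dict[str, float] = field(default_factory=lambda: dict(_DEFAULT_METS))

    def __post_init__(self) -> None:
        missing = set(ACTIVITY_LABELS) - set(self.values)
        if missing:
            raise ValueError(f"MET table missing labels: {sorted(missing)}")
        bad = {k: v for k, v in self.values.items() if not v > 0}
        if bad:
            raise ValueError(f"MET values must be positive: {bad}")

    @classmethod
    def default(cls, walking_met: float | None = None) -> "METTable":
        vals = dict(_DEFAULT_METS)
        if walking_met is not None:
            vals["walking"] = float(walking_met)
        return cls(vals)

    def __getitem__(self, label: str) -> float:
        return self.values[label]


# ---------------------------------------------------------------------------
# Epoch and minute series
# ---------------------------------------------------------------------------


class RaggedMinuteError(ValueError):
    """An epoch series does not divide into whole 12-epoch clock minutes."""


def _check_codes(codes: np.ndarray) -> np.ndarray:
    codes = np.asarray(codes, dtype=np.int8)
    if codes.ndim != 1:
        raise ValueError("label codes must be one-dimensional")
    if codes.size and (codes.min() < 0 or codes.max() >= len(ALL_LABELS)):
        raise ValueError("label codes out of range")
    return codes


@dataclass
class EpochStream:
    """One participant's ordered 5-second label epochs.

    ``start`` is the timestamp of the first epoch; subsequent epochs follow
    at a constant 5-second spacing (the series therefore needs no per-epoch
    timestamp storage). ``codes`` indexes into :data:`ALL_LABELS`.
    """

    participant_id: str
    start: pd.Timestamp
    codes: np.ndarray

    def __post_init__(self) -> None:
        self.start = pd.Timestamp(self.start)
        self.codes = _check_codes(self.codes)

    @property
    def n_epochs(self) -> int:
        return int(self.codes.size)

    def labels(self) -> np.ndarray:
        return np.asarray(ALL_LABELS, dtype=object)[self.codes]

    def timestamps(self) -> pd.DatetimeIndex:
        return self.start + pd.to_timedelta(np.arange(self.n_epochs) * EPOCH_SECONDS, unit="s")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "participant_id": self.participant_id,
                "timestamp": self.timestamps(),
                "label": pd.Categorical.from_codes(self.codes, categories=list(ALL_LABELS)),
            }
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "EpochStream":
        """Build a stream from a (participant_id, timestamp, label) table.

        Validates the closed label set and the strict 5-second spacing.
        """
        pid = frame["participant_id"].iloc[0]
        ts = pd.to_datetime(frame["timestamp"])
        deltas = ts.diff().dropna().dt.total_seconds()
        if len(deltas) and not np.all(deltas == EPOCH_SECONDS):
            bad = int(np.flatnonzero(deltas.to_numpy() != EPOCH_SECONDS)[0])
            raise ValueError(f"epoch spacing is not a constant 5 s (first break after row {bad})")
        labels = frame["label"].astype(str)
        unknown = set(labels.unique()) - set(ALL_LABELS)
        if unknown:
            raise ValueError(f"unknown activity labels: {sorted(unknown)}")
        codes = labels.map(_CODE).to_numpy(dtype=np.int8)
        return cls(participant_id=str(pid), start=ts.iloc[0], codes=codes)


@dataclass
class MinuteSeries:
    """One participant's per-minute labels after majority voting."""

    participant_id: str
    start: pd.Timestamp
    codes: np.ndarray

    def __post_init__(self) -> None:
        self.start = pd.Timestamp(self.start)
        self.codes = _check_codes(self.codes)

    @property
    def n_minutes(self) -> int:
        return int(self.codes.size)

    def minute_times(self) -> np.ndarray:
        t0 = np.datetime64(self.start, "s")
        return t0 + np.arange(self.n_minutes) * np.timedelta64(60, "s")

    def dates(self) -> np.ndarray:
        return self.minute_times().astype("datetime64[D]")

    def to_frame(self) -> pd.DataFrame:
        times = self.minute_times()
        return pd.DataFrame(
            {
                "participant_id": self.participant_id,
                "date": times.astype("datetime64[D]"),
                "minute_of_day": ((times - times.astype("datetime64[D]")) / np.timedelta64(60, "s")).astype(int),
                "label": pd.Categorical.from_codes(self.codes, categories=list(ALL_LABELS)),
            }
        )


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------


def majority_vote_minutes(stream: EpochStream) -> MinuteSeries:
    """Collapse 5-s epochs to one label per clock minute by majority vote.

    Each minute takes the most frequent label among its 12 epochs (non-wear
    competes like any other label). Ties are broken by the label of the
    earliest epoch in the minute that belongs to a tied label — a
    deterministic, data-driven rule with no a-priori label priority.

    Raises
    ------
    RaggedMinuteError
        If the stream does not start on a clock-minute boundary or its
        length is not a whole number of 12-epoch minutes.
    """
    start = stream.start
    if start.second != 0 or start.microsecond or start.nanosecond:
        raise RaggedMinuteError(
            f"stream for {stream.participant_id!r} starts at {start}, not on a minute boundary"
        )
    n = stream.n_epochs
    if n % EPOCHS_PER_MINUTE != 0:
        raise RaggedMinuteError(
            f"stream for {stream.participant_id!r} has {n} epochs; the trailing minute "
            f"starting at minute index {n // EPOCHS_PER_MINUTE} has only {n % EPOCHS_PER_MINUTE} epochs"
        )
    mat = stream.codes.reshape(-1, EPOCHS_PER_MINUTE)
    n_min = mat.shape[0]
    counts = np.empty((n_min, len(ALL_LABELS)), dtype=np.int8)
    for k in range(len(ALL_LABELS)):
        counts[:, k] = (mat == k).sum(axis=1)
    max_count = counts.max(axis=1)
    # count of each epoch's own label within its minute
    own = np.take_along_axis(counts, mat.astype(np.intp), axis=1)
    is_tied_winner = own == max_count[:, None]
    first = is_tied_winner.argmax(axis=1)
    winners = mat[np.arange(n_min), first]
    return MinuteSeries(stream.participant_id, start, winners)


def trim_first_last_day(minutes: MinuteSeries) -> MinuteSeries:
    """Drop all minutes on the first and last calendar date of monitoring.

    With fewer than three distinct dates nothing can remain; an empty series
    is returned with a warning (the participant later fails inclusion).
    """
    dates = minutes.dates()
    if minutes.n_minutes == 0:
        return MinuteSeries(minutes.participant_id, minutes.start, np.empty(0, np.int8))
    uniq = np.unique(dates)
    if uniq.size < 3:
        warnings.warn(
            f"participant {minutes.participant_id!r}: only {uniq.size} monitoring date(s); "
            "nothing remains after first/last-day trimming",
            stacklevel=2,
        )
        return MinuteSeries(minutes.participant_id, minutes.start, np.empty(0, np.int8))
    keep = (dates != uniq[0]) & (dates != uniq[-1])
    idx = np.flatnonzero(keep)
    new_start = pd.Timestamp(minutes.minute_times()[idx[0]])
    return MinuteSeries(minutes.participant_id, new_start, minutes.codes[keep])


def daily_minutes(minutes: MinuteSeries) -> pd.DataFrame:
    """Per-day label minute totals.

    Returns one row per complete calendar day with columns
    ``participant_id, date, is_weekend`` and one minute-count column per
    label (non-wear included); complete days sum to 1440. Incomplete days
    (possible only in externally supplied, untrimmed data) are dropped with
    a warning.
    """
    cols = ["participant_id", "date", "is_weekend", *ALL_LABELS]
    if minutes.n_minutes == 0:
        return pd.DataFrame(columns=cols)
    dates = minutes.dates()
    uniq, inv, day_totals = np.unique(dates, return_inverse=True, return_counts=True)
    label_counts = np.zeros((uniq.size, len(ALL_LABELS)), dtype=np.int64)
    np.add.at(label_counts, (inv, minutes.codes.astype(np.intp)), 1)
    complete = day_totals == MINUTES_PER_DAY
    if not complete.all():
        warnings.warn(
            f"participant {minutes.participant_id!r}: dropping "
            f"{int((~complete).sum())} incomplete day(s)",
            stacklevel=2,
        )
    uniq, label_counts = uniq[complete], label_counts[complete]
    out = pd.DataFrame(label_counts.astype(float), columns=list(ALL_LABELS))
    out.insert(0, "participant_id", minutes.participant_id)
    dates_idx = pd.DatetimeIndex(uniq)
    out.insert(1, "date", dates_idx.date)
    out.insert(2, "is_weekend", dates_idx.weekday >= 5)
    return out


def apply_nonwear_exclusion(days: pd.DataFrame) -> pd.DataFrame:
    """Drop the first day with > 60 non-wear minutes and every later day.

    ``days`` must be in chronological order (as produced by
    :func:`daily_minutes`). Retained days are marked ``valid``.
    """
    days = days.reset_index(drop=True)
    if days.empty:
        out = days.copy()
        out["valid"] = pd.Series(dtype=bool)
        return out
    over = days[NONWEAR].to_numpy() > NONWEAR_EXCLUSION_MINUTES
    cutoff = int(np.argmax(over)) if over.any() else len(days)
    out = days.iloc[:cutoff].copy()
    out["valid"] = True
    return out


@dataclass(frozen=True)
class InclusionDecision:
    participant_id: str
    included: bool
    reason: str
    n_valid_days: int
    n_weekdays: int
    n_weekend_days: int
    strict: bool


def check_inclusion(days: pd.DataFrame, strict: bool = False) -> InclusionDecision:
    """Minimum-monitoring rule.

    Default: at least one valid weekday (Mon–Fri) and one valid weekend day
    (Sat/Sun). Strict: at least three weekdays and one weekend day.
    """
    pid = str(days["participant_id"].iloc[0]) if len(days) else ""
    n_weekend = int(days["is_weekend"].sum()) if len(days) else 0
    n_weekday = int(len(days) - n_weekend)
    need_wd = 3 if strict else 1
    if n_weekday >= need_wd and n_weekend >= 1:
        return InclusionDecision(pid, True, "ok", len(days), n_weekday, n_weekend, strict)
    reason = (
        f"requires >= {need_wd} weekday(s) and >= 1 weekend day; "
        f"has {n_weekday} weekday(s), {n_weekend} weekend day(s)"
    )
    return InclusionDecision(pid, False, reason, len(days), n_weekday, n_weekend, strict)


# ---------------------------------------------------------------------------
# Participant summary
# ---------------------------------------------------------------------------


@dataclass
class ParticipantPASummary:
    """Daily-average activity minutes, MET minutes and category totals.

    ``daily_met_minutes`` multiplies average minutes per label by the MET
    table; non-wear minutes contribute zero MET minutes and belong to no
    category. ``weekly`` values are 7 x daily. ``who_compliant`` flags a
    daily running/cycling MET-minute average of at least 600/7.
    """

    participant_id: str
    scope: str
    available: bool
    n_valid_days: int = 0
    n_valid_weekdays: int = 0
    n_valid_weekend_days: int = 0
    daily_minutes: dict[str, float] = field(default_factory=dict)
    daily_met_minutes: dict[str, float] = field(default_factory=dict)
    category_minutes: dict[str, float] = field(default_factory=dict)
    category_met_daily: dict[str, float] = field(default_factory=dict)
    category_met_weekly: dict[str, float] = field(default_factory=dict)
    who_compliant: bool = False

    def to_record(self) -> dict:
        rec: dict = {
            "participant_id": self.participant_id,
            "scope": self.scope,
            "available": self.available,
            "n_valid_days": self.n_valid_days,
            "n_valid_weekdays": self.n_valid_weekdays,
            "n_valid_weekend_days": self.n_valid_weekend_days,
            "who_compliant": self.who_compliant,
        }
        for lab, v in self.daily_minutes.items():
            rec[f"min_{lab}"] = v
        for lab, v in self.daily_met_minutes.items():
            rec[f"met_{lab}"] = v
        for cat, v in self.category_minutes.items():
            rec[f"min_cat_{cat}"] = v
        for cat, v in self.category_met_daily.items():
            rec[f"met_daily_{cat}"] = v
        for cat, v in self.category_met_weekly.items():
            rec[f"met_weekly_{cat}"] = v
        return rec


def summarize_participant(
    days: pd.DataFrame,
    met_table: METTable | None = None,
    scope: str = "all",
) -> ParticipantPASummary:
    """Aggregate valid days into a participant's PA summary.

    Parameters
    ----------
    days
        Valid-day table from :func:`apply_nonwear_exclusion`.
    met_table
        MET value per label; defaults to the device-classification table.
    scope
        ``"all"``, ``"weekday"`` or ``"weekend"`` — restricts the
        daily-average denominator to the named day type.
    """
    if met_table is None:
        met_table = METTable()
    if scope not in ("all", "weekday", "weekend"):
        raise ValueError(f"unknown scope {scope!r}")
    pid = str(days["participant_id"].iloc[0]) if len(days) else ""
    if scope == "weekday":
        sel = days[~days["is_weekend"]]
    elif scope == "weekend":
        sel = days[days["is_weekend"]]
    else:
        sel = days
    if sel.empty:
        return ParticipantPASummary(pid, scope, available=False)
    n_weekend = int(sel["is_weekend"].sum())
    avg_min = {lab: float(sel[lab].mean()) for lab in ALL_LABELS}
    met_min = {lab: avg_min[lab] * met_table[lab] for lab in ACTIVITY_LABELS}
    met_min[NONWEAR] = 0.0
    cat_min = {c: sum(avg_min[m] for m in mem) for c, mem in CATEGORY_MEMBERS.items()}
    cat_met = {c: sum(met_min[m] for m in mem) for c, mem in CATEGORY_MEMBERS.items()}
    summary = ParticipantPASummary(
        participant_id=pid,
        scope=scope,
        available=True,
        n_valid_days=len(sel),
        n_valid_weekdays=len(sel) - n_weekend,
        n_valid_weekend_days=n_weekend,
        daily_minutes=avg_min,
        daily_met_minutes=met_min,
        category_minutes=cat_min,
        category_met_daily=cat_met,
        category_met_weekly={c: 7.0 * v for c, v in cat_met.items()},
    )
    summary.who_compliant = who_compliance(summary)
    return summary


def who_compliance(summary: ParticipantPASummary) -> bool:
    """True iff daily running/cycling MET minutes reach the guideline cut-off."""
    if not summary.available:
        return False
    return summary.category_met_daily["running_cycling"] >= who_daily_threshold()


def process_stream(
    stream: EpochStream,
    met_table: METTable | None = None,
    strict: bool = False,
    scope: str = "all",
) -> tuple[ParticipantPASummary | None, dict]:
    """Run the full epoch-to-summary chain for one participant.

    Returns ``(summary, flow)`` where ``flow`` records counts at each stage
    and the inclusion decision; ``summary`` is ``None`` when the participant
    fails inclusion.
    """
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        minutes = majority_vote_minutes(stream)
        trimmed = trim_first_last_day(minutes)
        days = daily_minutes(trimmed)
    kept = apply_nonwear_exclusion(days)
    decision = check_inclusion(kept, strict=strict) if len(kept) else InclusionDecision(
        stream.participant_id, False, "no valid days", 0, 0, 0, strict
    )
    flow = {
        "participant_id": stream.participant_id,
        "n_recorded_days": int(np.unique(minutes.dates()).size) if minutes.n_minutes else 0,
        "n_days_after_trim": len(days),
        "n_days_after_nonwear": len(kept),
        "included": decision.included,
        "exclusion_reason": "" if decision.included else decision.reason,
    }
    if not decision.included:
        return None, flow
    return summarize_participant(kept, met_table=met_table, scope=scope), flow
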