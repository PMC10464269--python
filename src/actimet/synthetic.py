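"""Synthetic two-group activity cohort generator.

Generates an SGA-vs-control cohort with the statistical structure the
downstream analysis assumes: per-participant 5-second activity/posture
label streams with a night-time lying block, bout-structured daytime
activity and injected non-wear episodes; IPAQ short-form self-reports that
are noisily and optimistically coupled to the underlying activity; SF-36
component summaries linked to objectively measured activity; and the
covariates the models adjust for (sex, weekly work hours, month of
assessment).

Calibration
-----------
Default label minute budgets are solved from the published group-level
category MET-minute means of a thigh-accelerometer cohort of adults born
small for gestational age and controls (sedentary ~1238/1256, on feet
~708/682, on the move ~218/227, running/cycling ~46/37 MET min/day), so
that default cohorts land near those values:

===========  =======  =========
label        SGA      control
===========  =======  =========
lying        640      632
sitting      460      480
standing     272      253
walking      61       68
running      6        3
cycling      1        4
===========  =======  =========

The generative model for the activity–HRQoL link is

    on_the_move_MET = group_baseline + group_effect(SGA)
                      + beta_group * (PCS - 50) + noise,

with PCS and MCS drawn exogenously (mean 50, SD 10); this makes the
configured slope ``beta_group`` recoverable by the interaction regression
without errors-in-variables attenuation.

All randomness flows from one master seed through named substreams, so the
cohort is bit-reproducible and any participant can be regenerated alone.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import sf36 as sf36mod
from ._seeds import substream
from .accel import (
    ACTIVITY_LABELS,
    ALL_LABELS,
    EPOCHS_PER_MINUTE,
    MINUTES_PER_DAY,
    NONWEAR_CODE,
    EpochStream,
)
from .ipaq import IPAQResponse

__all__ = [
    "CohortConfig",
    "ActivityProfile",
    "CohortBundle",
    "ConfigError",
    "GROUP_BUDGETS",
    "generate_cohort",
    "simulate_epoch_stream",
    "inject_nonwear",
    "derive_ipaq_from_truth",
    "derive_sf36_from_truth",
    "onmove_met_of",
]

_LCODE = {lab: i for i, lab in enumerate(ALL_LABELS)}

GROUP_BUDGETS: dict[str, dict[str, float]] = {
    "control": {"lying": 632, "sitting": 480, "standing": 253, "walking": 68, "running": 3, "cycling": 4},
    "SGA": {"lying": 640, "sitting": 460, "standing": 272, "walking": 61, "running": 6, "cycling": 1},
}

_MET = {"lying": 1.0, "sitting": 1.3, "standing": 1.8, "walking": 2.8, "running": 7.0, "cycling": 4.0}

#: Mean bout length (minutes) per label used to lay daytime activity out as
#: contiguous runs; walking bouts straddle the 10-minute self-report cut-off.
_BOUT_MEAN = {"lying": 30.0, "sitting": 40.0, "standing": 8.0, "walking": 7.0, "running": 20.0, "cycling": 15.0}

#: Anchor Wednesday for monitoring start dates (weekly grid over ~18 months).
_ANCHOR_DATE = pd.Timestamp("2019-09-02")  # a Monday; weekday offsets added


class ConfigError(ValueError):
    """A cohort configuration field is out of range."""


@dataclass
class CohortConfig:
    """Study-condition knobs for the synthetic cohort.

    The defaults describe the emulated study: 7 recorded days starting on a
    Wednesday, slightly more women than men, no additional group effect on
    top of the baseline budget difference, an SGA-only activity–PCS slope of
    4.0 MET min/day per PCS point, and self-reported MVPA overestimated by
    half.
    """

    n_sga: int = 40
    n_control: int = 48
    prop_female: float = 0.56
    n_days: int = 7
    seed: int = 0
    start_weekday: int = 2  # 0=Monday ... 2=Wednesday
    group_effect_onmove_met: float = 0.0
    beta_metmin_per_pcs_point: dict[str, float] = field(
        default_factory=lambda: {"SGA": 4.0, "control": 0.0}
    )
    pcs_sd: float = 10.0
    onmove_noise_sd_met: float = 100.0
    day_to_day_sd: float = 25.0
    selfreport_bias_mvpa: float = 1.5
    selfreport_noise_sd: float = 60.0
    nonwear_rate: float = 0.2
    nonwear_duration_minutes: tuple[float, float] = (3.2, 0.8)  # lognormal (mu, sigma) of minutes
    ipaq_incomplete_rate: float = 0.30
    ipaq_invalid_rate: float = 0.02
    sf36_partial_rate: float = 0.02

    def __post_init__(self) -> None:
        if self.n_sga <= 0:
            raise ConfigError("n_sga must be a positive count")
        if self.n_control <= 0:
            raise ConfigError("n_control must be a positive count")
        if not 0.0 <= self.prop_female <= 1.0:
            raise ConfigError("prop_female must be a fraction in [0, 1]")
        if self.n_days < 3:
            raise ConfigError("n_days must be at least 3 (no analyzable day after trimming otherwise)")
        if not 0 <= self.start_weekday <= 6:
            raise ConfigError("start_weekday must be in 0..6")
        if self.selfreport_bias_mvpa < 1.0:
            raise ConfigError("selfreport_bias_mvpa must be >= 1 (overestimation factor)")
        if self.selfreport_noise_sd < 0:
            raise ConfigError("selfreport_noise_sd must be non-negative")
        if self.nonwear_rate < 0:
            raise ConfigError("nonwear_rate must be non-negative")
        for rate_name in ("ipaq_incomplete_rate", "ipaq_invalid_rate", "sf36_partial_rate"):
            v = getattr(self, rate_name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{rate_name} must be a fraction in [0, 1]")
        missing = [g for g in ("SGA", "control") if g not in self.beta_metmin_per_pcs_point]
        if missing:
            raise ConfigError(f"beta_metmin_per_pcs_point missing group(s): {missing}")


@dataclass
class ActivityProfile:
    """Expected daily minute budget per activity label for one participant.

    ``night_window`` is a (start_minute, end_minute) clock interval, wrapping
    midnight, that is forced to lying; the lying budget must cover it.
    """

    participant_id: str
    expected_minutes: dict[str, float]
    night_window: tuple[int, int] = (1380, 420)  # 23:00 - 07:00
    day_to_day_sd: float = 25.0

    def __post_init__(self) -> None:
        missing = set(ACTIVITY_LABELS) - set(self.expected_minutes)
        if missing:
            raise ConfigError(f"profile missing labels: {sorted(missing)}")
        if any(v < 0 for v in self.expected_minutes.values()):
            raise ConfigError("expected minutes must be non-negative")
        total = sum(self.expected_minutes.values())
        if abs(total - MINUTES_PER_DAY) > 1e-6:
            raise ConfigError(f"expected minutes must sum to 1440, got {total}")
        if self.expected_minutes["lying"] + 1e-9 < self.night_length:
            raise ConfigError("lying budget smaller than the night window")

    @property
    def night_length(self) -> int:
        start, end = self.night_window
        return (end - start) % MINUTES_PER_DAY if start != end else 0


def onmove_met_of(minutes: dict[str, float]) -> float:
    """On-the-move MET minutes implied by a label minute budget."""
    return sum(_MET[lab] * minutes[lab] for lab in ("walking", "running", "cycling"))


# ---------------------------------------------------------------------------
# Epoch-stream simulation
# ---------------------------------------------------------------------------


def _bout_lengths(total: int, mean_len: float, rng: np.random.Generator) -> list[int]:
    """Split ``total`` minutes into bouts with roughly exponential lengths."""
    out: list[int] = []
    remaining = total
    while remaining > 0:
        length = min(remaining, max(1, int(round(rng.exponential(mean_len)))))
        out.append(length)
        remaining -= length
    return out


def _simulate_day(profile: ActivityProfile, rng: np.random.Generator) -> tuple[np.ndarray, dict]:
    """One day's 1440 per-minute labels plus the day's truth record."""
    night_start, night_end = profile.night_window
    night_len = profile.night_length
    wake = MINUTES_PER_DAY - night_len

    draws: dict[str, int] = {}
    for lab in ("standing", "walking", "running", "cycling"):
        e = profile.expected_minutes[lab]
        sd = min(profile.day_to_day_sd, e) if e > 0 else 0.0
        draws[lab] = max(0, int(round(rng.normal(e, sd)))) if sd > 0 else int(round(e))
    extra_lying = profile.expected_minutes["lying"] - night_len
    sd = min(profile.day_to_day_sd, extra_lying) if extra_lying > 0 else 0.0
    draws["lying"] = max(0, int(round(rng.normal(extra_lying, sd)))) if sd > 0 else int(round(extra_lying))

    active = sum(draws.values())
    if active > wake:  # rescale (rare under default budgets)
        scale = wake / active
        for lab in draws:
            draws[lab] = int(math.floor(draws[lab] * scale))
        active = sum(draws.values())
    draws["sitting"] = wake - active

    bouts: list[tuple[str, int]] = []
    walking_long = 0
    for lab in ("lying", "sitting", "standing", "walking", "running", "cycling"):
        for length in _bout_lengths(draws[lab], _BOUT_MEAN[lab], rng):
            bouts.append((lab, length))
            if lab == "walking" and length >= 10:
                walking_long += length
    rng.shuffle(bouts)

    day = np.empty(MINUTES_PER_DAY, dtype=np.int8)
    night_mask = np.zeros(MINUTES_PER_DAY, dtype=bool)
    if night_len:
        idx = (np.arange(night_start, night_start + night_len)) % MINUTES_PER_DAY
        night_mask[idx] = True
    day[night_mask] = _LCODE["lying"]
    wake_codes = np.concatenate(
        [np.full(length, _LCODE[lab], dtype=np.int8) for lab, length in bouts]
    ) if bouts else np.empty(0, dtype=np.int8)
    day[~night_mask] = wake_codes

    truth = {lab: float(np.sum(day == _LCODE[lab])) for lab in ACTIVITY_LABELS}
    truth["walking_long_bouts"] = float(walking_long)
    return day, truth


def simulate_epoch_stream(
    profile: ActivityProfile,
    n_days: int,
    seed: int | np.random.Generator,
    start_date: pd.Timestamp | str = "2019-09-04",
) -> tuple[EpochStream, pd.DataFrame]:
    """Simulate ``n_days`` calendar days of 5-second label epochs.

    Each day holds exactly 17,280 epochs (1440 minutes); the night window
    is entirely lying; daytime labels are laid out as bouts so that
    per-minute majority voting is meaningful. Returns the stream and a
    per-day truth table of label minutes (with the long-bout walking total
    used for self-report coupling).
    """
    if n_days < 1:
        raise ConfigError("n_days must be at least 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    start = pd.Timestamp(start_date).normalize()
    days, records = [], []
    for d in range(n_days):
        day, truth = _simulate_day(profile, rng)
        days.append(day)
        truth.update(
            {
                "participant_id": profile.participant_id,
                "day_index": d,
                "date": (start + pd.Timedelta(days=d)).date(),
            }
        )
        records.append(truth)
    minute_codes = np.concatenate(days)
    epochs = np.repeat(minute_codes, EPOCHS_PER_MINUTE)
    stream = EpochStream(profile.participant_id, start, epochs)
    cols = ["participant_id", "day_index", "date", *ACTIVITY_LABELS, "walking_long_bouts"]
    return stream, pd.DataFrame.from_records(records)[cols]


def inject_nonwear(
    stream: EpochStream,
    rate: float,
    duration_params: tuple[float, float] = (3.2, 0.8),
    seed: int | np.random.Generator = 0,
) -> EpochStream:
    """Relabel random contiguous epoch runs as non-wear.

    The number of episodes is Poisson with mean ``rate`` x days; episode
    durations (minutes) are lognormal with the given (mu, sigma) of the
    log. ``rate=0`` returns an identical stream. Epoch count is unchanged.
    """
    codes = stream.codes.copy()
    if rate > 0:
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        n_days = stream.n_epochs / (MINUTES_PER_DAY * EPOCHS_PER_MINUTE)
        n_episodes = rng.poisson(rate * n_days)
        for _ in range(n_episodes):
            start = int(rng.integers(0, stream.n_epochs))
            minutes = max(1.0, rng.lognormal(*duration_params))
            length = int(round(minutes * EPOCHS_PER_MINUTE))
            codes[start : start + length] = NONWEAR_CODE
    return EpochStream(stream.participant_id, stream.start, codes)


# ---------------------------------------------------------------------------
# Self-report and HRQoL coupling
# ---------------------------------------------------------------------------


def derive_ipaq_from_truth(
    profile: ActivityProfile,
    bias: float,
    noise_sd: float,
    seed: int | np.random.Generator,
    daily_truth: pd.DataFrame | None = None,
) -> IPAQResponse:
    """Build an IPAQ short-form response from the underlying activity.

    Reported walking couples only weakly to true walking: the instrument
    counts only bouts of >= 10 minutes, and full recall noise
    (``noise_sd`` minutes) is added. Reported moderate/vigorous PA couple
    to true cycling/running with multiplicative overestimation ``bias``
    and a third of the recall noise — reproducing the field's observation
    that self-report correlates worst for walking and best for MVPA
    against device-measured running/cycling.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if daily_truth is not None and len(daily_truth):
        walk_long = float(daily_truth["walking_long_bouts"].mean())
        run = float(daily_truth["running"].mean())
        cyc = float(daily_truth["cycling"].mean())
        sit = float(daily_truth["sitting"].mean())
        days_walk = int(min(7, (daily_truth["walking_long_bouts"] > 0).sum()))
        days_run = int(min(7, (daily_truth["running"] > 0).sum()))
        days_cyc = int(min(7, (daily_truth["cycling"] > 0).sum()))
    else:
        walk_long = 0.6 * profile.expected_minutes["walking"]
        run = profile.expected_minutes["running"]
        cyc = profile.expected_minutes["cycling"]
        sit = profile.expected_minutes["sitting"]
        days_walk = 7 if walk_long > 0 else 0
        days_run = 7 if run > 0 else 0
        days_cyc = 7 if cyc > 0 else 0

    def report(value: float, sd: float) -> float:
        return max(0.0, value + (rng.normal(0.0, sd) if sd > 0 else 0.0))

    minutes_walking = report(walk_long, noise_sd)
    minutes_mpa = report(bias * cyc, noise_sd / 3.0)
    minutes_vpa = report(bias * run, noise_sd / 3.0)
    sitting = report(sit, noise_sd / 3.0)
    return IPAQResponse(
        participant_id=profile.participant_id,
        days_walking=days_walk if minutes_walking > 0 else 0,
        minutes_walking=round(minutes_walking, 1),
        days_mpa=days_cyc if minutes_mpa > 0 else 0,
        minutes_mpa=round(minutes_mpa, 1),
        days_vpa=days_run if minutes_vpa > 0 else 0,
        minutes_vpa=round(minutes_vpa, 1),
        sitting_minutes=round(sitting, 1),
        administration="examination",
    )


_DOMAIN_PCS_LOAD = {
    "physical_functioning": 0.8,
    "role_physical": 0.7,
    "bodily_pain": 0.65,
    "general_health": 0.5,
    "vitality": 0.35,
    "social_functioning": 0.2,
    "role_emotional": 0.05,
    "mental_health": 0.0,
}
_DOMAIN_MCS_LOAD = {
    "physical_functioning": 0.0,
    "role_physical": 0.05,
    "bodily_pain": 0.1,
    "general_health": 0.3,
    "vitality": 0.45,
    "social_functioning": 0.55,
    "role_emotional": 0.7,
    "mental_health": 0.8,
}


def derive_sf36_from_truth(
    profile: ActivityProfile,
    beta_metmin_per_pcs_point: float,
    noise_sd: float,
    seed: int | np.random.Generator,
    baseline_onmove_met: float | None = None,
    pcs_sd: float = 10.0,
) -> tuple[dict, ActivityProfile]:
    """Draw SF-36 summaries and couple the activity profile to them.

    PCS and MCS are drawn exogenously (mean 50, SD ``pcs_sd``; MCS
    independent of activity). The returned profile has its walking minutes
    adjusted so that its expected on-the-move MET minutes equal
    ``baseline + beta x (PCS - 50) + N(0, noise_sd)`` — putting the noise
    on the activity side keeps the configured slope recoverable by
    regression without attenuation. Domain scores consistent with the
    summaries are also generated.

    Returns ``(record, adjusted_profile)`` where ``record`` holds
    participant_id, pcs, mcs, the eight domain scores and the on-the-move
    MET target.
    """
    if not np.isfinite(beta_metmin_per_pcs_point):
        raise ConfigError("beta_metmin_per_pcs_point must be finite")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if baseline_onmove_met is None:
        baseline_onmove_met = onmove_met_of(profile.expected_minutes)
    pcs = float(rng.normal(50.0, pcs_sd))
    mcs = float(rng.normal(50.0, pcs_sd))
    noise = float(rng.normal(0.0, noise_sd)) if noise_sd > 0 else 0.0
    target = baseline_onmove_met + beta_metmin_per_pcs_point * (pcs - 50.0) + noise

    minutes = dict(profile.expected_minutes)
    rc_met = _MET["running"] * minutes["running"] + _MET["cycling"] * minutes["cycling"]
    new_walking = max(0.0, (target - rc_met) / _MET["walking"])
    delta = new_walking - minutes["walking"]
    minutes["walking"] = new_walking
    # absorb the shift in sitting, spilling into lying (down to the forced
    # night block) if sitting runs out
    minutes["sitting"] -= delta
    if minutes["sitting"] < 0:
        spill = minutes["sitting"]
        minutes["sitting"] = 0.0
        lying_floor = float(profile.night_length)
        new_lying = minutes["lying"] + spill
        if new_lying < lying_floor:
            # cap walking so the budget stays feasible
            minutes["walking"] += (new_lying - lying_floor) / 1.0
            minutes["walking"] = max(0.0, minutes["walking"])
            new_lying = lying_floor
        minutes["lying"] = new_lying
        total = sum(minutes.values())
        minutes["sitting"] += MINUTES_PER_DAY - total  # re-balance rounding
        minutes["sitting"] = max(0.0, minutes["sitting"])
    adjusted = ActivityProfile(
        participant_id=profile.participant_id,
        expected_minutes=minutes,
        night_window=profile.night_window,
        day_to_day_sd=profile.day_to_day_sd,
    )
    zp, zm = (pcs - 50.0) / 10.0, (mcs - 50.0) / 10.0
    domains = {}
    for d in sf36mod.DOMAINS:
        mean = sf36mod._ILLUSTRATIVE_NORM_MEANS[d]
        sd = sf36mod._ILLUSTRATIVE_NORM_SDS[d]
        val = mean + sd * (_DOMAIN_PCS_LOAD[d] * zp + _DOMAIN_MCS_LOAD[d] * zm + 0.3 * rng.normal())
        domains[d] = float(np.clip(val, 0.0, 100.0))
    record = {
        "participant_id": profile.participant_id,
        "pcs": pcs,
        "mcs": mcs,
        "onmove_met_target": target,
        **domains,
    }
    return record, adjusted


# ---------------------------------------------------------------------------
# Cohort assembly
# ---------------------------------------------------------------------------


@dataclass
class CohortBundle:
    """Everything the analysis consumes, plus the generating truth."""

    config: CohortConfig
    participants: pd.DataFrame
    daily_truth: pd.DataFrame
    ipaq: pd.DataFrame
    sf36: pd.DataFrame
    epoch_streams: dict[str, EpochStream] = field(default_factory=dict)

    def truth_daily_met(self, category: str = "on_the_move") -> pd.Series:
        """Participant-level daily MET minutes of a category from the truth
        minutes (pre non-wear), indexed by participant_id."""
        members = {
            "sedentary": ("lying", "sitting"),
            "on_feet": ("standing", "walking", "running", "cycling"),
            "on_the_move": ("walking", "running", "cycling"),
            "running_cycling": ("running", "cycling"),
        }[category]
        per_day = sum(self.daily_truth[lab] * _MET[lab] for lab in members)
        return per_day.groupby(self.daily_truth["participant_id"]).mean()


def _participant_profile(
    pid: str, group: str, config: CohortConfig, rng: np.random.Generator | None = None
) -> ActivityProfile:
    """Group budget with participant-level running/cycling heterogeneity.

    Running/cycling volume is strongly right-skewed between people (most do
    almost none, a few train regularly), so the participant's
    running/cycling MET minutes are drawn from an exponential with the
    group-budget mean; the running-vs-cycling MET split of the group budget
    is preserved and the minute difference is absorbed by sitting/lying.
    """
    minutes = {k: float(v) for k, v in GROUP_BUDGETS[group].items()}
    if group == "SGA" and config.group_effect_onmove_met != 0.0:
        shift_walk = config.group_effect_onmove_met / _MET["walking"]
        minutes["walking"] = max(0.0, minutes["walking"] + shift_walk)
        minutes["sitting"] = minutes["sitting"] - (minutes["walking"] - GROUP_BUDGETS[group]["walking"])
        if minutes["sitting"] < 0:
            minutes["lying"] += minutes["sitting"]
            minutes["sitting"] = 0.0
    if rng is not None:
        base_rc = _MET["running"] * minutes["running"] + _MET["cycling"] * minutes["cycling"]
        if base_rc > 0:
            run_share = _MET["running"] * minutes["running"] / base_rc
            rc = rng.exponential(base_rc)
            old = minutes["running"] + minutes["cycling"]
            minutes["running"] = run_share * rc / _MET["running"]
            minutes["cycling"] = (1.0 - run_share) * rc / _MET["cycling"]
            minutes["sitting"] -= minutes["running"] + minutes["cycling"] - old
            if minutes["sitting"] < 0:
                minutes["lying"] += minutes["sitting"]
                minutes["sitting"] = 0.0
                total = sum(minutes.values())
                if total > MINUTES_PER_DAY:  # extreme draw: trim the excess
                    for lab in ("running", "cycling"):
                        cut = min(minutes[lab], total - MINUTES_PER_DAY)
                        minutes[lab] -= cut
                        total -= cut
                        if total <= MINUTES_PER_DAY:
                            break
                minutes["sitting"] += MINUTES_PER_DAY - sum(minutes.values())
    return ActivityProfile(pid, minutes, day_to_day_sd=config.day_to_day_sd)


def generate_cohort(config: CohortConfig, materialize_epochs: bool = True) -> CohortBundle:
    """Generate the full cohort bundle under the config's master seed.

    With ``materialize_epochs=False`` the 5-second streams are skipped and
    only the per-day truth minutes are produced — two orders of magnitude
    faster, for simulation studies that start from daily summaries.
    """
    ids = [f"S{i:03d}" for i in range(1, config.n_sga + 1)] + [
        f"C{i:03d}" for i in range(1, config.n_control + 1)
    ]
    groups = ["SGA"] * config.n_sga + ["control"] * config.n_control

    part_records, sf_records, truth_frames, ipaq_rows = [], [], [], []
    streams: dict[str, EpochStream] = {}
    for pid, group in zip(ids, groups):
        rng_cov = substream(config.seed, "covariates", pid)
        sex = "female" if rng_cov.random() < config.prop_female else "male"
        work_hours = float(np.clip(rng_cov.normal(37.5, 8.0), 0.0, 60.0))
        week_offset = int(rng_cov.integers(0, 78))
        start_date = _ANCHOR_DATE + pd.Timedelta(days=7 * week_offset + config.start_weekday)

        profile0 = _participant_profile(pid, group, config, substream(config.seed, "profile", pid))
        baseline = onmove_met_of(profile0.expected_minutes)
        sf_rec, profile = derive_sf36_from_truth(
            profile0,
            beta_metmin_per_pcs_point=config.beta_metmin_per_pcs_point[group],
            noise_sd=config.onmove_noise_sd_met,
            seed=substream(config.seed, "sf36", pid),
            baseline_onmove_met=baseline,
            pcs_sd=config.pcs_sd,
        )

        rng_act = substream(config.seed, "activity", pid)
        stream, truth = simulate_epoch_stream(profile, config.n_days, rng_act, start_date=start_date)
        if materialize_epochs:
            stream = inject_nonwear(
                stream,
                config.nonwear_rate,
                config.nonwear_duration_minutes,
                substream(config.seed, "nonwear", pid),
            )
            streams[pid] = stream
        truth_frames.append(truth)

        rng_sr = substream(config.seed, "ipaq", pid)
        resp = derive_ipaq_from_truth(
            profile,
            bias=config.selfreport_bias_mvpa,
            noise_sd=config.selfreport_noise_sd,
            seed=rng_sr,
            daily_truth=truth,
        )
        row = {
            "participant_id": pid,
            "administration": resp.administration,
            "days_walking": resp.days_walking,
            "minutes_walking": resp.minutes_walking,
            "days_mpa": resp.days_mpa,
            "minutes_mpa": resp.minutes_mpa,
            "days_vpa": resp.days_vpa,
            "minutes_vpa": resp.minutes_vpa,
            "sitting_minutes": resp.sitting_minutes,
        }
        u = rng_sr.random()
        if u < config.ipaq_invalid_rate:
            row["minutes_walking"], row["minutes_mpa"] = 700.0, 500.0  # trips the 960-min rule
            row["days_walking"] = max(1, row["days_walking"])
            row["days_mpa"] = max(1, row["days_mpa"])
        elif u < config.ipaq_invalid_rate + config.ipaq_incomplete_rate:
            victim = ["minutes_walking", "minutes_mpa", "minutes_vpa"][int(rng_sr.integers(0, 3))]
            row[victim] = None
            row[victim.replace("minutes", "days")] = None
        ipaq_rows.append(row)

        if rng_sr.random() < config.sf36_partial_rate:
            sf_rec = dict(sf_rec)
            victim_dom = sf36mod.DOMAINS[int(rng_sr.integers(0, len(sf36mod.DOMAINS)))]
            sf_rec[victim_dom] = float("nan")
            sf_rec["pcs"] = float("nan")
            sf_rec["mcs"] = float("nan")
        sf_records.append(sf_rec)

        part_records.append(
            {
                "participant_id": pid,
                "group": group,
                "sex": sex,
                "work_hours": round(work_hours, 1),
                "start_date": start_date.date(),
                # first complete retained day is the day after the trimmed first day
                "month_of_assessment": int((start_date + pd.Timedelta(days=1)).month),
                "onmove_met_target": sf_rec["onmove_met_target"],
            }
        )

    return CohortBundle(
        config=config,
        participants=pd.DataFrame.from_records(part_records),
        daily_truth=pd.concat(truth_frames, ignore_index=True),
        ipaq=pd.DataFrame.from_records(ipaq_rows),
        sf36=pd.DataFrame.from_records(sf_records),
        epoch_streams=streams,
    )
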