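"""Simulation-based calibration checks for the inference machinery.

The study-scale estimates themselves cannot be checked against ground truth
(the raw cohort is synthetic), so the package ships the calibration studies
that justify trusting its machinery instead:

* confidence-interval coverage of the BCa bootstrap on a known Gaussian mean;
* type-I error of the sex-adjusted group comparison under a true null;
* recovery (CI coverage) of injected group effects and interaction slopes
  from full synthetic cohorts;
* exhaustive equivalence of the minute majority vote and the IPAQ level
  classifier against independently written brute-force evaluators;
* per-day minute conservation and category-nesting invariants over many
  simulated days;
* byte-reproducibility and wall-time of the end-to-end demo pipeline.

Every function is deterministic given its ``seed`` and returns plain numbers
so callers (the validation suite and the ``scripts/acceptance.py`` report)
can apply their own tolerances.
"""

from __future__ import annotations

import itertools
import time
from pathlib import Path

import numpy as np

from ._seeds import substream, substream_seed
from .accel import ALL_LABELS, EpochStream, MINUTES_PER_DAY, majority_vote_minutes
from .ipaq import IPAQResponse, Level, Validity, score_response, validate_response
from .stats import (
    BootstrapConfig,
    adjusted_group_difference,
    bca_interval,
    interaction_association,
)
from .synthetic import (
    GROUP_BUDGETS,
    CohortConfig,
    generate_cohort,
    onmove_met_of,
)

__all__ = [
    "bca_mean_coverage",
    "group_test_type_i_error",
    "effect_recovery_coverage",
    "vote_oracle_agreement",
    "ipaq_grid_agreement",
    "day_conservation",
    "smoke_reproducibility",
]

_MET = {"lying": 1.0, "sitting": 1.3, "standing": 1.8, "walking": 2.8, "running": 7.0, "cycling": 4.0}


def bca_mean_coverage(
    n: int = 40, reps: int = 1000, B: int = 1000, mean: float = 0.0, sd: float = 1.0, seed: int = 0
) -> float:
    """Fraction of replicates whose 95% BCa interval covers the true mean."""
    rng = np.random.default_rng(seed)
    hits = 0
    for r in range(reps):
        data = rng.normal(mean, sd, size=n)
        cfg = BootstrapConfig(B=B, seed=substream_seed(seed, "bca", r), stratify_by_group=False)
        lo, hi = bca_interval(np.mean, data, cfg)
        hits += lo <= mean <= hi
    return hits / reps


def group_test_type_i_error(
    n1: int = 40, n2: int = 48, reps: int = 1000, B: int = 200, alpha: float = 0.05, seed: int = 0
) -> float:
    """Rejection rate of the sex-adjusted group test when no effect exists.

    Defaults use the demo-cohort group sizes (40/48). With much smaller
    groups (~20 per arm) the case-resampling BCa test is noticeably
    anti-conservative (rejection ~8-9%), a known small-sample property of
    bootstrap percentile-type intervals.
    """
    rng = np.random.default_rng(seed)
    group = np.array(["SGA"] * n1 + ["control"] * n2)
    rejections = 0
    for r in range(reps):
        sex = rng.choice(["female", "male"], size=n1 + n2)
        y = rng.normal(0.0, 1.0, size=n1 + n2)
        res = adjusted_group_difference(
            y, group, sex, cfg=BootstrapConfig(B=B, seed=substream_seed(seed, "null", r))
        )
        rejections += res.p_value <= alpha
    return rejections / reps


def effect_recovery_coverage(
    reps: int = 100,
    B: int = 500,
    group_effect: float = -50.0,
    slope: float = 4.0,
    seed: int = 0,
) -> tuple[float, float]:
    """CI coverage for an injected group effect and interaction slope.

    Each replicate generates a fresh default-size cohort (40 SGA / 48
    control) whose SGA on-the-move MET minutes are shifted by
    ``group_effect`` on top of the baseline budget difference and coupled to
    PCS with the given ``slope``; the analysis models are then asked to
    recover both. Returns ``(coverage_group_effect, coverage_slope)``.
    """
    budget_diff = onmove_met_of({k: float(v) for k, v in GROUP_BUDGETS["SGA"].items()}) - onmove_met_of(
        {k: float(v) for k, v in GROUP_BUDGETS["control"].items()}
    )
    true_diff = budget_diff + group_effect
    cover_diff = cover_slope = 0
    for r in range(reps):
        cfg = CohortConfig(
            seed=substream_seed(seed, "cohort", r),
            group_effect_onmove_met=group_effect,
            beta_metmin_per_pcs_point={"SGA": slope, "control": 0.0},
        )
        bundle = generate_cohort(cfg, materialize_epochs=False)
        part = bundle.participants.set_index("participant_id")
        y = bundle.truth_daily_met("on_the_move").loc[part.index]

        res = adjusted_group_difference(
            y, part["group"], part["sex"],
            cfg=BootstrapConfig(B=B, seed=substream_seed(seed, "diff", r)),
        )
        cover_diff += res.ci_low <= true_diff <= res.ci_high

        sf = bundle.sf36.set_index("participant_id").loc[part.index]
        ok = sf["pcs"].notna().to_numpy()
        ares = interaction_association(
            y.to_numpy()[ok],
            sf["pcs"].to_numpy()[ok],
            part["group"].to_numpy()[ok],
            part["sex"].to_numpy()[ok],
            cfg=BootstrapConfig(B=B, seed=substream_seed(seed, "slope", r)),
        )
        _, lo, hi, _ = ares.slopes["SGA"]
        cover_slope += lo <= slope <= hi
    return cover_diff / reps, cover_slope / reps


def _brute_force_vote(labels: list[str]) -> str:
    """Mode of a minute with the earliest-tied-epoch tie rule, by counting."""
    counts: dict[str, int] = {}
    for lab in labels:
        counts[lab] = counts.get(lab, 0) + 1
    best = max(counts.values())
    tied = {lab for lab, c in counts.items() if c == best}
    for lab in labels:
        if lab in tied:
            return lab
    raise AssertionError("unreachable")


def vote_oracle_agreement(
    labels: tuple[str, ...] = ("lying", "walking", "nonwear"),
    orders_per_multiset: int = 3,
    seed: int = 0,
) -> tuple[int, int]:
    """Compare the minute vote to a brute-force oracle.

    Enumerates every 12-epoch multiset over the given labels, lays each out
    in sorted order plus shuffled orders (the tie rule is order-dependent),
    and votes. Returns ``(n_cases, n_agreements)``.
    """
    import pandas as pd

    code = {lab: i for i, lab in enumerate(ALL_LABELS)}
    rng = np.random.default_rng(seed)
    start = pd.Timestamp("2021-03-01")
    n_cases = n_agree = 0
    for combo in itertools.combinations_with_replacement(labels, 12):
        arrangements = [list(combo)]
        for _ in range(orders_per_multiset):
            arr = list(combo)
            rng.shuffle(arr)
            arrangements.append(arr)
        for arr in arrangements:
            stream = EpochStream("P", start, np.array([code[l] for l in arr], dtype=np.int8))
            got = ALL_LABELS[majority_vote_minutes(stream).codes[0]]
            n_cases += 1
            n_agree += got == _brute_force_vote(arr)
    return n_cases, n_agree


def _brute_force_ipaq_level(days: dict[str, int], minutes: dict[str, float]) -> Level:
    """The five IPAQ protocol criteria written out directly."""
    met = {"walking": 3.3, "mpa": 4.0, "vpa": 8.0}
    total = sum(met[c] * days[c] * minutes[c] for c in met)
    combo_days = min(7, days["walking"] + days["mpa"] + days["vpa"])
    if (days["vpa"] >= 3 and total >= 1500) or (combo_days >= 7 and total >= 3000):
        return Level.HIGH
    mod_days = (days["mpa"] if minutes["mpa"] >= 30 else 0) + (
        days["walking"] if minutes["walking"] >= 30 else 0
    )
    if (days["vpa"] >= 3 and minutes["vpa"] >= 20) or mod_days >= 5 or (combo_days >= 5 and total >= 600):
        return Level.MODERATE
    return Level.LOW


def ipaq_grid_agreement(
    minutes_grid: tuple[float, ...] = (0.0, 10.0, 20.0, 30.0, 60.0, 120.0),
) -> tuple[int, int]:
    """Compare the level classifier to a brute-force evaluator exhaustively.

    Walks the full grid of days 0..7 x the minute grid for each of the
    three categories, skipping responses the validity rules reject, and
    classifies each remaining response both ways. Returns
    ``(n_cases, n_agreements)``.
    """
    cells = list(itertools.product(range(8), minutes_grid))
    n_cases = n_agree = 0
    for (dw, mw), (dm, mm), (dv, mv) in itertools.product(cells, cells, cells):
        r = IPAQResponse("P", dw, mw, dm, mm, dv, mv, sitting_minutes=0.0)
        if validate_response(r) is not Validity.VALID:
            continue
        got = score_response(r).level
        want = _brute_force_ipaq_level(
            {"walking": dw, "mpa": dm, "vpa": dv}, {"walking": mw, "mpa": mm, "vpa": mv}
        )
        n_cases += 1
        n_agree += got is want
    return n_cases, n_agree


def day_conservation(n_days: int = 10_000, seed: int = 0) -> tuple[int, int]:
    """Minute conservation and category nesting over simulated days.

    Generates cohorts (without epoch materialisation) until ``n_days``
    person-days exist, then checks that every day's label minutes sum to
    1440 and that the MET-minute categories nest
    (running/cycling <= on the move <= on feet). Returns
    ``(n_days_checked, n_violations)``.
    """
    from .accel import ACTIVITY_LABELS

    per_cohort = 7 * 2 * 360
    checked = violations = 0
    k = 0
    while checked < n_days:
        bundle = generate_cohort(
            CohortConfig(n_sga=360, n_control=360, seed=substream_seed(seed, "days", k)),
            materialize_epochs=False,
        )
        t = bundle.daily_truth
        if checked + len(t) > n_days:
            t = t.iloc[: n_days - checked]
        total = t[list(ACTIVITY_LABELS)].sum(axis=1)
        violations += int((total != MINUTES_PER_DAY).sum())
        rc = 7.0 * t["running"] + 4.0 * t["cycling"]
        onmove = rc + 2.8 * t["walking"]
        onfeet = onmove + 1.8 * t["standing"]
        violations += int((rc > onmove + 1e-9).sum() + (onmove > onfeet + 1e-9).sum())
        checked += len(t)
        k += 1
    return checked, violations


def smoke_reproducibility(base_dir: str | Path, seed: int = 0, B: int = 2000) -> tuple[float, bool]:
    """Run the demo pipeline twice; return (first run seconds, identical?)."""
    from .pipeline import RunConfig, run_pipeline

    base = Path(base_dir)
    t0 = time.perf_counter()
    r1 = run_pipeline(RunConfig(out_dir=str(base / "run1"), seed=seed, bootstrap_B=B))
    elapsed = time.perf_counter() - t0
    r2 = run_pipeline(RunConfig(out_dir=str(base / "run2"), seed=seed, bootstrap_B=B))
    return elapsed, r1.content_hash == r2.content_hash
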