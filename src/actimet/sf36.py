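"""SF-36 health-survey scoring.

Aggregates the 36 items of the Short Form 36 Health Survey into eight
0–100 domain scores (higher = better functioning) and two norm-based
component summaries — the physical (PCS) and mental (MCS) component
summary — expressed as T-scores (population mean 50, SD 10).

Domain scoring follows the standard recipe: item responses are recoded so
that higher always means better health, summed per domain, and linearly
transformed to 0–100::

    domain = 100 * (sum of recoded items - minimum possible) / score range

Component summaries z-score each domain against population norms, combine
the z-scores with factor-analytic weights, and rescale::

    T = 50 + 10 * sum_i coef_i * (domain_i - norm_mean_i) / norm_sd_i

The bundled item map and norm/coefficient tables are *illustrative*: they
reproduce the structure of published orthogonal-rotation solutions (physical
functioning, role-physical and bodily pain load mainly on the PCS; social
functioning, role-emotional and mental health on the MCS; vitality, general
health and social functioning on both) but are not the licensed scoring
coefficients. Studies requiring exact licensed scoring supply their own
tables via :class:`NormCoefficients` / ``item_map``. Domain scores may also
be supplied directly, bypassing item scoring.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "DOMAINS",
    "SF36Domains",
    "SF36Summaries",
    "NormCoefficients",
    "default_item_map",
    "score_domains",
    "score_components",
    "score_domain_table",
]

DOMAINS = (
    "physical_functioning",
    "role_physical",
    "bodily_pain",
    "general_health",
    "vitality",
    "social_functioning",
    "role_emotional",
    "mental_health",
)


@dataclass
class SF36Domains:
    """Eight 0–100 domain scores; ``nan`` marks a domain that could not be
    scored (too many unanswered items)."""

    participant_id: str
    scores: dict[str, float]

    def __post_init__(self) -> None:
        unknown = set(self.scores) - set(DOMAINS)
        if unknown:
            raise ValueError(f"unknown domains: {sorted(unknown)}")
        for d, v in self.scores.items():
            if v == v and not (0.0 <= v <= 100.0):
                raise ValueError(f"domain {d} score {v} outside [0, 100]")

    def complete(self) -> bool:
        return all(d in self.scores and self.scores[d] == self.scores[d] for d in DOMAINS)


@dataclass(frozen=True)
class SF36Summaries:
    participant_id: str
    pcs: float
    mcs: float


# ---------------------------------------------------------------------------
# Item map (illustrative)
# ---------------------------------------------------------------------------


def default_item_map() -> dict[str, dict]:
    """Illustrative 36-item map: item -> {domain, levels, reverse}.

    ``reverse`` items are recoded ``levels + 1 - raw`` so that higher
    recoded values always indicate better health. Item ``q2`` (self-rated
    health transition) is conventionally unscored and is absent.
    """
    m: dict[str, dict] = {}

    def add(item, domain, levels, reverse):
        m[item] = {"domain": domain, "levels": levels, "reverse": reverse}

    add("q1", "general_health", 5, True)
    for s in "abcdefghij":
        add(f"q3{s}", "physical_functioning", 3, False)
    for s in "abcd":
        add(f"q4{s}", "role_physical", 2, False)
    for s in "abc":
        add(f"q5{s}", "role_emotional", 2, False)
    add("q6", "social_functioning", 5, True)
    add("q7", "bodily_pain", 6, True)
    add("q8", "bodily_pain", 5, True)
    # q9 wellbeing grid: positively worded items are reversed
    add("q9a", "vitality", 6, True)
    add("q9b", "mental_health", 6, False)
    add("q9c", "mental_health", 6, False)
    add("q9d", "mental_health", 6, True)
    add("q9e", "vitality", 6, True)
    add("q9f", "mental_health", 6, False)
    add("q9g", "vitality", 6, False)
    add("q9h", "mental_health", 6, True)
    add("q9i", "vitality", 6, False)
    add("q10", "social_functioning", 5, False)
    add("q11a", "general_health", 5, False)
    add("q11b", "general_health", 5, True)
    add("q11c", "general_health", 5, False)
    add("q11d", "general_health", 5, True)
    return m


def score_domains(
    items: dict[str, float] | pd.Series,
    item_map: dict[str, dict] | None = None,
    participant_id: str = "",
    min_answered_frac: float = 0.5,
) -> SF36Domains:
    """Score raw item responses into the eight 0–100 domain scores.

    Missing items are tolerated per domain up to ``min_answered_frac``
    (default: at least half the items answered), with person-mean
    imputation of the recoded values; below the threshold the domain is
    ``nan``.

    Raises
    ------
    KeyError
        For an item code absent from the item map.
    """
    if item_map is None:
        item_map = default_item_map()
    if isinstance(items, pd.Series):
        items = items.dropna().to_dict()
    unknown = set(items) - set(item_map)
    if unknown:
        raise KeyError(f"item codes not in the item map: {sorted(unknown)}")
    per_domain: dict[str, list[tuple[float | None, int]]] = {d: [] for d in DOMAINS}
    for code, spec_ in item_map.items():
        raw = items.get(code)
        levels = spec_["levels"]
        if raw is None or raw != raw:
            rec = None
        else:
            raw = float(raw)
            if not (1.0 <= raw <= levels):
                raise ValueError(f"item {code}: response {raw} outside 1..{levels}")
            rec = (levels + 1 - raw) if spec_["reverse"] else raw
        per_domain[spec_["domain"]].append((rec, levels))

    scores: dict[str, float] = {}
    for d, entries in per_domain.items():
        n_items = len(entries)
        answered = [rec for rec, _ in entries if rec is not None]
        if n_items == 0 or len(answered) / n_items < min_answered_frac:
            scores[d] = float("nan")
            continue
        mean_rec = sum(answered) / len(answered)
        total = sum(rec if rec is not None else mean_rec for rec, _ in entries)
        lo = float(n_items)  # every item's minimum recoded value is 1
        rng = float(sum(levels - 1 for _, levels in entries))
        scores[d] = 100.0 * (total - lo) / rng
    return SF36Domains(participant_id=participant_id, scores=scores)


# ---------------------------------------------------------------------------
# Component summaries
# ---------------------------------------------------------------------------

_ILLUSTRATIVE_NORM_MEANS = {
    "physical_functioning": 84.2,
    "role_physical": 81.0,
    "bodily_pain": 75.2,
    "general_health": 72.0,
    "vitality": 61.1,
    "social_functioning": 83.3,
    "role_emotional": 81.3,
    "mental_health": 74.7,
}
_ILLUSTRATIVE_NORM_SDS = {
    "physical_functioning": 23.3,
    "role_physical": 34.0,
    "bodily_pain": 23.7,
    "general_health": 20.3,
    "vitality": 20.9,
    "social_functioning": 22.7,
    "role_emotional": 33.0,
    "mental_health": 18.1,
}
# Orthogonal-rotation style weights: PF/RP/BP dominate the physical summary,
# SF/RE/MH the mental summary; VT/GH/SF load on both. Illustrative values.
_ILLUSTRATIVE_PCS = {
    "physical_functioning": 0.42,
    "role_physical": 0.35,
    "bodily_pain": 0.32,
    "general_health": 0.25,
    "vitality": 0.03,
    "social_functioning": -0.01,
    "role_emotional": -0.19,
    "mental_health": -0.22,
}
_ILLUSTRATIVE_MCS = {
    "physical_functioning": -0.23,
    "role_physical": -0.12,
    "bodily_pain": -0.10,
    "general_health": -0.02,
    "vitality": 0.24,
    "social_functioning": 0.27,
    "role_emotional": 0.43,
    "mental_health": 0.49,
}


@dataclass(frozen=True)
class NormCoefficients:
    """Population norms and factor weights for the component summaries."""

    means: dict[str, float] = field(default_factory=lambda: dict(_ILLUSTRATIVE_NORM_MEANS))
    sds: dict[str, float] = field(default_factory=lambda: dict(_ILLUSTRATIVE_NORM_SDS))
    pcs_coefs: dict[str, float] = field(default_factory=lambda: dict(_ILLUSTRATIVE_PCS))
    mcs_coefs: dict[str, float] = field(default_factory=lambda: dict(_ILLUSTRATIVE_MCS))

    def __post_init__(self) -> None:
        for name, table in (
            ("means", self.means),
            ("sds", self.sds),
            ("pcs_coefs", self.pcs_coefs),
            ("mcs_coefs", self.mcs_coefs),
        ):
            if set(table) != set(DOMAINS):
                raise ValueError(f"{name} must cover exactly the eight domains")
        if any(v <= 0 for v in self.sds.values()):
            raise ValueError("norm SDs must be positive")

    @classmethod
    def identity(cls) -> "NormCoefficients":
        """Mean-0 / SD-1 norms: T-scores become raw weighted sums rescaled."""
        return cls(
            means={d: 0.0 for d in DOMAINS},
            sds={d: 1.0 for d in DOMAINS},
            pcs_coefs=dict(_ILLUSTRATIVE_PCS),
            mcs_coefs=dict(_ILLUSTRATIVE_MCS),
        )


def score_components(
    domains: SF36Domains,
    norms: NormCoefficients | None = None,
    strict: bool = True,
) -> SF36Summaries:
    """Physical and mental component summary T-scores.

    ``strict`` requires all eight domains; otherwise missing domains are
    imputed at the norm mean (zero z-score).
    """
    if norms is None:
        norms = NormCoefficients()
    z: dict[str, float] = {}
    for d in DOMAINS:
        v = domains.scores.get(d, float("nan"))
        if v != v:
            if strict:
                raise ValueError(
                    f"participant {domains.participant_id!r}: domain {d} missing; "
                    "component summaries unavailable in strict mode"
                )
            z[d] = 0.0
        else:
            z[d] = (v - norms.means[d]) / norms.sds[d]
    pcs = 50.0 + 10.0 * sum(norms.pcs_coefs[d] * z[d] for d in DOMAINS)
    mcs = 50.0 + 10.0 * sum(norms.mcs_coefs[d] * z[d] for d in DOMAINS)
    return SF36Summaries(domains.participant_id, pcs=pcs, mcs=mcs)


def score_domain_table(
    table: pd.DataFrame,
    norms: NormCoefficients | None = None,
    strict: bool = True,
) -> pd.DataFrame:
    """Component summaries for a table of domain scores.

    ``table`` has ``participant_id`` plus the eight domain columns. In
    strict mode participants with missing domains get ``nan`` summaries
    (dropped from analysis, matching per-table complete-case counts).
    """
    records = []
    for _, row in table.iterrows():
        scores = {d: float(row[d]) for d in DOMAINS if d in row.index}
        dom = SF36Domains(str(row["participant_id"]), scores)
        if strict and not dom.complete():
            records.append(
                {"participant_id": dom.participant_id, "pcs": math.nan, "mcs": math.nan}
            )
            continue
        s = score_components(dom, norms=norms, strict=strict)
        records.append({"participant_id": s.participant_id, "pcs": s.pcs, "mcs": s.mcs})
    return pd.DataFrame.from_records(records)
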