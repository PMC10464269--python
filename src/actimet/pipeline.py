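"""End-to-end orchestration: simulate -> process -> score -> infer -> report.

:func:`run_pipeline` runs the whole analysis from a single :class:`RunConfig`
under one master seed, writes every intermediate and final table as
delimited text, keeps a participant-flow account (recorded -> trimmed ->
non-wear-excluded -> inclusion-passed, with a reason for every exclusion)
and emits a plain-text report stamped with the seed, bootstrap settings and
a content hash of the outputs.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from ._seeds import substream_seed
from .accel import CATEGORY_MEMBERS, METTable, process_stream
from .io import dump_yaml, write_table
from .ipaq import IPAQ_CATEGORIES, score_table
from .sf36 import DOMAINS, score_domain_table
from .stats import (
    BootstrapConfig,
    adjusted_group_difference,
    descriptive_table,
    interaction_association,
    proportion_test,
    spearman_rho,
)
from .synthetic import CohortBundle, CohortConfig, generate_cohort

__all__ = ["RunConfig", "RunReport", "run_pipeline"]

_CATEGORIES = tuple(CATEGORY_MEMBERS)


@dataclass
class RunConfig:
    """One pipeline run: cohort conditions plus analysis options."""

    out_dir: str = "actimet_run"
    seed: int = 0
    cohort: CohortConfig = field(default_factory=CohortConfig)
    bootstrap_B: int = 2000
    strict_inclusion: bool = False
    walking_met: float | None = None  # None = device value 2.8; 3.3 = IPAQ variant
    scope: str = "all"
    ipaq_partial: bool = False
    write_epochs: bool = False
    adjust_for: tuple[str, ...] = ()  # extra covariates: "month_of_assessment", "work_hours"

    def __post_init__(self) -> None:
        # the cohort inherits the master seed so one integer pins the run
        self.cohort.seed = self.seed

    @classmethod
    def from_yaml_dict(cls, data: dict) -> "RunConfig":
        cohort = CohortConfig(**data.pop("cohort", {}))
        data.pop("seed_cohort", None)
        adj = tuple(data.pop("adjust_for", ()) or ())
        cfg = cls(cohort=cohort, adjust_for=adj, **data)
        return cfg

    def to_dict(self) -> dict:
        d = asdict(self)
        d["adjust_for"] = list(self.adjust_for)
        d["cohort"]["nonwear_duration_minutes"] = list(self.cohort.nonwear_duration_minutes)
        return d


@dataclass
class RunReport:
    out_dir: Path
    flow: pd.DataFrame
    summaries: pd.DataFrame
    comparisons: pd.DataFrame
    associations: pd.DataFrame
    who: dict
    content_hash: str


def _participant_summaries(bundle: CohortBundle, cfg: RunConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    met = METTable.default(walking_met=cfg.walking_met)
    flow_rows, records = [], []
    for pid in sorted(bundle.epoch_streams):
        summary, flow = process_stream(
            bundle.epoch_streams[pid], met_table=met, strict=cfg.strict_inclusion, scope=cfg.scope
        )
        flow_rows.append(flow)
        if summary is not None and summary.available:
            records.append(summary.to_record())
    return pd.DataFrame.from_records(records), pd.DataFrame.from_records(flow_rows)


def _flow_accounting(flow: pd.DataFrame) -> pd.DataFrame:
    stages = [
        ("recorded", len(flow)),
        ("with_trimmed_days", int((flow["n_days_after_trim"] > 0).sum())),
        ("after_nonwear_rule", int((flow["n_days_after_nonwear"] > 0).sum())),
        ("inclusion_passed", int(flow["included"].sum())),
    ]
    return pd.DataFrame(stages, columns=["stage", "n_participants"])


def run_pipeline(cfg: RunConfig) -> RunReport:
    """Run the full pipeline and write all outputs under ``cfg.out_dir``."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundle = generate_cohort(cfg.cohort, materialize_epochs=True)
    participants = bundle.participants

    # --- accelerometer processing -------------------------------------
    summaries, flow = _participant_summaries(bundle, cfg)
    flow_table = _flow_accounting(flow)
    analysed = summaries.merge(participants, on="participant_id", how="inner")

    # --- questionnaire scoring ----------------------------------------
    ipaq_scores = score_table(bundle.ipaq, partial=cfg.ipaq_partial)
    sf36_summ = score_domain_table(bundle.sf36[["participant_id", *DOMAINS]], strict=True)
    # keep the directly supplied T-scores when item/domain scoring is bypassed
    sf36_summ = sf36_summ.rename(columns={"pcs": "pcs_scored", "mcs": "mcs_scored"}).merge(
        bundle.sf36[["participant_id", "pcs", "mcs"]], on="participant_id"
    )

    # --- inference -----------------------------------------------------
    boot_seed = substream_seed(cfg.seed, "bootstrap")
    extra = None
    if cfg.adjust_for:
        extra_cols = {}
        for name in cfg.adjust_for:
            col = analysed[name]
            extra_cols[name] = col.astype(str) if name == "month_of_assessment" else col
        extra = pd.DataFrame(extra_cols)
    comp_rows = []
    for i, cat in enumerate(_CATEGORIES):
        bcfg = BootstrapConfig(B=cfg.bootstrap_B, seed=substream_seed(boot_seed, "compare", cat))
        res = adjusted_group_difference(
            analysed[f"met_daily_{cat}"],
            analysed["group"],
            analysed["sex"],
            extra_covariates=extra,
            cfg=bcfg,
            outcome=f"objective_{cat}",
        )
        comp_rows.append(res.to_record())

    ipaq_analysed = ipaq_scores.merge(participants, on="participant_id", how="inner")
    ipaq_valid = ipaq_analysed[ipaq_analysed["total_weekly_met"].notna()]
    for cat in IPAQ_CATEGORIES:
        bcfg = BootstrapConfig(B=cfg.bootstrap_B, seed=substream_seed(boot_seed, "compare_sr", cat))
        res = adjusted_group_difference(
            ipaq_valid[f"daily_met_{cat}"],
            ipaq_valid["group"],
            ipaq_valid["sex"],
            cfg=bcfg,
            outcome=f"selfreport_{cat}",
        )
        comp_rows.append(res.to_record())
    comparisons = pd.DataFrame.from_records(comp_rows)

    hr = analysed.merge(sf36_summ, on="participant_id", how="inner")
    assoc_rows = []
    for cat in _CATEGORIES:
        for meas in ("pcs", "mcs"):
            bcfg = BootstrapConfig(
                B=cfg.bootstrap_B, seed=substream_seed(boot_seed, "assoc", cat, meas)
            )
            sub = hr.dropna(subset=[f"met_daily_{cat}", meas])
            res = interaction_association(
                sub[f"met_daily_{cat}"],
                sub[meas],
                sub["group"],
                sub["sex"],
                cfg=bcfg,
                pa_name=cat,
                sf36_name=meas,
            )
            assoc_rows.append(res.to_record())
    associations = pd.DataFrame.from_records(assoc_rows)

    # --- guideline compliance and correlations -------------------------
    sga = analysed[analysed["group"] == "SGA"]
    ctl = analysed[analysed["group"] == "control"]
    who_res = proportion_test(
        int(sga["who_compliant"].sum()), len(sga), int(ctl["who_compliant"].sum()), len(ctl)
    )
    who = {
        "k_SGA": int(sga["who_compliant"].sum()),
        "n_SGA": len(sga),
        "pct_SGA": who_res.prop1_pct,
        "k_control": int(ctl["who_compliant"].sum()),
        "n_control": len(ctl),
        "pct_control": who_res.prop2_pct,
        "chi2": who_res.statistic,
        "p_value": who_res.p_value,
    }

    corr_rows = []
    sr = analysed.merge(ipaq_valid[["participant_id", *(f"daily_met_{c}" for c in IPAQ_CATEGORIES)]],
                        on="participant_id", how="inner")
    sr["daily_met_mvpa"] = sr["daily_met_mpa"] + sr["daily_met_vpa"]
    for grp, sub in sr.groupby("group"):
        for obj, rep in (("met_walking", "daily_met_walking"), ("met_daily_running_cycling", "daily_met_mvpa")):
            try:
                rho = spearman_rho(sub[obj], sub[rep])
            except ValueError:
                rho = float("nan")
            corr_rows.append({"group": grp, "objective": obj, "selfreport": rep, "spearman_rho": rho})
    correlations = pd.DataFrame.from_records(corr_rows)

    desc = descriptive_table(
        participants.assign(female=(participants["sex"] == "female").astype(int)),
        {"work_hours": "continuous", "female": "dichotomous"},
        seed=substream_seed(cfg.seed, "descriptives"),
        n_perm=20_000,
    )

    # --- outputs --------------------------------------------------------
    tables = {
        "participants.csv": participants,
        "daily_truth.csv": bundle.daily_truth,
        "pa_summaries.csv": summaries,
        "participant_flow.csv": flow,
        "flow_accounting.csv": flow_table,
        "ipaq_scores.csv": ipaq_scores,
        "sf36_summaries.csv": sf36_summ,
        "compare_met_minutes.csv": comparisons,
        "associations_sf36.csv": associations,
        "correlations.csv": correlations,
        "descriptives.csv": desc,
    }
    for name, df in tables.items():
        write_table(df, out / name)
    if cfg.write_epochs and bundle.epoch_streams:
        from .io import write_epoch_streams

        write_epoch_streams(bundle.epoch_streams, out / "epoch_streams.csv")
    dump_yaml(cfg.to_dict(), out / "run_config.yaml")

    sha = hashlib.sha256()
    for name in sorted(tables):
        sha.update((out / name).read_bytes())
    content_hash = sha.hexdigest()

    report_lines = [
        f"actimet v{__version__} pipeline report",
        f"master_seed: {cfg.seed}",
        f"bootstrap: B={cfg.bootstrap_B}, method=BCa, stratified_by_group=True",
        f"inclusion_rule: {'>=3 weekdays & >=1 weekend day' if cfg.strict_inclusion else '>=1 weekday & >=1 weekend day'}",
        f"walking_met: {cfg.walking_met if cfg.walking_met is not None else 2.8}",
        "",
        "participant flow:",
        flow_table.to_string(index=False),
        "",
        "guideline compliance (daily running/cycling MET minutes >= 600/7):",
        f"  SGA {who['k_SGA']}/{who['n_SGA']} = {who['pct_SGA']}%  "
        f"control {who['k_control']}/{who['n_control']} = {who['pct_control']}%  "
        f"(chi2 p = {who['p_value']:.3f})",
        "",
        f"content_hash: {content_hash}",
        "",
    ]
    (out / "report.txt").write_text("\n".join(report_lines))

    return RunReport(
        out_dir=out,
        flow=flow_table,
        summaries=summaries,
        comparisons=comparisons,
        associations=associations,
        who=who,
        content_hash=content_hash,
    )
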