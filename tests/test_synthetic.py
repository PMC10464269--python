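"""Synthetic cohort generator: invariants, determinism, recoverability."""

import numpy as np
import pandas as pd
import pytest

from actimet.accel import (
    ACTIVITY_LABELS,
    ALL_LABELS,
    EPOCHS_PER_DAY,
    MINUTES_PER_DAY,
    majority_vote_minutes,
    process_stream,
)
from actimet.ipaq import validate_response
from actimet.stats import spearman_rho
from actimet.synthetic import (
    ActivityProfile,
    CohortConfig,
    ConfigError,
    GROUP_BUDGETS,
    derive_ipaq_from_truth,
    derive_sf36_from_truth,
    generate_cohort,
    inject_nonwear,
    onmove_met_of,
    simulate_epoch_stream,
)


def profile(pid="P1", **overrides):
    minutes = {k: float(v) for k, v in GROUP_BUDGETS["control"].items()}
    minutes.update(overrides)
    total = sum(minutes.values())
    minutes["sitting"] += MINUTES_PER_DAY - total
    return ActivityProfile(pid, minutes)


class TestProfileValidation:
    def test_must_sum_to_1440(self):
        with pytest.raises(ConfigError, match="1440"):
            ActivityProfile("P1", {lab: 100.0 for lab in ACTIVITY_LABELS})

    def test_lying_must_cover_night(self):
        bad = {lab: 0.0 for lab in ACTIVITY_LABELS}
        bad["lying"] = 200.0
        bad["sitting"] = MINUTES_PER_DAY - 200.0
        with pytest.raises(ConfigError, match="night"):
            ActivityProfile("P1", bad)

    def test_config_errors_name_the_field(self):
        with pytest.raises(ConfigError, match="n_sga"):
            CohortConfig(n_sga=0)
        with pytest.raises(ConfigError, match="prop_female"):
            CohortConfig(prop_female=1.5)
        with pytest.raises(ConfigError, match="n_days"):
            CohortConfig(n_days=2)
        with pytest.raises(ConfigError, match="selfreport_bias_mvpa"):
            CohortConfig(selfreport_bias_mvpa=0.8)
        with pytest.raises(ConfigError, match="beta_metmin_per_pcs_point"):
            CohortConfig(beta_metmin_per_pcs_point={"SGA": 1.0})


class TestEpochSimulation:
    def test_epoch_count_and_minute_conservation(self):
        stream, truth = simulate_epoch_stream(profile(), n_days=4, seed=0)
        assert stream.n_epochs == 4 * EPOCHS_PER_DAY
        # per-day label minutes in the truth table sum to 1440
        assert truth[list(ACTIVITY_LABELS)].sum(axis=1).eq(MINUTES_PER_DAY).all()

    def test_truth_matches_stream_counts(self):
        stream, truth = simulate_epoch_stream(profile(), n_days=3, seed=5)
        minutes = majority_vote_minutes(stream)
        for i, lab in enumerate(ACTIVITY_LABELS):
            assert float(np.sum(minutes.codes == i)) == pytest.approx(truth[lab].sum())

    def test_degenerate_all_lying_profile(self):
        p = ActivityProfile(
            "P1",
            {**{lab: 0.0 for lab in ACTIVITY_LABELS}, "lying": 1440.0},
            day_to_day_sd=0.0,
        )
        stream, truth = simulate_epoch_stream(p, n_days=3, seed=1)
        assert (truth["lying"] == MINUTES_PER_DAY).all()
        assert np.all(stream.codes == 0)

    def test_walking_mean_near_budget(self):
        p = profile(walking=60.0)
        p.day_to_day_sd = 10.0
        _, truth = simulate_epoch_stream(p, n_days=10, seed=3)
        se = 10.0 / np.sqrt(10)
        assert truth["walking"].mean() == pytest.approx(60.0, abs=3 * se)

    def test_night_window_is_lying(self):
        stream, _ = simulate_epoch_stream(profile(), n_days=2, seed=2)
        minutes = majority_vote_minutes(stream)
        clock = np.arange(minutes.n_minutes) % MINUTES_PER_DAY
        night = (clock >= 1380) | (clock < 420)
        assert np.all(minutes.codes[night] == 0)  # lying is code 0


class TestNonwear:
    def test_rate_zero_is_identity(self):
        stream, _ = simulate_epoch_stream(profile(), n_days=3, seed=4)
        out = inject_nonwear(stream, rate=0.0, seed=9)
        assert np.array_equal(out.codes, stream.codes)

    def test_deterministic_given_seed(self):
        stream, _ = simulate_epoch_stream(profile(), n_days=5, seed=4)
        a = inject_nonwear(stream, rate=1.0, seed=11)
        b = inject_nonwear(stream, rate=1.0, seed=11)
        assert np.array_equal(a.codes, b.codes)
        assert a.n_epochs == stream.n_epochs

    def test_long_midweek_gap_triggers_exclusion(self):
        # 90 contiguous non-wear minutes on day 3 of 7: the non-wear rule
        # drops that day onward, leaving 1 retained day after trimming
        stream, _ = simulate_epoch_stream(profile(), n_days=7, seed=6, start_date="2019-09-04")
        codes = stream.codes.copy()
        start = 2 * EPOCHS_PER_DAY + 600 * 12  # day 3, 10:00
        codes[start : start + 90 * 12] = len(ALL_LABELS) - 1  # nonwear code
        gapped = type(stream)(stream.participant_id, stream.start, codes)
        _, flow = process_stream(gapped)
        assert flow["n_days_after_trim"] == 5
        assert flow["n_days_after_nonwear"] == 1
        assert not flow["included"]


class TestCouplings:
    def test_ipaq_response_valid_and_biased(self):
        rng = np.random.default_rng(0)
        p = profile(running=20.0, cycling=20.0)
        over = under = 0
        for i in range(50):
            resp = derive_ipaq_from_truth(p, bias=1.5, noise_sd=10.0, seed=rng)
            assert validate_response(resp).value != "invalid"
            reported_mvpa = resp.minutes_mpa + resp.minutes_vpa
            if reported_mvpa > 40.0:
                over += 1
            else:
                under += 1
        # bias 1.5 means reports exceed the 40 true minutes almost always
        assert over > 45

    def test_sf36_noiseless_slope_exact(self):
        rng = np.random.default_rng(1)
        rows = []
        base = onmove_met_of(profile().expected_minutes)
        for i in range(40):
            rec, adj = derive_sf36_from_truth(
                profile(f"P{i}"), beta_metmin_per_pcs_point=2.0, noise_sd=0.0, seed=rng
            )
            rows.append((rec["pcs"], onmove_met_of(adj.expected_minutes)))
        pcs = np.array([r[0] for r in rows])
        met = np.array([r[1] for r in rows])
        slope = np.polyfit(pcs, met, 1)[0]
        assert slope == pytest.approx(2.0, abs=1e-6)
        assert met.mean() == pytest.approx(base + 2.0 * (pcs.mean() - 50.0), abs=1e-6)

    def test_sf36_adjusted_profile_feasible(self):
        rng = np.random.default_rng(2)
        for i in range(200):
            rec, adj = derive_sf36_from_truth(
                profile(f"P{i}"), beta_metmin_per_pcs_point=8.0, noise_sd=150.0, seed=rng
            )
            # the ActivityProfile constructor re-validates: sum 1440,
            # non-negative, lying covers the night
            assert sum(adj.expected_minutes.values()) == pytest.approx(MINUTES_PER_DAY)


class TestCohort:
    def test_same_seed_identical_bundles(self):
        cfg = CohortConfig(n_sga=6, n_control=6, seed=123)
        a = generate_cohort(cfg)
        b = generate_cohort(CohortConfig(n_sga=6, n_control=6, seed=123))
        pd.testing.assert_frame_equal(a.participants, b.participants)
        pd.testing.assert_frame_equal(a.daily_truth, b.daily_truth)
        pd.testing.assert_frame_equal(a.ipaq, b.ipaq)
        pd.testing.assert_frame_equal(a.sf36, b.sf36)
        for pid in a.epoch_streams:
            assert np.array_equal(a.epoch_streams[pid].codes, b.epoch_streams[pid].codes)

    def test_different_seed_differs(self):
        a = generate_cohort(CohortConfig(n_sga=4, n_control=4, seed=1), materialize_epochs=False)
        b = generate_cohort(CohortConfig(n_sga=4, n_control=4, seed=2), materialize_epochs=False)
        assert not a.daily_truth[list(ACTIVITY_LABELS)].equals(b.daily_truth[list(ACTIVITY_LABELS)])

    def test_fast_path_truth_matches_materialized(self, small_cohort):
        cfg = small_cohort.config
        fast = generate_cohort(
            CohortConfig(n_sga=cfg.n_sga, n_control=cfg.n_control, seed=cfg.seed),
            materialize_epochs=False,
        )
        pd.testing.assert_frame_equal(fast.daily_truth, small_cohort.daily_truth)
        assert fast.epoch_streams == {}

    def test_monitoring_starts_wednesday(self, small_cohort):
        starts = pd.to_datetime(small_cohort.participants["start_date"])
        assert (starts.dt.weekday == 2).all()

    def test_null_group_effect_recovered(self):
        """With matched budgets and no injected effect the groups' true
        on-the-move MET means agree within sampling error."""
        cfg = CohortConfig(
            n_sga=200,
            n_control=200,
            seed=31,
            beta_metmin_per_pcs_point={"SGA": 0.0, "control": 0.0},
            onmove_noise_sd_met=0.0,
        )
        bundle = generate_cohort(cfg, materialize_epochs=False)
        truth = bundle.truth_daily_met("on_the_move")
        g = bundle.participants.set_index("participant_id")["group"]
        diff = truth[g == "SGA"].mean() - truth[g == "control"].mean()
        expected = onmove_met_of({k: float(v) for k, v in GROUP_BUDGETS["SGA"].items()}) - onmove_met_of(
            {k: float(v) for k, v in GROUP_BUDGETS["control"].items()}
        )
        # running/cycling heterogeneity has SD ~ mean (~40); n=200/group
        se = 60.0 / np.sqrt(200)
        assert diff == pytest.approx(expected, abs=3 * np.sqrt(2) * se)

    def test_selfreport_bias_inflates_mvpa(self):
        cfg = CohortConfig(n_sga=60, n_control=60, seed=17, ipaq_incomplete_rate=0.0, ipaq_invalid_rate=0.0)
        bundle = generate_cohort(cfg, materialize_epochs=False)
        truth_rc = bundle.truth_daily_met("running_cycling")
        # reported MVPA MET minutes per day (IPAQ values: MPA 4, VPA 8)
        ipaq = bundle.ipaq.set_index("participant_id")
        reported = (
            4.0 * ipaq["days_mpa"] * ipaq["minutes_mpa"] + 8.0 * ipaq["days_vpa"] * ipaq["minutes_vpa"]
        ) / 7.0
        assert reported.mean() > truth_rc.mean()

    def test_walking_correlates_worse_than_mvpa(self):
        cfg = CohortConfig(n_sga=100, n_control=100, seed=23, ipaq_incomplete_rate=0.0, ipaq_invalid_rate=0.0)
        bundle = generate_cohort(cfg, materialize_epochs=False)
        t = bundle.daily_truth.groupby("participant_id")[["walking", "running", "cycling"]].mean()
        ipaq = bundle.ipaq.set_index("participant_id").loc[t.index]
        rho_walk = spearman_rho(t["walking"], ipaq["days_walking"] * ipaq["minutes_walking"])
        truth_rc_met = 7.0 * t["running"] + 4.0 * t["cycling"]
        rep_mvpa = ipaq["days_mpa"] * ipaq["minutes_mpa"] + ipaq["days_vpa"] * ipaq["minutes_vpa"]
        rho_mvpa = spearman_rho(truth_rc_met, rep_mvpa)
        assert rho_walk < rho_mvpa
        assert rho_mvpa > 0.5

    def test_missingness_rates_applied(self):
        cfg = CohortConfig(n_sga=150, n_control=150, seed=29, ipaq_incomplete_rate=0.3, sf36_partial_rate=0.05)
        bundle = generate_cohort(cfg, materialize_epochs=False)
        frac_missing = bundle.ipaq[["minutes_walking", "minutes_mpa", "minutes_vpa"]].isna().any(axis=1).mean()
        assert 0.2 < frac_missing < 0.4
        assert 0.0 < bundle.sf36["pcs"].isna().mean() < 0.15
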