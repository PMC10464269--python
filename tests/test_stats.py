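"""Inference layer: BCa bootstrap, regression contrasts, classical tests."""

import numpy as np
import pandas as pd
import pytest
import scipy.stats as sps

from actimet.stats import (
    BootstrapConfig,
    adjusted_group_difference,
    bca_interval,
    bootstrap_p,
    descriptive_table,
    interaction_association,
    mannwhitney_permutation,
    mdes_power,
    percent,
    ponderal_index,
    proportion_test,
    spearman_rho,
)


class TestClassicalTests:
    def test_spearman_perfect_monotone(self):
        x = np.array([1, 2, 3, 4, 5], dtype=float)
        assert spearman_rho(x, x**3) == pytest.approx(1.0)
        assert spearman_rho(x, -x) == pytest.approx(-1.0)

    def test_spearman_hand_case(self):
        # ranks of y vs x: one swap among five -> rho = 1 - 6*2/ (5*24) = 0.9
        x = [1.0, 2.0, 3.0, 4.0, 5.0]
        y = [10.0, 20.0, 40.0, 30.0, 50.0]
        assert spearman_rho(x, y) == pytest.approx(0.9)

    def test_spearman_guards(self):
        with pytest.raises(ValueError, match="3 complete pairs"):
            spearman_rho([1.0, 2.0], [2.0, 1.0])
        with pytest.raises(ValueError, match="zero variance"):
            spearman_rho([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    def test_percent_and_ponderal(self):
        assert percent(5, 37) == 13.5
        assert percent(6, 43) == 14.0
        assert percent(56, 86, decimals=0) == 65.0
        assert percent(68, 118, decimals=0) == 58.0
        # 2916 g at 48.5 cm
        assert round(ponderal_index(2916, 48.5), 1) == 2.6

    def test_proportion_test_identical_groups(self):
        res = proportion_test(10, 40, 10, 40)
        assert res.statistic == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_proportion_test_hand_chi2(self):
        # 2x2 table [[10,10],[0,20]]: chi2 = 40*(10*20-10*0)^2/(20*20*10*30)
        res = proportion_test(10, 20, 0, 20)
        assert res.statistic == pytest.approx(40 * (10 * 20) ** 2 / (20 * 20 * 10 * 30))
        assert res.prop1_pct == 50.0 and res.prop2_pct == 0.0

    def test_proportion_test_zero_margin_raises(self):
        with pytest.raises(ValueError, match="margin"):
            proportion_test(0, 20, 0, 20)

    def test_mdes_normal_closed_form(self):
        got = mdes_power(64, 81)
        z = sps.norm.ppf
        expect = (z(0.975) + z(0.80)) * np.sqrt(1 / 64 + 1 / 81)
        assert got == pytest.approx(expect)
        assert got == pytest.approx(0.4685, abs=5e-4)

    def test_mdes_scales_with_sqrt_n(self):
        assert mdes_power(50, 50) == pytest.approx(np.sqrt(2) * mdes_power(100, 100))

    def test_mdes_noncentral_t_slightly_larger(self):
        normal = mdes_power(64, 81)
        nct = mdes_power(64, 81, method="noncentral_t")
        assert nct > normal
        assert nct == pytest.approx(normal, rel=0.02)


class TestMannWhitney:
    def test_exact_matches_scipy(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            x = rng.normal(size=5)
            y = rng.normal(0.5, size=6)
            u, p = mannwhitney_permutation(x, y)
            ref = sps.mannwhitneyu(x, y, alternative="two-sided", method="exact")
            assert u == pytest.approx(float(ref.statistic))
            assert p == pytest.approx(float(ref.pvalue), abs=1e-12)

    def test_identical_groups_p_one(self):
        x = np.arange(6, dtype=float)
        _, p = mannwhitney_permutation(x, x)
        assert p == pytest.approx(1.0)

    def test_monte_carlo_close_to_scipy_asymptotic(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=15)
        y = rng.normal(0.8, size=15)
        _, p = mannwhitney_permutation(x, y, n_perm=50_000, seed=9)
        ref = sps.mannwhitneyu(x, y, alternative="two-sided")
        assert p == pytest.approx(float(ref.pvalue), abs=0.01)


class TestBCaBootstrap:
    def test_degenerate_data_zero_width_with_warning(self):
        data = np.full(30, 4.0)
        with pytest.warns(UserWarning, match="degenerate"):
            lo, hi = bca_interval(np.mean, data, BootstrapConfig(B=200, seed=0))
        assert lo == hi == 4.0

    def test_matches_scipy_bca_on_fixed_sample(self):
        rng = np.random.default_rng(11)
        data = rng.gamma(2.0, 3.0, size=60)
        cfg = BootstrapConfig(B=4000, seed=5)
        lo, hi = bca_interval(np.mean, data, cfg)
        ref = sps.bootstrap(
            (data,),
            np.mean,
            method="BCa",
            n_resamples=4000,
            confidence_level=0.95,
            random_state=np.random.default_rng(7),
        ).confidence_interval
        se = data.std(ddof=1) / np.sqrt(data.size)
        assert lo == pytest.approx(ref.low, abs=0.15 * se)
        assert hi == pytest.approx(ref.high, abs=0.15 * se)

    def test_symmetric_statistic_close_to_percentile(self):
        rng = np.random.default_rng(2)
        data = rng.normal(10.0, 2.0, size=80)
        cfg = BootstrapConfig(B=4000, seed=8)
        lo, hi = bca_interval(np.mean, data, cfg)
        boot = np.array(
            [np.mean(rng.choice(data, data.size)) for _ in range(4000)]
        )
        plo, phi = np.quantile(boot, [0.025, 0.975])
        se = data.std(ddof=1) / np.sqrt(data.size)
        assert lo == pytest.approx(plo, abs=0.2 * se)
        assert hi == pytest.approx(phi, abs=0.2 * se)

    def test_p_value_consistent_with_interval(self):
        """p <= alpha exactly when the (1-alpha) interval excludes zero."""
        rng = np.random.default_rng(6)
        for shift in (0.0, 0.3, 1.0):
            data = rng.normal(shift, 1.0, size=40)
            cfg = BootstrapConfig(B=1000, seed=13)
            p = bootstrap_p(np.mean, data, cfg)
            for alpha in (0.01, 0.05, 0.2):
                lo, hi = bca_interval(np.mean, data, cfg, alpha=alpha)
                excludes = lo > 0 or hi < 0
                assert (p <= alpha) == excludes

    def test_interval_width_shrinks_with_n(self):
        rng = np.random.default_rng(21)
        widths = []
        for n in (20, 80, 320):
            data = rng.normal(0, 1, size=n)
            lo, hi = bca_interval(np.mean, data, BootstrapConfig(B=1000, seed=3))
            widths.append(hi - lo)
        assert widths[0] > widths[1] > widths[2]

    def test_config_validation(self):
        with pytest.raises(ValueError, match="at least 100"):
            BootstrapConfig(B=10)
        with pytest.raises(ValueError, match="alpha grid"):
            BootstrapConfig(alpha_grid=[0.0, 0.5])


def make_two_group(n_per=40, effect=0.0, sex_shift=0.0, seed=0):
    rng = np.random.default_rng(seed)
    group = np.array(["SGA"] * n_per + ["control"] * n_per)
    sex = rng.choice(["female", "male"], size=2 * n_per)
    y = rng.normal(100.0, 10.0, size=2 * n_per)
    y[group == "SGA"] += effect
    y[sex == "male"] += sex_shift
    return pd.DataFrame({"y": y, "group": group, "sex": sex})


class TestAdjustedGroupDifference:
    def test_recovers_injected_effect(self):
        df = make_two_group(n_per=120, effect=-8.0, seed=1)
        res = adjusted_group_difference(df["y"], df["group"], df["sex"], cfg=BootstrapConfig(B=500, seed=2))
        assert res.index_group == "SGA" and res.reference_group == "control"
        assert res.estimate == pytest.approx(-8.0, abs=3.0)
        assert res.ci_low <= res.estimate <= res.ci_high
        assert res.p_value <= 0.01

    def test_null_effect_interval_usually_covers_zero(self):
        df = make_two_group(n_per=60, effect=0.0, seed=5)
        res = adjusted_group_difference(df["y"], df["group"], df["sex"], cfg=BootstrapConfig(B=500, seed=6))
        assert res.ci_low < 0 < res.ci_high
        assert res.p_value > 0.05

    def test_sex_adjustment_removes_confounding(self):
        # construct sex imbalance: SGA mostly male, males shifted +20
        rng = np.random.default_rng(9)
        n = 80
        group = np.array(["SGA"] * n + ["control"] * n)
        sex = np.where(
            np.concatenate([rng.random(n) < 0.9, rng.random(n) < 0.1]), "male", "female"
        )
        y = rng.normal(100.0, 5.0, size=2 * n) + np.where(sex == "male", 20.0, 0.0)
        res = adjusted_group_difference(y, group, sex, cfg=BootstrapConfig(B=500, seed=10))
        # naive difference is ~ +16; adjusted estimate should be near 0
        naive = y[:n].mean() - y[n:].mean()
        assert abs(naive) > 10.0
        assert abs(res.estimate) < 3.0

    def test_small_group_refused(self):
        df = make_two_group(n_per=8)
        with pytest.raises(ValueError, match="at least 10"):
            adjusted_group_difference(df["y"], df["group"], df["sex"])

    def test_extra_covariates_and_missing_rows(self):
        df = make_two_group(n_per=40, effect=-5.0, seed=3)
        extra = pd.DataFrame({"work_hours": np.random.default_rng(4).normal(37.5, 8, len(df))})
        df.loc[0, "y"] = np.nan
        res = adjusted_group_difference(
            df["y"], df["group"], df["sex"], extra_covariates=extra, cfg=BootstrapConfig(B=200, seed=5)
        )
        assert res.n_dropped["y"] == 1
        assert "work_hours" in res.covariates

    def test_singular_design_names_columns(self):
        df = make_two_group(n_per=20, seed=12)
        # duplicate of the group indicator as an extra covariate
        extra = pd.DataFrame({"dup": (df["group"] == "SGA").astype(float)})
        with pytest.raises(ValueError, match="dup"):
            adjusted_group_difference(df["y"], df["group"], df["sex"], extra_covariates=extra)


class TestInteractionAssociation:
    def test_noiseless_slopes_exact(self):
        rng = np.random.default_rng(7)
        n = 60
        group = np.array(["SGA"] * n + ["control"] * n)
        sex = rng.choice(["female", "male"], size=2 * n)
        sf = rng.normal(50.0, 10.0, size=2 * n)
        slope = np.where(group == "SGA", 4.0, 0.5)
        pa = 200.0 + slope * (sf - 50.0) + np.where(sex == "male", 10.0, 0.0)
        res = interaction_association(pa, sf, group, sex, cfg=BootstrapConfig(B=200, seed=1))
        est_sga = res.slopes["SGA"][0]
        est_ctl = res.slopes["control"][0]
        assert est_sga == pytest.approx(4.0, abs=1e-8)
        assert est_ctl == pytest.approx(0.5, abs=1e-8)
        assert res.interaction_p <= 0.01

    def test_noisy_interaction_detected(self):
        rng = np.random.default_rng(8)
        n = 100
        group = np.array(["SGA"] * n + ["control"] * n)
        sex = rng.choice(["female", "male"], size=2 * n)
        sf = rng.normal(50.0, 10.0, size=2 * n)
        pa = 300.0 + np.where(group == "SGA", 4.0, 0.0) * (sf - 50.0) + rng.normal(0, 30, 2 * n)
        res = interaction_association(pa, sf, group, sex, cfg=BootstrapConfig(B=500, seed=2))
        est, lo, hi, _ = res.slopes["SGA"]
        # OLS slope SE here is ~0.3; the estimate and interval sit near 4
        assert est == pytest.approx(4.0, abs=1.0)
        assert hi - lo < 2.5
        assert res.interaction_p <= 0.01

    def test_interaction_p_near_uniform_under_null(self):
        """Bootstrap interaction p-values are roughly uniform when slopes
        are equal (calibration check via Kolmogorov-Smirnov)."""
        rng = np.random.default_rng(42)
        pvals = []
        n = 30
        for rep in range(150):
            group = np.array(["SGA"] * n + ["control"] * n)
            sex = rng.choice(["female", "male"], size=2 * n)
            sf = rng.normal(50.0, 10.0, size=2 * n)
            pa = 250.0 + 1.0 * (sf - 50.0) + rng.normal(0, 40, 2 * n)
            res = interaction_association(
                pa, sf, group, sex, cfg=BootstrapConfig(B=200, seed=rep)
            )
            pvals.append(res.interaction_p)
        ks = sps.kstest(pvals, "uniform")
        assert ks.pvalue > 0.01


class TestDescriptiveTable:
    def test_shape_and_types(self):
        rng = np.random.default_rng(14)
        n = 30
        df = pd.DataFrame(
            {
                "group": ["SGA"] * n + ["control"] * n,
                "age": rng.normal(24, 1, 2 * n),
                "score": rng.integers(1, 6, 2 * n),
                "female": rng.integers(0, 2, 2 * n),
            }
        )
        out = descriptive_table(
            df,
            {"age": "continuous", "score": "ordinal", "female": "dichotomous"},
            n_perm=5_000,
            seed=1,
        )
        assert list(out["variable"]) == ["age", "score", "female"]
        assert out["p_value"].between(0, 1).all()
        assert out.loc[0, "n_SGA"] == n and out.loc[0, "n_control"] == n

    def test_unknown_type_raises(self):
        df = make_two_group(n_per=12)
        with pytest.raises(ValueError, match="unknown variable type"):
            descriptive_table(df, {"y": "nominal"})
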